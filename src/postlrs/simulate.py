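"""Synthetic post-myopic-LRS pseudophakic cohorts.

Generates eyes with the statistical structure the analysis assumes: long
axial lengths and flattened corneas (negatively correlated), a multi-model
IOL mix with labelled A-constants, implanted powers chosen by a designated
ground-truth method for a near-emmetropic target, and observed postoperative
refractions equal to the truth method's prediction (computed with a per-model
*true* constant) plus Gaussian noise.  A fraction of records loses its IOL
model label, so the manufacturer-constant vs optimized-constant split of the
analysis is exercised.

The marginal AL and K distributions are truncated normals; the latent means
are recentered so the *truncated* means match the configured ones.  A sidecar
table records the generating method, true constants, targets and noiseless
refractions — sufficient to replay every prediction exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as spo
from scipy import stats as sps

from .cohort import EyeRecord
from .formulas import Method, emmetropic_power, predict, srkt_predict_refraction
from .cohort import convert_constant
from .subgroups import RangeScheme

__all__ = [
    "IolModel",
    "DEFAULT_CATALOG",
    "SimulationConfig",
    "simulate_cohort",
    "truth_mixture_cohort",
    "synthetic_barrett_table",
]


@dataclass(frozen=True)
class IolModel:
    name: str
    a_constant: float   # labelled (manufacturer) A-constant
    share: float        # market share among known-model eyes


#: A plausible multi-model market mix; the small-share tail guarantees that a
#: cohort-sized draw contains under-represented models (sub-3 groups).
DEFAULT_CATALOG: tuple[IolModel, ...] = (
    IolModel("SN60WF", 118.7, 0.28),
    IolModel("ZCB00", 119.3, 0.22),
    IolModel("MA60AC", 118.9, 0.16),
    IolModel("PCB00", 119.3, 0.12),
    IolModel("SA60AT", 118.4, 0.10),
    IolModel("MX60", 119.2, 0.06),
    IolModel("ZA9003", 119.1, 0.03),
    IolModel("LI61AO", 118.0, 0.02),
    IolModel("XLSTABI", 118.3, 0.01),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort draw.

    Biometry defaults reproduce the descriptive statistics of the clinical
    setting this pipeline targets (post-myopic-LRS eyes: long AL, flat K,
    negative AL-K correlation).  ``truth_model`` is the method whose
    predictions, evaluated with per-model true constants, generate the
    observed refractions.
    """

    n_eyes: int
    seed: int
    al_mean: float = 27.65
    al_sd: float = 2.11
    al_min: float = 23.72
    al_max: float = 34.20
    k_mean: float = 38.08
    k_sd: float = 2.69
    k_min: float = 31.56
    k_max: float = 43.81
    al_k_correlation: float = -0.5
    iol_catalog: tuple[IolModel, ...] = DEFAULT_CATALOG
    power_step: float = 0.5
    truth_model: Method = Method.SHAMMAS
    noise_sd: float = 0.4          # D, postop refraction noise
    unknown_model_fraction: float = 0.19
    targets: tuple[float, ...] = (0.0, -0.25, -0.5)
    #: true A-constant per model; None draws one offset per model in
    #: [-0.75, +0.75] around the label from the cohort's RNG stream
    true_a_constants: Mapping[str, float] | None = None

    def __post_init__(self):
        if not (self.al_min < self.al_max and self.k_min < self.k_max):
            raise ValueError("inconsistent truncation bounds")
        total = sum(m.share for m in self.iol_catalog)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"catalog shares must sum to 1, got {total}")
        for mean, sd, lo, hi, name in (
            (self.al_mean, self.al_sd, self.al_min, self.al_max, "AL"),
            (self.k_mean, self.k_sd, self.k_min, self.k_max, "K"),
        ):
            if mean < lo - 5 * sd or mean > hi + 5 * sd:
                raise ValueError(f"infeasible truncation for {name}")


def _recentered_latent_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Latent normal mean whose (lo, hi)-truncated mean equals ``mean``."""

    def trunc_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return sps.truncnorm.mean(a, b, loc=mu, scale=sd) - mean

    return spo.brentq(trunc_mean, mean - 5 * sd, mean + 5 * sd, xtol=1e-10)


def _bvn_rect_means(mu, s1, s2, rho, lo1, hi1, lo2, hi2):
    """First moments of a bivariate normal truncated to a rectangle (Tallis)."""
    a1, b1 = (lo1 - mu[0]) / s1, (hi1 - mu[0]) / s1
    a2, b2 = (lo2 - mu[1]) / s2, (hi2 - mu[1]) / s2
    cov = [[1.0, rho], [rho, 1.0]]
    bvn = sps.multivariate_normal([0.0, 0.0], cov)
    L = (bvn.cdf([b1, b2]) - bvn.cdf([a1, b2])
         - bvn.cdf([b1, a2]) + bvn.cdf([a1, a2]))
    root = math.sqrt(1.0 - rho * rho)

    def band(x, lo, hi):
        # P(lo < Z2 < hi | Z1 = x) for standard BVN
        return sps.norm.cdf((hi - rho * x) / root) - sps.norm.cdf((lo - rho * x) / root)

    e1 = (sps.norm.pdf(a1) * band(a1, a2, b2) - sps.norm.pdf(b1) * band(b1, a2, b2)
          + rho * (sps.norm.pdf(a2) * band(a2, a1, b1)
                   - sps.norm.pdf(b2) * band(b2, a1, b1))) / L
    e2 = (sps.norm.pdf(a2) * band(a2, a1, b1) - sps.norm.pdf(b2) * band(b2, a1, b1)
          + rho * (sps.norm.pdf(a1) * band(a1, a2, b2)
                   - sps.norm.pdf(b1) * band(b1, a2, b2))) / L
    return mu[0] + s1 * e1, mu[1] + s2 * e2


def _recentered_latent_means(cfg: SimulationConfig) -> tuple[float, float]:
    """Latent (AL, K) means whose rectangle-truncated joint means hit the
    configured ones; the correlation couples the two, so the recentering is a
    2-D root-find on the Tallis moments."""

    def residual(mu):
        m1, m2 = _bvn_rect_means(mu, cfg.al_sd, cfg.k_sd, cfg.al_k_correlation,
                                 cfg.al_min, cfg.al_max, cfg.k_min, cfg.k_max)
        return [m1 - cfg.al_mean, m2 - cfg.k_mean]

    sol = spo.root(residual, [cfg.al_mean, cfg.k_mean], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"latent mean recentering failed: {sol.message}")
    return float(sol.x[0]), float(sol.x[1])


def _draw_biometry(cfg: SimulationConfig, rng: np.random.Generator,
                   n: int) -> tuple[np.ndarray, np.ndarray]:
    mu_al, mu_k = _recentered_latent_means(cfg)
    cov = np.array([
        [cfg.al_sd ** 2, cfg.al_k_correlation * cfg.al_sd * cfg.k_sd],
        [cfg.al_k_correlation * cfg.al_sd * cfg.k_sd, cfg.k_sd ** 2],
    ])
    out_al = np.empty(n)
    out_k = np.empty(n)
    filled = 0
    while filled < n:
        batch = rng.multivariate_normal([mu_al, mu_k], cov, size=max(2 * (n - filled), 16))
        ok = ((batch[:, 0] >= cfg.al_min) & (batch[:, 0] <= cfg.al_max)
              & (batch[:, 1] >= cfg.k_min) & (batch[:, 1] <= cfg.k_max))
        take = batch[ok][: n - filled]
        out_al[filled:filled + len(take)] = take[:, 0]
        out_k[filled:filled + len(take)] = take[:, 1]
        filled += len(take)
    return out_al, out_k


def _true_constants(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, float]:
    if cfg.true_a_constants is not None:
        return dict(cfg.true_a_constants)
    return {
        m.name: m.a_constant + rng.uniform(-0.75, 0.75)
        for m in cfg.iol_catalog
    }


def _generate(cfg: SimulationConfig,
              truth_of: Callable[[float, float], Method]
              ) -> tuple[list[EyeRecord], pd.DataFrame]:
    rng = np.random.default_rng(cfg.seed)
    sidecar_cols = ["eye_id", "truth_method", "iol_model_true",
                    "true_a_constant", "target_d", "se_noiseless_d"]
    if cfg.n_eyes == 0:
        return [], pd.DataFrame(columns=sidecar_cols)

    true_const = _true_constants(cfg, rng)
    al, k = _draw_biometry(cfg, rng, cfg.n_eyes)
    shares = np.array([m.share for m in cfg.iol_catalog])
    model_idx = rng.choice(len(cfg.iol_catalog), size=cfg.n_eyes, p=shares)
    targets = rng.choice(cfg.targets, size=cfg.n_eyes)
    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_eyes) if cfg.noise_sd > 0 \
        else np.zeros(cfg.n_eyes)
    n_unknown = int(round(cfg.unknown_model_fraction * cfg.n_eyes))
    unknown_idx = set(rng.choice(cfg.n_eyes, size=n_unknown, replace=False)) \
        if n_unknown else set()

    records: list[EyeRecord] = []
    side_rows = []
    for i in range(cfg.n_eyes):
        model = cfg.iol_catalog[model_idx[i]]
        truth = truth_of(k[i], al[i])
        eye = EyeRecord(
            eye_id=f"S{i:04d}", al=float(al[i]), k=float(k[i]),
            a_const=model.a_constant, iol_model=model.name,
            p_iol=0.0, se_post=0.0,
        )
        p_exact = emmetropic_power(truth, eye, true_const[model.name],
                                   float(targets[i]))
        eye.p_iol = round(p_exact / cfg.power_step) * cfg.power_step
        se_noiseless = predict(truth, eye, true_const[model.name]).se_pred
        eye.se_post = se_noiseless + float(noise[i])
        if i in unknown_idx:
            eye.iol_model = "UNKNOWN"
        records.append(eye)
        side_rows.append({
            "eye_id": eye.eye_id, "truth_method": truth.value,
            "iol_model_true": model.name,
            "true_a_constant": true_const[model.name],
            "target_d": float(targets[i]), "se_noiseless_d": se_noiseless,
        })
    return records, pd.DataFrame(side_rows, columns=sidecar_cols)


def simulate_cohort(cfg: SimulationConfig) -> tuple[list[EyeRecord], pd.DataFrame]:
    """Draw one cohort under a single ground-truth method.

    Returns (records, sidecar).  Two calls with the same config are
    byte-identical; the sidecar suffices to replay every noiseless
    prediction exactly.
    """
    truth = Method(cfg.truth_model)
    if truth is Method.BARRETT_TK:
        raise ValueError("the ground-truth method must be an internal method")
    return _generate(cfg, lambda _k, _al: truth)


def truth_mixture_cohort(
    cfg: SimulationConfig,
    k_scheme: RangeScheme,
    al_scheme: RangeScheme,
    mixture: Mapping[tuple[int, int], Method],
) -> tuple[list[EyeRecord], pd.DataFrame]:
    """Cohort whose generating method differs by (K, AL) range.

    ``mixture`` maps every (K-range index, AL-range index) cell to the
    internal method that generates eyes falling in that cell; used to test
    that the range-partitioned comparison recovers the generating method.
    """
    cells = {(i, j) for i in range(k_scheme.n_ranges)
             for j in range(al_scheme.n_ranges)}
    missing = cells - set(mixture)
    if missing:
        raise ValueError(f"mixture does not cover cells {sorted(missing)}")
    for m in mixture.values():
        if Method(m) is Method.BARRETT_TK:
            raise ValueError("mixture methods must be internal")

    def truth_of(k: float, al: float) -> Method:
        return Method(mixture[(k_scheme.assign(k), al_scheme.assign(al))])

    return _generate(cfg, truth_of)


def synthetic_barrett_table(records: Sequence[EyeRecord],
                            constants: Sequence[float],
                            k_scale: float = 0.985) -> pd.DataFrame:
    """Synthetic stand-in for an externally computed Barrett True-K table.

    The true Barrett True-K algebra is unpublished, so cohorts that need an
    external-prediction table in tests and demonstrations use this surrogate:
    SRK/T evaluated at a mildly rescaled keratometry (``k_scale``) for each
    requested A-constant.  It is *not* the Barrett formula — only a
    structurally plausible external predictor with the right interface.
    """
    rows = []
    for r in records:
        for c in constants:
            se = srkt_predict_refraction(r.al, r.k * k_scale,
                                         convert_constant(c, "srkt_acd"), r.p_iol)
            rows.append({"eye_id": r.eye_id, "method": Method.BARRETT_TK.value,
                         "constant": float(c), "predicted_se_d": se})
    return pd.DataFrame(rows, columns=["eye_id", "method", "constant",
                                       "predicted_se_d"])
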