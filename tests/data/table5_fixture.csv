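kind,mode,k_range,al_range,value
grid,manufacturer_constants,0,0,BARRETT_TK
grid,manufacturer_constants,0,1,BARRETT_TK
grid,manufacturer_constants,0,2,BARRETT_TK
grid,manufacturer_constants,0,3,BARRETT_TK
grid,manufacturer_constants,1,0,ALMA
grid,manufacturer_constants,1,1,ALMA+BARRETT_TK
grid,manufacturer_constants,1,2,ALMA+BARRETT_TK
grid,manufacturer_constants,1,3,BARRETT_TK
grid,manufacturer_constants,2,0,ALMA
grid,manufacturer_constants,2,1,ALMA
grid,manufacturer_constants,2,2,ALMA
grid,manufacturer_constants,2,3,ALMA+BARRETT_TK
grid,manufacturer_constants,3,0,ALMA
grid,manufacturer_constants,3,1,ALMA
grid,manufacturer_constants,3,2,ALMA
grid,manufacturer_constants,3,3,ALMA+BARRETT_TK
grid,optimized_constants,0,0,BARRETT_TK
grid,optimized_constants,0,1,ALMA+BARRETT_TK
grid,optimized_constants,0,2,ALMA
grid,optimized_constants,0,3,ALMA
grid,optimized_constants,1,0,BARRETT_TK
grid,optimized_constants,1,1,ALMA+BARRETT_TK
grid,optimized_constants,1,2,ALMA
grid,optimized_constants,1,3,ALMA
grid,optimized_constants,2,0,ALMA+BARRETT_TK
grid,optimized_constants,2,1,ALMA
grid,optimized_constants,2,2,ALMA
grid,optimized_constants,2,3,ALMA+BARRETT_TK
grid,optimized_constants,3,0,BARRETT_TK
grid,optimized_constants,3,1,BARRETT_TK
grid,optimized_constants,3,2,ALMA+BARRETT_TK
grid,optimized_constants,3,3,BARRETT_TK
alk,manufacturer_constants,0,,ALMA
alk,manufacturer_constants,1,,ALMA
alk,manufacturer_constants,2,,BARRETT_TK
alk,optimized_constants,0,,BARRETT_TK
alk,optimized_constants,1,,-
alk,optimized_constants,2,,ALMA
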