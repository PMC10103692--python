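trait,condition,parameter,value
RWC,normal,sigma2_A,7.113
RWC,water_deficit,sigma2_A,14.797
Proline,normal,sigma2_A,0.003
Proline,water_deficit,sigma2_A,0.004
CAT,normal,sigma2_A,0.9
CAT,water_deficit,sigma2_A,0.61
APX,normal,sigma2_A,0.74
APX,water_deficit,sigma2_A,1.09
TC,normal,sigma2_A,0.06
TC,water_deficit,sigma2_A,0.11
RWC,normal,sigma2_D,38.497
RWC,water_deficit,sigma2_D,45.153
Proline,normal,sigma2_D,0.009
Proline,water_deficit,sigma2_D,0.014
CAT,normal,sigma2_D,2.78
CAT,water_deficit,sigma2_D,2.25
APX,normal,sigma2_D,3.55
APX,water_deficit,sigma2_D,4.63
TC,normal,sigma2_D,0.27
TC,water_deficit,sigma2_D,0.37
RWC,normal,sigma2_E,2.611
RWC,water_deficit,sigma2_E,1.707
Proline,normal,sigma2_E,0.003
Proline,water_deficit,sigma2_E,0.002
CAT,normal,sigma2_E,0.04
CAT,water_deficit,sigma2_E,0.03
APX,normal,sigma2_E,0.09
APX,water_deficit,sigma2_E,0.07
TC,normal,sigma2_E,0.01
TC,water_deficit,sigma2_E,0.01
RWC,normal,h2_broad,94.58
RWC,water_deficit,h2_broad,97.23
Proline,normal,h2_broad,77.13
Proline,water_deficit,h2_broad,91.18
CAT,normal,h2_broad,99.01
CAT,water_deficit,h2_broad,98.85
APX,normal,h2_broad,98.02
APX,water_deficit,h2_broad,98.82
TC,normal,h2_broad,98.42
TC,water_deficit,h2_broad,98.93
RWC,normal,h2_narrow,14.75
RWC,water_deficit,h2_narrow,24
Proline,normal,h2_narrow,20.82
Proline,water_deficit,h2_narrow,18.45
CAT,normal,h2_narrow,24.32
CAT,water_deficit,h2_narrow,20.93
APX,normal,h2_narrow,16.99
APX,water_deficit,h2_narrow,18.85
TC,normal,h2_narrow,18.73
TC,water_deficit,h2_narrow,22.81
RWC,normal,contrib_lines,63.67
RWC,water_deficit,contrib_lines,78.24
Proline,normal,contrib_lines,70.36
Proline,water_deficit,contrib_lines,64.36
CAT,normal,contrib_lines,49.07
CAT,water_deficit,contrib_lines,43.61
APX,normal,contrib_lines,44.96
APX,water_deficit,contrib_lines,57.48
TC,normal,contrib_lines,44.9
TC,water_deficit,contrib_lines,59.97
RWC,normal,contrib_testers,8.51
RWC,water_deficit,contrib_testers,2.22
Proline,normal,contrib_testers,10.19
Proline,water_deficit,contrib_testers,12.2
CAT,normal,contrib_testers,31.42
CAT,water_deficit,contrib_testers,34.25
APX,normal,contrib_testers,29.29
APX,water_deficit,contrib_testers,18.53
TC,normal,contrib_testers,31.05
TC,water_deficit,contrib_testers,19.4
RWC,normal,contrib_lxt,27.83
RWC,water_deficit,contrib_lxt,19.54
Proline,normal,contrib_lxt,19.45
Proline,water_deficit,contrib_lxt,23.44
CAT,normal,contrib_lxt,19.51
CAT,water_deficit,contrib_lxt,22.14
APX,normal,contrib_lxt,25.74
APX,water_deficit,contrib_lxt,23.98
TC,normal,contrib_lxt,24.06
TC,water_deficit,contrib_lxt,20.63
DTH,normal,sigma2_A,5.51
DTH,water_deficit,sigma2_A,4.97
PH,normal,sigma2_A,3.67
PH,water_deficit,sigma2_A,2
GYPP,normal,sigma2_A,3.45
GYPP,water_deficit,sigma2_A,1.89
SpF,normal,sigma2_A,0.4
SpF,water_deficit,sigma2_A,0.47
GI,normal,sigma2_A,0.59
GI,water_deficit,sigma2_A,0.79
DTH,normal,sigma2_D,26.11
DTH,water_deficit,sigma2_D,26.3
PH,normal,sigma2_D,24.17
PH,water_deficit,sigma2_D,13.56
GYPP,normal,sigma2_D,17.93
GYPP,water_deficit,sigma2_D,7.99
SpF,normal,sigma2_D,2.27
SpF,water_deficit,sigma2_D,2.45
GI,normal,sigma2_D,1.21
GI,water_deficit,sigma2_D,1.69
DTH,normal,sigma2_E,2.27
DTH,water_deficit,sigma2_E,1.49
PH,normal,sigma2_E,2.36
PH,water_deficit,sigma2_E,1.64
GYPP,normal,sigma2_E,2.34
GYPP,water_deficit,sigma2_E,1.72
SpF,normal,sigma2_E,0.35
SpF,water_deficit,sigma2_E,0.35
GI,normal,sigma2_E,0.53
GI,water_deficit,sigma2_E,0.45
DTH,normal,h2_broad,93.31
DTH,water_deficit,h2_broad,95.45
PH,normal,h2_broad,92.18
PH,water_deficit,h2_broad,90.47
GYPP,normal,h2_broad,90.12
GYPP,water_deficit,h2_broad,85.2
SpF,normal,h2_broad,88.37
SpF,water_deficit,h2_broad,89.29
GI,normal,h2_broad,77.42
GI,water_deficit,h2_broad,84.64
DTH,normal,h2_narrow,16.27
DTH,water_deficit,h2_narrow,15.16
PH,normal,h2_narrow,12.15
PH,water_deficit,h2_narrow,11.65
GYPP,normal,h2_narrow,14.55
GYPP,water_deficit,h2_narrow,16.29
SpF,normal,h2_narrow,13.3
SpF,water_deficit,h2_narrow,14.48
GI,normal,h2_narrow,25.3
GI,water_deficit,h2_narrow,26.93
DTH,normal,contrib_lines,61.83
DTH,water_deficit,contrib_lines,64.77
PH,normal,contrib_lines,67.67
PH,water_deficit,contrib_lines,58.03
GYPP,normal,contrib_lines,69.06
GYPP,water_deficit,contrib_lines,70.85
SpF,normal,contrib_lines,67.24
SpF,water_deficit,contrib_lines,62.08
GI,normal,contrib_lines,70.62
GI,water_deficit,contrib_lines,77.11
DTH,normal,contrib_testers,12.23
DTH,water_deficit,contrib_testers,7.79
PH,normal,contrib_testers,1.42
PH,water_deficit,contrib_testers,10.55
GYPP,normal,contrib_testers,3.42
GYPP,water_deficit,contrib_testers,4.28
SpF,normal,contrib_testers,3.89
SpF,water_deficit,contrib_testers,10.42
GI,normal,contrib_testers,13.23
GI,water_deficit,contrib_testers,6.86
DTH,normal,contrib_lxt,25.94
DTH,water_deficit,contrib_lxt,27.45
PH,normal,contrib_lxt,30.92
PH,water_deficit,contrib_lxt,31.42
GYPP,normal,contrib_lxt,27.51
GYPP,water_deficit,contrib_lxt,24.87
SpF,normal,contrib_lxt,28.87
SpF,water_deficit,contrib_lxt,27.5
GI,normal,contrib_lxt,16.15
GI,water_deficit,contrib_lxt,16.03
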