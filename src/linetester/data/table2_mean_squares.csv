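trait,condition,source,df,value
RWC,normal,genotypes,30,268.42
RWC,water_deficit,genotypes,30,357.5
Proline,normal,genotypes,30,0.07
Proline,water_deficit,genotypes,30,0.1
CAT,normal,genotypes,30,23.36
CAT,water_deficit,genotypes,30,18.33
APX,normal,genotypes,30,19.02
APX,water_deficit,genotypes,30,27.08
TC,normal,genotypes,30,1.46
TC,water_deficit,genotypes,30,2.55
RWC,normal,parents,9,289.16
RWC,water_deficit,parents,9,202.46
Proline,normal,parents,9,0.02
Proline,water_deficit,parents,9,0.06
CAT,normal,parents,9,20.32
CAT,water_deficit,parents,9,14.03
APX,normal,parents,9,7.58
APX,water_deficit,parents,9,11.91
TC,normal,parents,9,0.42
TC,water_deficit,parents,9,1.15
RWC,normal,crosses,20,254.67
RWC,water_deficit,crosses,20,421.26
Proline,normal,crosses,20,0.09
Proline,water_deficit,crosses,20,0.11
CAT,normal,crosses,20,25.74
CAT,water_deficit,crosses,20,18.41
APX,normal,crosses,20,25
APX,water_deficit,crosses,20,34.92
TC,normal,crosses,20,2
TC,water_deficit,crosses,20,3.27
RWC,normal,parents_vs_crosses,1,356.78
RWC,water_deficit,parents_vs_crosses,1,477.68
Proline,normal,parents_vs_crosses,1,0.02
Proline,water_deficit,parents_vs_crosses,1,0.12
CAT,normal,parents_vs_crosses,1,3.05
CAT,water_deficit,parents_vs_crosses,1,55.52
APX,normal,parents_vs_crosses,1,2.52
APX,water_deficit,parents_vs_crosses,1,6.79
TC,normal,parents_vs_crosses,1,0.01
TC,water_deficit,parents_vs_crosses,1,0.55
RWC,normal,lines,6,540.49
RWC,water_deficit,lines,6,1098.66
Proline,normal,lines,6,0.21
Proline,water_deficit,lines,6,0.24
CAT,normal,lines,6,42.1
CAT,water_deficit,lines,6,26.76
APX,normal,lines,6,37.47
APX,water_deficit,lines,6,66.91
TC,normal,lines,6,2.99
TC,water_deficit,lines,6,6.54
RWC,normal,testers,2,216.62
RWC,water_deficit,testers,2,93.64
Proline,normal,testers,2,0.09
Proline,water_deficit,testers,2,0.14
CAT,normal,testers,2,80.85
CAT,water_deficit,testers,2,63.06
APX,normal,testers,2,73.23
APX,water_deficit,testers,2,64.72
TC,normal,testers,2,6.21
TC,water_deficit,testers,2,6.35
RWC,normal,lines_x_testers,12,118.1
RWC,water_deficit,lines_x_testers,12,137.17
Proline,normal,lines_x_testers,12,0.03
Proline,water_deficit,lines_x_testers,12,0.04
CAT,normal,lines_x_testers,12,8.37
CAT,water_deficit,lines_x_testers,12,6.79
APX,normal,lines_x_testers,12,10.73
APX,water_deficit,lines_x_testers,12,13.96
TC,normal,lines_x_testers,12,0.8
TC,water_deficit,lines_x_testers,12,1.12
RWC,normal,error,60,2.61
RWC,water_deficit,error,60,1.71
Proline,normal,error,60,0.003
Proline,water_deficit,error,60,0.002
CAT,normal,error,60,0.04
CAT,water_deficit,error,60,0.03
APX,normal,error,60,0.09
APX,water_deficit,error,60,0.07
TC,normal,error,60,0.01
TC,water_deficit,error,60,0.01
RWC,normal,sigma2_gca,,3.56
RWC,water_deficit,sigma2_gca,,7.4
Proline,normal,sigma2_gca,,0.002
Proline,water_deficit,sigma2_gca,,0.002
CAT,normal,sigma2_gca,,0.45
CAT,water_deficit,sigma2_gca,,0.3
APX,normal,sigma2_gca,,0.37
APX,water_deficit,sigma2_gca,,0.55
TC,normal,sigma2_gca,,0.03
TC,water_deficit,sigma2_gca,,0.06
RWC,normal,sigma2_sca,,38.5
RWC,water_deficit,sigma2_sca,,45.15
Proline,normal,sigma2_sca,,0.009
Proline,water_deficit,sigma2_sca,,0.014
CAT,normal,sigma2_sca,,2.78
CAT,water_deficit,sigma2_sca,,2.25
APX,normal,sigma2_sca,,3.55
APX,water_deficit,sigma2_sca,,4.63
TC,normal,sigma2_sca,,0.27
TC,water_deficit,sigma2_sca,,0.37
RWC,normal,gca_sca_ratio,,0.09
RWC,water_deficit,gca_sca_ratio,,0.16
Proline,normal,gca_sca_ratio,,0.185
Proline,water_deficit,gca_sca_ratio,,0.127
CAT,normal,gca_sca_ratio,,0.16
CAT,water_deficit,gca_sca_ratio,,0.13
APX,normal,gca_sca_ratio,,0.1
APX,water_deficit,gca_sca_ratio,,0.12
TC,normal,gca_sca_ratio,,0.12
TC,water_deficit,gca_sca_ratio,,0.15
DTH,normal,genotypes,30,156.56
DTH,water_deficit,genotypes,30,143.52
PH,normal,genotypes,30,120.33
PH,water_deficit,genotypes,30,85.8
GYPP,normal,genotypes,30,131.47
GYPP,water_deficit,genotypes,30,63.23
SpF,normal,genotypes,30,13.99
SpF,water_deficit,genotypes,30,23.83
GI,normal,genotypes,30,14.67
GI,water_deficit,genotypes,30,21.17
DTH,normal,parents,9,105.92
DTH,water_deficit,parents,9,86.53
PH,normal,parents,9,74.74
PH,water_deficit,parents,9,100.78
GYPP,normal,parents,9,107.78
GYPP,water_deficit,parents,9,42.82
SpF,normal,parents,9,10.65
SpF,water_deficit,parents,9,39.5
GI,normal,parents,9,13.85
GI,water_deficit,parents,9,24.02
DTH,normal,crosses,20,186.39
DTH,water_deficit,crosses,20,175.75
PH,normal,crosses,20,145.3
PH,water_deficit,crosses,20,80.82
GYPP,normal,crosses,20,122.41
GYPP,water_deficit,crosses,20,61.94
SpF,normal,crosses,20,14.9
SpF,water_deficit,crosses,20,16.82
GI,normal,crosses,20,15.48
GI,water_deficit,crosses,20,20.63
DTH,normal,parents_vs_crosses,1,15.45
DTH,water_deficit,parents_vs_crosses,1,11.9
PH,normal,parents_vs_crosses,1,31.15
PH,water_deficit,parents_vs_crosses,1,50.73
GYPP,normal,parents_vs_crosses,1,525.94
GYPP,water_deficit,parents_vs_crosses,1,272.48
SpF,normal,parents_vs_crosses,1,25.62
SpF,water_deficit,parents_vs_crosses,1,22.92
GI,normal,parents_vs_crosses,1,5.9
GI,water_deficit,parents_vs_crosses,1,6.29
DTH,normal,lines,6,384.15
DTH,water_deficit,lines,6,379.42
PH,normal,lines,6,327.74
PH,water_deficit,lines,6,156.32
GYPP,normal,lines,6,281.8
GYPP,water_deficit,lines,6,146.29
SpF,normal,lines,6,33.4
SpF,water_deficit,lines,6,34.8
GI,normal,lines,6,36.43
GI,water_deficit,lines,6,53.03
DTH,normal,testers,2,228
DTH,water_deficit,testers,2,136.84
PH,normal,testers,2,20.58
PH,water_deficit,testers,2,85.25
GYPP,normal,testers,2,41.92
GYPP,water_deficit,testers,2,26.49
SpF,normal,testers,2,5.8
SpF,water_deficit,testers,2,17.52
GI,normal,testers,2,20.48
GI,water_deficit,testers,2,14.15
DTH,normal,lines_x_testers,12,80.58
DTH,water_deficit,lines_x_testers,12,80.4
PH,normal,lines_x_testers,12,74.87
PH,water_deficit,lines_x_testers,12,42.32
GYPP,normal,lines_x_testers,12,56.13
GYPP,water_deficit,lines_x_testers,12,25.68
SpF,normal,lines_x_testers,12,7.17
SpF,water_deficit,lines_x_testers,12,7.71
GI,normal,lines_x_testers,12,4.17
GI,water_deficit,lines_x_testers,12,5.51
DTH,normal,error,60,2.27
DTH,water_deficit,error,60,1.49
PH,normal,error,60,2.36
PH,water_deficit,error,60,1.64
GYPP,normal,error,60,2.34
GYPP,water_deficit,error,60,1.72
SpF,normal,error,60,0.35
SpF,water_deficit,error,60,0.35
GI,normal,error,60,0.53
GI,water_deficit,error,60,0.45
DTH,normal,sigma2_gca,,2.76
DTH,water_deficit,sigma2_gca,,2.48
PH,normal,sigma2_gca,,1.83
PH,water_deficit,sigma2_gca,,1
GYPP,normal,sigma2_gca,,1.73
GYPP,water_deficit,sigma2_gca,,0.94
SpF,normal,sigma2_gca,,0.2
SpF,water_deficit,sigma2_gca,,0.24
GI,normal,sigma2_gca,,0.29
GI,water_deficit,sigma2_gca,,0.39
DTH,normal,sigma2_sca,,26.11
DTH,water_deficit,sigma2_sca,,26.3
PH,normal,sigma2_sca,,24.17
PH,water_deficit,sigma2_sca,,13.56
GYPP,normal,sigma2_sca,,17.93
GYPP,water_deficit,sigma2_sca,,7.99
SpF,normal,sigma2_sca,,2.27
SpF,water_deficit,sigma2_sca,,2.45
GI,normal,sigma2_sca,,1.21
GI,water_deficit,sigma2_sca,,1.69
DTH,normal,gca_sca_ratio,,0.11
DTH,water_deficit,gca_sca_ratio,,0.09
PH,normal,gca_sca_ratio,,0.08
PH,water_deficit,gca_sca_ratio,,0.07
GYPP,normal,gca_sca_ratio,,0.1
GYPP,water_deficit,gca_sca_ratio,,0.12
SpF,normal,gca_sca_ratio,,0.09
SpF,water_deficit,gca_sca_ratio,,0.1
GI,normal,gca_sca_ratio,,0.24
GI,water_deficit,gca_sca_ratio,,0.23
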