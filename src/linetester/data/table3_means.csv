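genotype,role,line,tester,condition,RWC,Proline,CAT,APX,TC,DTH,PH,GYPP,SpF,GI
Puebla,line_parent,Puebla,,normal,86.2,1.52,21.23,18.98,8.52,94.9,112.17,49.35,95.53,33.08
Puebla,line_parent,Puebla,,water_deficit,73.17,2.06,25.53,22.5,7.77,89,96.67,33.81,89.83,32.81
Hispagran,line_parent,Hispagran,,normal,87.7,1.6,23.52,17.41,8.68,95.9,110.8,50.89,95.4,32.44
Hispagran,line_parent,Hispagran,,water_deficit,75.43,1.92,26.13,21.6,8.07,90,100.9,35.42,88.92,30.8
IET1444,line_parent,IET1444,,normal,65.03,1.49,20.06,16.36,7.59,103.9,118.13,39.13,91.31,27.23
IET1444,line_parent,IET1444,,water_deficit,61.03,1.66,23.93,19.16,6.48,97,108.67,34.8,85.31,24.97
WAB1573,line_parent,WAB1573,,normal,62.73,1.5,18.76,17.94,7.89,109.67,117.2,31.83,90.83,27.83
WAB1573,line_parent,WAB1573,,water_deficit,57.46,1.71,23.39,19.3,6.18,103,109.53,28.47,82.38,23.4
Giza177,line_parent,Giza177,,normal,76.35,1.45,16.16,14.44,7.9,98.9,114.33,46.83,94.43,29.6
Giza177,line_parent,Giza177,,water_deficit,61.83,1.82,19.7,16.31,6.62,90,109.17,31.23,88.39,27.69
Sakha101,line_parent,Sakha101,,normal,77.28,1.46,16.45,15.4,7.52,104.9,106,46.43,92.73,27.04
Sakha101,line_parent,Sakha101,,water_deficit,56.84,1.67,22.48,17.31,6.98,94,99.67,38.93,80.88,26.16
Sakha105,line_parent,Sakha105,,normal,82.43,1.31,17.73,14.39,7.85,93.9,107.17,42.32,93.14,29.96
Sakha105,line_parent,Sakha105,,water_deficit,73.57,1.77,20.33,18.49,6.48,88,96.4,30.28,89.09,26.38
Sakha106,tester_parent,,Sakha106,normal,79.17,1.5,19.24,17.24,7.97,95.9,109.17,43.33,94.6,30.88
Sakha106,tester_parent,,Sakha106,water_deficit,62,1.89,24.11,19.56,6.75,89,98.2,36.13,87.7,28.64
Sakha107,tester_parent,,Sakha107,normal,95.07,1.58,23.29,18.23,8.29,89.9,102.17,48.78,95.52,28.7
Sakha107,tester_parent,,Sakha107,water_deficit,80.17,1.96,25.72,21.86,7.37,84,94.17,38.23,91.71,27.55
Sakha108,tester_parent,,Sakha108,normal,79.1,1.58,17.77,15.86,8.17,99.9,112.17,50.93,96.28,31.63
Sakha108,tester_parent,,Sakha108,water_deficit,66.27,1.97,23.22,20.41,7.43,94,98.17,39.63,91.39,30.06
Puebla x Sakha106,cross,Puebla,Sakha106,normal,92.07,1.74,24,20.78,9.43,85.57,105.48,56.53,95.83,34.65
Puebla x Sakha106,cross,Puebla,Sakha106,water_deficit,84.73,2.1,26.75,25.31,8.33,80.83,90.65,42.73,88.94,32.95
Puebla x Sakha107,cross,Puebla,Sakha107,normal,97.7,1.73,22.6,20.02,9.14,84.9,101.04,60.06,95.25,32.94
Puebla x Sakha107,cross,Puebla,Sakha107,water_deficit,89.87,2.07,22.25,24.49,8.64,78.83,86.7,47.24,90.59,31.99
Puebla x Sakha108,cross,Puebla,Sakha108,normal,70.07,1.52,18.1,17,7.99,96.9,116.71,53.49,91.23,32.4
Puebla x Sakha108,cross,Puebla,Sakha108,water_deficit,75.78,1.9,19.65,20.18,6.43,89.83,98.57,41.64,87.89,31.42
Hispagran x Sakha106,cross,Hispagran,Sakha106,normal,93.63,1.76,24.2,22.14,9.03,91.9,101.4,55.79,96.35,34.3
Hispagran x Sakha106,cross,Hispagran,Sakha106,water_deficit,86.2,2.01,26.92,26.18,8.42,79.83,94.69,40.48,90.66,32.87
Hispagran x Sakha107,cross,Hispagran,Sakha107,normal,90.51,1.48,20.1,14.28,7.87,94.9,111.23,52.03,93.51,30.49
Hispagran x Sakha107,cross,Hispagran,Sakha107,water_deficit,67.64,1.84,22.3,18.97,6.83,87.83,103.72,40.59,89.78,28.91
Hispagran x Sakha108,cross,Hispagran,Sakha108,normal,96.6,1.77,22.1,20.49,8.48,91.57,101.91,56.36,95.76,33.8
Hispagran x Sakha108,cross,Hispagran,Sakha108,water_deficit,91.69,2.03,24.61,27.09,7.78,83.83,93.86,43.78,94.06,32.01
IET1444 x Sakha106,cross,IET1444,Sakha106,normal,72.64,1.42,17.64,18.24,7.89,98.57,127.67,43.53,88.3,29.6
IET1444 x Sakha106,cross,IET1444,Sakha106,water_deficit,64.35,1.87,21.8,20.67,6.93,94.83,99.65,34.17,86,27
IET1444 x Sakha107,cross,IET1444,Sakha107,normal,80.88,1.45,18.94,17.97,8.3,102.23,124.47,34.73,91,26.5
IET1444 x Sakha107,cross,IET1444,Sakha107,water_deficit,65.72,1.53,19.5,19.9,7.71,99.13,97.14,29.7,86.33,23
IET1444 x Sakha108,cross,IET1444,Sakha108,normal,72.9,1.44,17.75,13.78,7.22,96.9,119.57,50.43,89.33,29.1
IET1444 x Sakha108,cross,IET1444,Sakha108,water_deficit,66.19,1.62,20.13,16.36,6.43,93.77,102.9,37.17,88.39,27.67
WAB1573 x Sakha106,cross,WAB1573,Sakha106,normal,75,1.52,17.31,19.59,8.43,103.33,114.67,37.63,92.9,29.3
WAB1573 x Sakha106,cross,WAB1573,Sakha106,water_deficit,63.2,1.82,21.86,22.15,6.74,96.83,106.26,33.17,88,27
WAB1573 x Sakha107,cross,WAB1573,Sakha107,normal,79.73,1.46,19.1,19.11,8.45,110.23,114.47,47.03,91.96,26.4
WAB1573 x Sakha107,cross,WAB1573,Sakha107,water_deficit,64.57,1.56,21.23,22.2,6.93,98.83,103.42,37.17,88.57,24.67
WAB1573 x Sakha108,cross,WAB1573,Sakha108,normal,81,1.3,12.99,17.96,6.63,116.9,113.63,45.13,92.09,31
WAB1573 x Sakha108,cross,WAB1573,Sakha108,water_deficit,72.33,1.5,17.98,20.22,5.95,108.83,105.47,35.17,88.02,27
Giza177 x Sakha106,cross,Giza177,Sakha106,normal,89.6,1.37,19.95,18.38,8.18,95.9,114.08,49.79,92.66,30.65
Giza177 x Sakha106,cross,Giza177,Sakha106,water_deficit,77.78,1.71,23.4,20.94,7.63,90.83,99.23,34.68,89.63,28.74
Giza177 x Sakha107,cross,Giza177,Sakha107,normal,96.4,1.15,21.72,14.02,9.35,90.23,103.69,57.56,96.65,31.06
Giza177 x Sakha107,cross,Giza177,Sakha107,water_deficit,87.03,1.98,24.8,17.82,8.33,79.83,93.58,43.46,93.31,28.68
Giza177 x Sakha108,cross,Giza177,Sakha108,normal,89.89,1.2,15.94,14.57,7.54,108.9,113.67,54.27,94.34,30.65
Giza177 x Sakha108,cross,Giza177,Sakha108,water_deficit,87.17,1.61,20.42,16.81,6.05,97.83,103.82,38.89,89.67,28.33
Sakha101 x Sakha106,cross,Sakha101,Sakha106,normal,79.06,1.6,20.28,17.31,8.3,96.9,112.1,47.77,92.85,29.36
Sakha101 x Sakha106,cross,Sakha101,Sakha106,water_deficit,60.25,1.79,22.4,19.69,6.03,90.83,103.09,38.04,85.6,27.11
Sakha101 x Sakha107,cross,Sakha101,Sakha107,normal,75.04,1.44,19.74,12.33,7.87,99.57,108.82,50.19,91.64,27.76
Sakha101 x Sakha107,cross,Sakha101,Sakha107,water_deficit,54.87,1.65,22.19,16.03,6.35,94.83,100.99,42.61,86.54,26.21
Sakha101 x Sakha108,cross,Sakha101,Sakha108,normal,68.19,1.37,16.45,14.31,6.92,98.9,113.73,52.52,92.24,29.35
Sakha101 x Sakha108,cross,Sakha101,Sakha108,water_deficit,62.97,1.74,20.08,16.24,5.48,92.83,103.09,42.22,87.32,28.06
Sakha105 x Sakha106,cross,Sakha105,Sakha106,normal,79.85,1.41,19.1,17.5,7.28,99.9,110.69,46.8,91.84,28.89
Sakha105 x Sakha106,cross,Sakha105,Sakha106,water_deficit,55,1.71,21.9,20.83,5.55,94.83,101.17,36.37,84.13,26.17
Sakha105 x Sakha107,cross,Sakha105,Sakha107,normal,85.86,1.45,17.52,12.92,7.13,89.9,114.13,48.33,93.23,29.5
Sakha105 x Sakha107,cross,Sakha105,Sakha107,water_deficit,64.53,1.56,19.79,16.05,5.82,85.83,98.65,33.86,89,28.73
Sakha105 x Sakha108,cross,Sakha105,Sakha108,normal,82.57,1.31,14.1,13.89,6.96,101.9,112.4,45.24,91,30.19
Sakha105 x Sakha108,cross,Sakha105,Sakha108,water_deficit,62.23,1.52,17.92,16.73,5.39,90.83,104.41,32.39,88.61,27.93
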