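trial,outcome,timepoint,level,n,mean_or_prop,icc
HERNIA,EQ-5D,1 wk,centre,610,0.71,0.029
HERNIA,EQ-5D,1 wk,surgeon,610,0.71,0.023
HERNIA,EQ-5D,3 m,centre,497,0.86,0
HERNIA,EQ-5D,3 m,surgeon,497,0.86,0
KATMETAL,EQ-5D,3 m,centre,361,0.66,0
KATMETAL,EQ-5D,3 m,surgeon,361,0.66,0.014
KATMOBILE,EQ-5D,3 m,centre,448,0.66,0.06
KATMOBILE,EQ-5D,3 m,surgeon,448,0.66,0.071
KATPATELLA,EQ-5D,3 m,centre,1169,0.70,0.008
KATPATELLA,EQ-5D,3 m,surgeon,1169,0.70,0.005
REFLUX,EQ-5D,3 m,centre,149,0.79,0.001
REFLUX,EQ-5D,3 m,surgeon,104,0.82,0.001
STARS,EQ-5D,4 m,centre,277,0.61,0
STARS,EQ-5D,4 m,surgeon,277,0.61,0.015
KATMETAL,EQ-5D,12 m,centre,354,0.71,0.006
KATMETAL,EQ-5D,12 m,surgeon,354,0.71,0
KATMOBILE,EQ-5D,12 m,centre,448,0.70,0.040
KATMOBILE,EQ-5D,12 m,surgeon,448,0.70,0.024
KATPATELLA,EQ-5D,12 m,centre,1157,0.74,0.017
KATPATELLA,EQ-5D,12 m,surgeon,1157,0.74,0.040
REFLUX,EQ-5D,12 m,centre,152,0.75,0.007
REFLUX,EQ-5D,12 m,surgeon,100,0.78,0.002
STARS,EQ-5D,12 m,centre,274,0.63,0
STARS,EQ-5D,12 m,surgeon,274,0.63,0
KATMETAL,EQ-5D,60 m,centre,302,0.68,0
KATMETAL,EQ-5D,60 m,surgeon,302,0.68,0
KATMOBILE,EQ-5D,60 m,centre,381,0.69,0.015
KATMOBILE,EQ-5D,60 m,surgeon,381,0.69,0.019
KATPATELLA,EQ-5D,60 m,centre,997,0.71,0.002
KATPATELLA,EQ-5D,60 m,surgeon,997,0.71,0.009
KATMETAL,Oxford knee score,3 m,centre,327,30.14,0
KATMETAL,Oxford knee score,3 m,surgeon,327,30.14,0.007
KATMOBILE,Oxford knee score,3 m,centre,389,29.88,0.073
KATMOBILE,Oxford knee score,3 m,surgeon,389,29.88,0.068
KATPATELLA,Oxford knee score,3 m,centre,1057,30.89,0.041
KATPATELLA,Oxford knee score,3 m,surgeon,1057,30.89,0.05
KATMETAL,Oxford knee score,12 m,centre,311,33.71,0.021
KATMETAL,Oxford knee score,12 m,surgeon,311,33.71,0.056
KATMOBILE,Oxford knee score,12 m,centre,387,32.99,0.063
KATMOBILE,Oxford knee score,12 m,surgeon,387,32.99,0.059
KATPATELLA,Oxford knee score,12 m,centre,1010,34.73,0.027
KATPATELLA,Oxford knee score,12 m,surgeon,1010,34.73,0.047
KATMETAL,Oxford knee score,60 m,centre,284,34.14,0
KATMETAL,Oxford knee score,60 m,surgeon,284,34.14,0.002
KATMOBILE,Oxford knee score,60 m,centre,350,33.43,0.044
KATMOBILE,Oxford knee score,60 m,surgeon,350,33.43,0.051
KATPATELLA,Oxford knee score,60 m,centre,928,34.90,0.045
KATPATELLA,Oxford knee score,60 m,surgeon,928,34.90,0.037
CLIVIT,Operating time (min),,centre,483,118.60,0.184
CLIVIT,Operating time (min),,surgeon,479,118.93,0.392
DISPACT,Operating time (min),,centre,344,190.03,0.268
DISPACT,Operating time (min),,surgeon,344,190.03,0.395
FILMS,Operating time (min),,centre,125,67.55,0.212
INSECT,Closure time (min),,centre,580,15.02,0.331
INSECT,Closure time (min),,surgeon,579,15.03,0.466
KATMETAL,Operating time (min),,centre,398,106.70,0.449
KATMETAL,Operating time (min),,surgeon,398,106.70,0.514
KATMOBILE,Operating time (min),,centre,503,122.37,0.167
KATMOBILE,Operating time (min),,surgeon,503,122.37,0.199
KATPATELLA,Operating time (min),,centre,1302,126.75,0.370
KATPATELLA,Operating time (min),,surgeon,1302,126.75,0.445
REFLUX,Operating time (min),,centre,108,112.81,0.375
REFLUX,Operating time (min),,surgeon,104,113.16,0.375
STARS,Operating time (min),,centre,298,62.40,0.072
STARS,Operating time (min),,surgeon,298,62.40,0.093
CLIVIT,Length of stay (days),,centre,488,3.05,0.065
CLIVIT,Length of stay (days),,surgeon,485,3.05,0
DISPACT,Length of stay (days),,centre,348,15.41,0.111
DISPACT,Length of stay (days),,surgeon,348,15.41,0.045
INSECT,Length of stay (days),,centre,589,14.59,0.012
INSECT,Length of stay (days),,surgeon,588,14.59,0
REFLUX,Length of stay (days),,centre,108,2.38,0.345
REFLUX,Length of stay (days),,surgeon,104,2.38,0.345
STARS,Length of stay (days),,centre,298,12.26,0.104
STARS,Length of stay (days),,surgeon,298,12.26,0.104
DISPACT,Fistula,,centre,352,0.29,0.122
DISPACT,Fistula,,surgeon,352,0.29,0.084
FILMS,Complication,6 m,centre,126,0.38,0
HERNIA,Complication,1 wk,centre,717,0.37,0
HERNIA,Complication,1 wk,surgeon,717,0.37,0.009
INSECT,Wound infection,,centre,625,0.16,0.01
INSECT,Wound infection,,surgeon,610,0.16,0.072
STARS,HRQ overall score,4 m,centre,276,68.85,0.058
STARS,HRQ overall score,4 m,surgeon,276,68.85,0.114
STARS,HRQ overall score,12 m,centre,258,74.04,0
STARS,HRQ overall score,12 m,surgeon,258,74.04,0
STARS,HRQ overall score,24 m,centre,236,75.37,0
STARS,HRQ overall score,24 m,surgeon,236,75.37,0
REFLUX,RQLS score,3 m,centre,141,83.85,0.143
REFLUX,RQLS score,3 m,surgeon,100,86.34,0.143
REFLUX,RQLS score,12 m,centre,145,84.58,0.058
REFLUX,RQLS score,12 m,surgeon,94,89.10,0
FILMS,Distance visual acuity (ETDRS),6 m,centre,127,60.24,0.175
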