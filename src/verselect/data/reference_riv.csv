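variable,RF,MARS,Lasso,XGBoost,CatBoost,LightGBM
BF(C),24.00,1.41,0.22,9.22,10.43,3.78
BF(M),23.37,13.20,0.00,9.30,14.07,0.43
BF(S),9.36,1.12,0.00,2.88,12.38,0.00
BF(D),12.09,6.95,0.00,10.31,17.16,1.40
BMI(C),10.92,0.00,0.00,1.92,2.34,0.02
BMI(M),8.10,3.70,0.00,1.08,8.57,0.11
BMI(S),9.58,8.35,0.00,1.81,16.79,0.12
BMI(D),15.97,0.00,0.00,8.56,10.91,0.31
BUN(C),22.97,24.22,0.00,3.04,17.98,2.38
BUN(M),56.80,48.17,10.73,40.22,46.50,11.82
BUN(S),99.03,100.00,53.95,100.00,94.22,100.00
BUN(D),17.44,31.61,0.00,4.85,6.83,0.66
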