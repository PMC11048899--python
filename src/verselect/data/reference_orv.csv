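variable,RF,MARS,Lasso,XGBoost,CatBoost,LightGBM
BF(C),18,70,70,25,39,34
BF(M),23,62,76,16,34,42
BF(S),51,70,76,46,41,71
BF(D),37,64,76,18,41,38
BMI(C),43,76,76,50,62,67
BMI(M),57,70,76,61,48,66
BMI(S),44,64,76,53,21,64
BMI(D),29,76,76,25,40,60
BUN(C),10,37,76,48,34,50
BUN(M),2,26,4,3,6,11
BUN(S),2,1,3,1,2,1
BUN(D),21,36,76,32,43,47
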