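variable,RIV-AMA,RIV-GMA,RIV-MA,ORV-AMA,ORV-RMA,ORV-BCA
BF(C),8.18,3.73,24.00,42.67,36.50,70
BF(M),10.06,0.00,23.37,42.17,38.00,76
BF(S),4.29,0.00,12.38,59.17,60.50,76
BF(D),7.98,0.00,17.16,45.67,39.50,76
BMI(C),2.53,0.00,10.92,62.33,64.50,76
BMI(M),3.59,0.00,8.57,63.00,63.50,76
BMI(S),6.11,0.00,16.79,53.67,58.50,76
BMI(D),5.96,0.00,15.97,51.00,50.00,76
BUN(C),11.76,0.00,24.22,42.50,42.50,76
BUN(M),35.71,29.42,56.80,8.67,5.00,26
BUN(S),91.20,89.19,100.00,1.67,1.50,1
BUN(D),10.23,0.00,31.61,42.50,39.50,76
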