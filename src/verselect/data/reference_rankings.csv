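rank,RIV-AMA,RIV-GMA,RIV-MA,ORV-AMA,ORV-RMA,ORV-BCA
1,BUN(S),BUN(S),BUN(S),BUN(S),BUN(S),BUN(S)
2,BUN(M),BUN(M),Hb(S),BUN(M),BUN(M),BUN(M)
3,Hb(S),Hb(S),BUN(M),Hb(S),Hb(S),LDL(M)
4,RBC(S),RBC(S),r-GT(M),RBC(S),FPG(D),HDL(S)
5,r-GT(M),RBC(M),RBC(S),FPG(D),RBC(S),TG(S)
6,HDL(S),UA(S),HDL(S),HDL(S),HDL(S),HC(S)
7,BUN(C),SBP(S),r-GT(D),RBC(M),RBC(M),UA(S)
8,RBC(M),FPG(D),BUN(D),SBP(S),Hb(M),BMI(S)
9,r-GT(D),BF(C),RBC(M),r-GT(M),SBP(M),DBP(D)
10,LDL(D),SBP(C),WC(C),SBP(M),BF(C),Hb(M)
11,FPG(D),Hb(M),LDL(D),Hb(M),UA(S),SGOT(D)
12,BUN(D),DBP(S),RBC(C),BF(M),BF(M),BF(C)
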