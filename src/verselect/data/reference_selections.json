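{
  "RIV": {
    "4": ["BUN(S)", "BUN(M)", "Hb(S)", "RBC(S)", "r-GT(M)"],
    "6": ["BUN(S)", "BUN(M)", "Hb(S)", "RBC(S)", "r-GT(M)", "RBC(M)", "HDL(S)", "UA(S)"],
    "8": ["BUN(S)", "BUN(M)", "Hb(S)", "RBC(S)", "r-GT(M)", "RBC(M)", "HDL(S)", "UA(S)", "BUN(C)", "SBP(S)", "r-GT(D)", "FPG(D)", "BUN(D)"],
    "10": ["BUN(S)", "BUN(M)", "Hb(S)", "RBC(S)", "r-GT(M)", "RBC(M)", "HDL(S)", "UA(S)", "BUN(C)", "SBP(S)", "r-GT(D)", "FPG(D)", "BUN(D)", "BF(C)", "LDL(D)", "SBP(C)", "WC(C)"],
    "12": ["BUN(S)", "BUN(M)", "Hb(S)", "RBC(S)", "r-GT(M)", "RBC(M)", "HDL(S)", "UA(S)", "BUN(C)", "SBP(S)", "r-GT(D)", "FPG(D)", "BUN(D)", "BF(C)", "LDL(D)", "SBP(C)", "WC(C)", "Hb(M)", "DBP(S)", "RBC(C)"]
  },
  "ORV": {
    "4": ["BUN(S)", "BUN(M)", "Hb(S)", "LDL(M)", "RBC(S)", "FPG(D)", "HDL(S)"],
    "6": ["BUN(S)", "BUN(M)", "Hb(S)", "LDL(M)", "RBC(S)", "FPG(D)", "HDL(S)", "TG(S)", "HC(S)"],
    "8": ["BUN(S)", "BUN(M)", "Hb(S)", "LDL(M)", "RBC(S)", "FPG(D)", "HDL(S)", "TG(S)", "HC(S)", "RBC(M)", "UA(S)", "SBP(S)", "Hb(M)", "BMI(S)"],
    "10": ["BUN(S)", "BUN(M)", "Hb(S)", "LDL(M)", "RBC(S)", "FPG(D)", "HDL(S)", "TG(S)", "HC(S)", "RBC(M)", "UA(S)", "SBP(S)", "Hb(M)", "BMI(S)", "r-GT(M)", "SBP(M)", "DBP(D)", "BF(C)"],
    "12": ["BUN(S)", "BUN(M)", "Hb(S)", "LDL(M)", "RBC(S)", "FPG(D)", "HDL(S)", "TG(S)", "HC(S)", "RBC(M)", "UA(S)", "SBP(S)", "Hb(M)", "BMI(S)", "r-GT(M)", "SBP(M)", "DBP(D)", "BF(C)", "SGOT(D)", "BF(M)"]
  }
}
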