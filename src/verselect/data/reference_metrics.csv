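model,BA,BA_sd,SEN,SEN_sd,SPE,SPE_sd,AUC,AUC_sd
LGR,0.704,0.09,0.656,0.32,0.752,0.19,0.669,0.10
RF,0.798,0.04,0.699,0.12,0.898,0.15,0.797,0.04
MARS,0.766,0.04,0.752,0.09,0.780,0.12,0.717,0.07
Lasso,0.813,0.05,0.769,0.06,0.856,0.12,0.800,0.08
XGBoost,0.769,0.05,0.741,0.13,0.797,0.18,0.763,0.06
CatBoost,0.763,0.06,0.777,0.16,0.750,0.14,0.708,0.07
LightGBM,0.780,0.10,0.791,0.15,0.770,0.17,0.781,0.12
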