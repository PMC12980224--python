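solute,alcohol,S0,S1,r2,rmsd,source
trans-polydatin,methanol,7.7174,-0.3212,0.985,0.059,fitted-study
p-coumaric acid,methanol,4.2020,-0.5472,0.978,0.041,fitted-study
quercetin,methanol,5.5012,0.8215,0.943,0.108,fitted-study
trans-resveratrol,methanol,4.6619,-0.0721,0.990,0.023,fitted-study
trans-polydatin,ethanol,8.7259,-1.2030,0.990,0.060,fitted-study
p-coumaric acid,ethanol,4.3500,-1.2294,0.994,0.044,fitted-study
quercetin,ethanol,5.4090,-0.9581,0.984,0.058,fitted-study
trans-resveratrol,ethanol,4.3347,-1.0773,0.984,0.044,fitted-study
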