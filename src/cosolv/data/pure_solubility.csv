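solute,solvent,x_1e5,source
trans-polydatin,methanol,859.7,literature-prior
trans-polydatin,ethanol,271.5,measured-298K
trans-polydatin,ethyl acetate,6.732,literature-prior
p-coumaric acid,methanol,2754,measured-298K
p-coumaric acid,ethanol,3352,measured-298K
p-coumaric acid,ethyl acetate,968.5,measured-298K
quercetin,methanol,143.8,literature-prior
quercetin,ethanol,601.9,measured-298K
quercetin,ethyl acetate,223.0,literature-prior
trans-resveratrol,methanol,1890,literature-prior
trans-resveratrol,ethanol,2583,measured-298K
trans-resveratrol,ethyl acetate,895.0,literature-prior
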