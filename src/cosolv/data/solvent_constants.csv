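name,molar_mass,density_298K,source
water,18.015,0.99705,literature
methanol,32.04,0.7866,literature
ethanol,46.07,0.7849,literature
ethyl acetate,88.11,0.894,literature
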