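solute,E,S,A,B,V,source
p-coumaric acid,1.14,1.49,1.28,0.67,1.2292,synthetic-estimate
quercetin,2.50,2.30,1.90,1.30,1.9632,synthetic-estimate
trans-resveratrol,2.00,2.00,1.40,1.10,1.7388,synthetic-estimate
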