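solute,x,source
p-coumaric acid,2.376e-6,measured-298K
quercetin,6.279e-5,measured-298K
trans-resveratrol,4.701e-6,measured-298K
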