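solvent,c,e,s,a,b,v,source
methanol,0.276,0.334,-0.714,0.243,-3.320,3.842,literature-dry
ethanol,0.222,0.471,-1.035,0.326,-3.596,3.857,literature-dry
ethyl acetate,0.328,0.369,-0.446,-0.700,-4.904,4.150,literature-dry
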