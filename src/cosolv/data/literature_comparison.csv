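solute,solvent,x_1e5,ref,source
p-coumaric acid,methanol,2754,this-work,measured-298K
p-coumaric acid,methanol,3950,ji,literature
p-coumaric acid,methanol,4269,vilas-boas,literature
p-coumaric acid,ethanol,3352,this-work,measured-298K
p-coumaric acid,ethanol,4560,ji,literature
p-coumaric acid,ethanol,5006,vilas-boas,literature
p-coumaric acid,ethanol,4612,noubigh,literature
p-coumaric acid,ethyl acetate,968.5,this-work,measured-298K
p-coumaric acid,ethyl acetate,1280,ji,literature
p-coumaric acid,ethyl acetate,1046,vilas-boas,literature
p-coumaric acid,ethyl acetate,1293,noubigh,literature
quercetin,ethanol,601.9,this-work,measured-298K
quercetin,ethanol,153.0,razmara,literature
quercetin,ethanol,250.5,malwade,literature
trans-resveratrol,ethanol,2583,this-work,measured-298K
trans-resveratrol,ethanol,1660,ghazwani,literature
trans-resveratrol,ethanol,1690,sun,literature
trans-resveratrol,ethanol,2480,ha,literature
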