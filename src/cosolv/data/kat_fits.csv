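mixture,solute,family,term,coefficient,rmsd,source
ethanol+ethyl acetate,p-coumaric acid,beta^2+dh2^2,intercept,-0.328,0.189,fitted-study
ethanol+ethyl acetate,p-coumaric acid,beta^2+dh2^2,beta^2,4.483,0.189,fitted-study
ethanol+ethyl acetate,p-coumaric acid,beta^2+dh2^2,dh2^2,-3.842,0.189,fitted-study
ethanol+ethyl acetate,trans-resveratrol,beta^2+dh2^2,intercept,-0.265,0.087,fitted-study
ethanol+ethyl acetate,trans-resveratrol,beta^2+dh2^2,beta^2,3.664,0.087,fitted-study
ethanol+ethyl acetate,trans-resveratrol,beta^2+dh2^2,dh2^2,-3.148,0.087,fitted-study
ethanol+ethyl acetate,quercetin,beta^2+dh2^2,intercept,-0.092,0.035,fitted-study
ethanol+ethyl acetate,quercetin,beta^2+dh2^2,beta^2,1.261,0.035,fitted-study
ethanol+ethyl acetate,quercetin,beta^2+dh2^2,dh2^2,-1.088,0.035,fitted-study
ethanol+ethyl acetate,trans-polydatin,beta^2+dh2^2,intercept,-0.033,0.060,fitted-study
ethanol+ethyl acetate,trans-polydatin,beta^2+dh2^2,beta^2,0.424,0.060,fitted-study
ethanol+ethyl acetate,trans-polydatin,beta^2+dh2^2,dh2^2,-0.358,0.060,fitted-study
ethanol+ethyl acetate,trans-polydatin,beta+dh2^2,intercept,-0.049,0.049,fitted-study
ethanol+ethyl acetate,trans-polydatin,beta+dh2^2,beta,0.136,0.049,fitted-study
ethanol+ethyl acetate,trans-polydatin,beta+dh2^2,dh2^2,-0.089,0.049,fitted-study
ethanol+ethyl acetate,trans-polydatin,alpha+dh2^2,intercept,-0.014,0.042,fitted-study
ethanol+ethyl acetate,trans-polydatin,alpha+dh2^2,alpha,0.052,0.042,fitted-study
ethanol+ethyl acetate,trans-polydatin,alpha+dh2^2,dh2^2,-0.098,0.042,fitted-study
methanol+ethyl acetate,p-coumaric acid,alpha+alpha^2+dh2^2,intercept,1.172,0.127,fitted-study
methanol+ethyl acetate,p-coumaric acid,alpha+alpha^2+dh2^2,alpha,3.231,0.127,fitted-study
methanol+ethyl acetate,p-coumaric acid,alpha+alpha^2+dh2^2,alpha^2,1.863,0.127,fitted-study
methanol+ethyl acetate,p-coumaric acid,alpha+alpha^2+dh2^2,dh2^2,-7.891,0.127,fitted-study
methanol+ethyl acetate,trans-resveratrol,alpha+alpha^2+dh2^2,intercept,0.767,0.211,fitted-study
methanol+ethyl acetate,trans-resveratrol,alpha+alpha^2+dh2^2,alpha,2.123,0.211,fitted-study
methanol+ethyl acetate,trans-resveratrol,alpha+alpha^2+dh2^2,alpha^2,1.184,0.211,fitted-study
methanol+ethyl acetate,trans-resveratrol,alpha+alpha^2+dh2^2,dh2^2,-5.121,0.211,fitted-study
methanol+ethyl acetate,quercetin,alpha+alpha^2+dh2^2,intercept,0.164,0.011,fitted-study
methanol+ethyl acetate,quercetin,alpha+alpha^2+dh2^2,alpha,0.439,0.011,fitted-study
methanol+ethyl acetate,quercetin,alpha+alpha^2+dh2^2,alpha^2,0.261,0.011,fitted-study
methanol+ethyl acetate,quercetin,alpha+alpha^2+dh2^2,dh2^2,-1.089,0.011,fitted-study
methanol+ethyl acetate,trans-polydatin,alpha+dh2^2,intercept,0.010,0.111,fitted-study
methanol+ethyl acetate,trans-polydatin,alpha+dh2^2,alpha,0.065,0.111,fitted-study
methanol+ethyl acetate,trans-polydatin,alpha+dh2^2,dh2^2,-0.083,0.111,fitted-study
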