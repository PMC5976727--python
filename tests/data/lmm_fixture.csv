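fetus_id,ga_days,weight_g,log_weight
F0001,142.968751804,375.595572105,5.92851295841
F0001,171.465089131,907.354482303,6.8105332032
F0001,226.347051027,2351.96844769,7.76300789383
F0001,268.862826336,4028.38853807,8.30112170849
F0002,139.428046827,254.749979153,5.54028259027
F0002,178.51374128,706.33051397,6.56008327804
F0002,226.252606966,1687.17098657,7.43080843282
F0002,279.327820929,2867.87835968,7.96132778788
F0003,145.461938473,397.951550018,5.98633026425
F0003,177.192324073,841.620018859,6.73532862837
F0003,219.283879233,1703.90744016,7.44067938676
F0003,266.834398506,3202.2015887,8.0715938487
F0004,139.799140481,372.844600982,5.92116171348
F0004,171.483978422,824.566324596,6.71485758097
F0004,222.445160473,2181.26087526,7.68765837173
F0004,272.288597226,3382.92334482,8.12649550959
F0005,144.5336853,355.680191677,5.87403198912
F0005,176.912601433,845.047688184,6.73939306148
F0005,221.903208714,1670.49232735,7.42087366876
F0005,282.120094716,3231.84707276,8.08080910193
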