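block,agecat,agemen,ageflb,numrel,nbiops,bmi,parity,e_gail_sbsp,s_gail_sbsp,bcddp
agemen,0,0,0,0,0,0,0,1,1,1
agemen,0,1,0,0,0,0,0,1.23,1.27,1.10
agemen,0,2,0,0,0,0,0,1.50,1.61,1.21
agecat x nbiops,0,0,0,0,0,0,0,,,1
agecat x nbiops,0,0,0,0,1,0,0,,,1.70
agecat x nbiops,0,0,0,0,2,0,0,,,2.88
agecat x nbiops,1,0,0,0,0,0,0,,,1
agecat x nbiops,1,0,0,0,1,0,0,,,1.27
agecat x nbiops,1,0,0,0,2,0,0,,,1.62
ageflb x numrel,0,0,0,0,0,0,0,1,1,1
ageflb x numrel,0,0,0,1,0,0,0,2.17,2.17,2.61
ageflb x numrel,0,0,0,2,0,0,0,4.70,4.73,6.80
ageflb x numrel,0,0,1,0,0,0,0,1.19,1.20,1.24
ageflb x numrel,0,0,1,1,0,0,0,2.57,2.61,2.68
ageflb x numrel,0,0,1,2,0,0,0,5.57,5.68,5.78
ageflb x numrel,0,0,2,0,0,0,0,1.40,1.44,1.55
ageflb x numrel,0,0,2,1,0,0,0,3.05,3.14,2.76
ageflb x numrel,0,0,2,2,0,0,0,6.60,6.83,4.91
ageflb x numrel,0,0,3,0,0,0,0,1.66,1.73,1.93
ageflb x numrel,0,0,3,1,0,0,0,3.61,3.77,2.83
ageflb x numrel,0,0,3,2,0,0,0,7.82,8.20,4.17
bmi,0,0,0,0,0,0,0,1,,
bmi,0,0,0,0,0,1,0,1.46,,
bmi,0,0,0,0,0,2,0,2.14,,
parity,0,0,0,0,0,0,0,1,,
parity,0,0,0,0,0,0,1,1.23,,
parity,0,0,0,0,0,0,2,1.50,,
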