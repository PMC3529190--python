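j,upper,cauc_B,cauc_c,overall_B,overall_c,chinese_B,chinese_c,malay_B,malay_c,indian_B,indian_c
1,20,0,0,0.3,11.7,0.2,10.5,0.5,17.4,0.5,11.0
2,25,1,49.3,1.9,14.3,1.8,11.9,1.1,25.7,2.2,12.9
3,30,7.6,53.1,8.1,14.2,7.0,12.5,15.9,22.5,4.9,19.7
4,35,26.6,62.5,24.8,19.8,25.5,16.8,27.7,47.0,5.9,14.8
5,40,66.1,82.5,57.6,32.6,60.3,29.4,60.0,53.9,31.6,34.8
6,45,126.5,130.7,118.7,58.5,121.5,51.6,123.7,98.6,87.9,60.7
7,50,186.6,218.1,162.6,106.2,169.1,95.1,145.1,175.1,128.4,111.9
8,55,221.1,365.5,187.0,182.1,193.6,165.1,158.4,297.5,147.2,212.6
9,60,272.1,585.2,204.3,319.1,211.0,271.1,167.0,617.7,181.5,445.9
10,65,334.8,943.9,199.1,565.9,202.1,489.6,209.3,1093.0,157.6,853.3
11,70,392.3,1502.8,193.9,989.5,199.8,856.5,131.9,2040.3,219.5,1158.5
12,75,417.8,2383.9,166.5,1798.6,161.3,1624.3,199.1,3034.6,152.5,1932.2
13,80,443.9,3883.2,179.0,3285.3,180.9,3001.6,128.6,5678.6,197.2,3662.0
14,85,442.1,6682.8,189.8,5681.0,191.4,5388.2,188.4,8681.2,125.0,6093.8
15,90,410.9,14490.8,166.2,11425.5,164.5,11352.1,117.6,13323.5,375.0,11000.0
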