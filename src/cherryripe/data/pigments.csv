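cultivar,cover,date,chl_a,chl_b,carotenoids,flavonoids,anthocyanins
Bellise,true,2012-05-29,0.07,0.03,1.39,34.5,1.38
Bellise,true,2012-06-01,0.06,0.02,1.93,45.2,5.79
Bellise,true,2012-06-04,0.06,,0.71,41.3,27.2
Bellise,true,2012-06-08,0.01,0.02,0.02,78.8,106.5
Bellise,true,2012-06-11,0.01,,1.35,85.9,190.7
Samba,true,2012-05-29,0.26,0.03,2.08,153,7.43
Samba,true,2012-06-01,0.33,0.10,2.27,162,11.96
Samba,true,2012-06-04,1.14,1.7,5.42,208,7.97
Samba,true,2012-06-08,0.06,0.03,1.42,154,11.1
Samba,true,2012-06-11,0.15,0.33,0.72,193,45.3
Samba,true,2012-06-15,0.03,0.11,0.16,198,69.6
Samba,true,2012-06-18,0.00,,1.35,234,106.6
Bellise,false,2012-05-29,3.53,2.16,5.08,92.2,5.58
Bellise,false,2012-06-01,0.02,0.07,0.06,94.4,7.27
Bellise,false,2012-06-04,0.00,,0.00,33.7,3.65
Bellise,false,2012-06-08,0.20,0.03,3.10,70.6,14.33
Bellise,false,2012-06-11,0.07,0.02,1.67,51.5,4.46
Bellise,false,2012-06-15,,,0.56,45.8,13.07
Bellise,false,2012-06-18,,,,53.49,11.28
Bellise,false,2012-06-22,,,,86.4,30.3
Bellise,false,2012-06-25,,,1.14,84.7,114.3
Samba,false,2012-05-29,0.01,0.01,0.01,188,9.47
Samba,false,2012-06-01,0.00,,0.00,242,6.16
Samba,false,2012-06-04,0.05,,0.07,255,5.50
Samba,false,2012-06-08,0.25,0.05,1.99,175,5.18
Samba,false,2012-06-11,,,0.05,171,4.78
Samba,false,2012-06-15,0.12,0.25,1.18,178,15.6
Samba,false,2012-06-18,0.02,,1.45,176,36.9
Samba,false,2012-06-22,0.05,0.07,1.43,169,31.3
Samba,false,2012-06-25,,,,215,172.8
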