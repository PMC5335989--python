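cultivar,cover,date,fruit_size_mm,fruit_size_sd,fruit_weight_g,fruit_weight_sd,firmness_shore_a,firmness_sd,firmness_at_ceiling
Bellise,true,2012-05-29,22.0,1.0,5.6,0.6,64.8,14.8,false
Bellise,true,2012-06-01,23.5,1.8,6.1,1.2,65.9,24.2,false
Bellise,true,2012-06-04,22.9,2.3,6.3,1.7,66.0,25.7,false
Bellise,true,2012-06-08,24.7,2.0,7.5,1.6,52.7,14.9,false
Bellise,true,2012-06-11,25.6,1.7,8.4,1.5,54.9,21.3,false
Samba,true,2012-05-29,19.7,0.7,4.8,0.4,86.7,11.7,false
Samba,true,2012-06-01,21.6,1.2,5.6,0.8,53.1,28.8,false
Samba,true,2012-06-04,23.0,1.6,6.6,1.2,77.9,15.7,false
Samba,true,2012-06-08,23.8,1.6,7.6,1.2,62.5,18.6,false
Samba,true,2012-06-11,24.8,1.6,8.2,1.3,69.3,12.9,false
Samba,true,2012-06-15,25.8,1.3,9.6,1.2,75.8,11.5,false
Bellise,false,2012-05-29,16.5,1.1,2.6,0.5,100,,true
Bellise,false,2012-06-01,18.5,1.1,3.2,0.5,100,,true
Bellise,false,2012-06-04,20.1,1.3,4.0,0.6,100,,true
Bellise,false,2012-06-08,20.3,1.1,4.2,0.6,100,,true
Bellise,false,2012-06-11,21.1,1.2,4.8,0.7,100,,true
Bellise,false,2012-06-15,22.6,1.1,5.9,0.8,100,,true
Bellise,false,2012-06-18,22.8,1.4,6.2,0.9,100,,true
Bellise,false,2012-06-22,23.9,1.5,7.7,1.3,75.8,11.8,false
Bellise,false,2012-06-25,24.3,1.4,7.9,1.1,70.9,12.4,false
Samba,false,2012-05-29,17.2,0.6,3.2,0.2,100,,true
Samba,false,2012-06-01,18.2,1.1,3.6,0.2,100,,true
Samba,false,2012-06-04,19.1,1.6,4.1,0.7,100,,true
Samba,false,2012-06-08,20.5,1.5,4.9,0.8,100,,true
Samba,false,2012-06-11,20.9,1.0,5.3,0.7,100,,true
Samba,false,2012-06-15,21.4,1.4,6.0,1.1,100,,true
Samba,false,2012-06-18,21.9,1.3,6.4,1.0,100,,true
Samba,false,2012-06-22,23.1,1.2,7.5,1.1,74.9,7.5,false
Samba,false,2012-06-25,24.5,1.1,8.7,1.1,70.5,8.7,false
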