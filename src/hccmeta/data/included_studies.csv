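study_id,first_author,year,n_total,n_male,n_female,n_high,n_low,method,follow_up_months,outcomes,nos_score,effect_sources
chen2012,Chen,2012,172,142,30,95,77,IHC,125,OS,,
li2016,Li,2016,72,65,7,41,31,IHC,60,DFS|OS,,
hao2014,Hao,2014,99,89,10,76,23,IHC,130,OS,,
song2014,Song,2014,300,267,33,155,145,IHC,64,OS,,
choi2011,Choi,2011,90,77,13,50,40,IHC,,none,,
jang2012,Jang,2012,154,132,22,55,99,IHC,140,DFS|OS,,
zhang2015,Zhang,2015,252,,,153,98,western_blot,125,DFS|OS,,
cheng2015,Cheng,2015,148,,,77,71,IHC,80,OS,,
liu2016,Liu,2016,148,128,20,76,72,IHC,80,OS,,
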