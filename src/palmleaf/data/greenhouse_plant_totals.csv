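plant_id,cultivar,condition,n_leaves,total_hybrid,total_photo
10,KU50,GH-I,5,0.31,0.32
11,KU50,GH-I,7,0.58,0.62
12,KU50,GH-I,8,0.72,0.79
13,HN,GH-I,20,2.90,2.70
14,HN,GH-I,20,3.09,2.87
15,HN,GH-I,18,2.74,2.59
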