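plant_id,cultivar,condition,n_leaves,n_representatives,total_photo_clustered,total_meter_clustered,total_meter_all
1,KU50,FL-I,209,13,51.93,48.73,51.03
2,KU50,FL-I,397,17,65.28,62.05,60.56
3,KU50,FL-I,198,16,23.50,22.20,21.06
4,KU50,FL-I,113,15,16.36,15.74,13.12
5,KU50,FL-I,56,9,13.77,12.59,10.82
6,R9,FL-I,377,7,62.22,56.79,35.74
7,R9,FL-I,136,12,27.27,25.75,23.92
8,R9,FL-R,208,10,64.59,60.75,60.19
9,R9,FL-R,127,12,23.09,21.89,19.39
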