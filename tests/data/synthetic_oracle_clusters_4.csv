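cluster_id,x_km,y_km,y,m
0,0.0,0.0,5,30
1,20.0,10.0,12,40
2,5.0,45.0,2,18
3,60.0,60.0,22,35
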