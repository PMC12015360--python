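cluster_id,x_km,y_km,y,m
0,0.0,0.0,3,20
1,30.0,0.0,10,25
2,0.0,50.0,1,15
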