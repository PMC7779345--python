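let_kev_um,time_point,n_star,df_c,df_xi,dabble,rbe
50,100ns,4.039473227e+17,0.9,0.2411642367,2.731896621,2.331959533
140,100ns,8.894065854e+16,0.9,0.04699602303,18.15055662,4.65826254
300,100ns,4.189493769e+16,0.9,0.02146141959,40.93571614,3.011337062
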