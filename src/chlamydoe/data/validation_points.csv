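point,acetate,light,ammonium,nitrate,co2,CR,CR_sd,MA_CYT,MA_CYT_sd,MA_ALT,MA_ALT_sd,PHIPSII800,PHIPSII800_sd,NPQ800,NPQ800_sd,P800,P800_sd
1,0.58,61,10.0,7.0,1.5,8.1,0.5,7.3,0.2,10.1,0.2,0.273,0.019,0.218,0.020,50.3,1.7
2,0.32,58,15.0,3.0,1.5,6.7,0.3,5.8,0.3,6.6,0.4,0.250,0.025,0.183,0.028,58.9,2.4
3,0.21,90,15.0,9.0,1.5,6.4,0.5,6.1,0.2,8.0,1.0,0.369,0.005,0.235,0.052,64.0,0.4
4,0.75,65,12.0,5.0,1.5,10.6,0.8,8.8,0.6,8.3,0.8,0.307,0.064,0.166,0.075,48.8,1.6
5,0.35,144,0.0,10.0,1.5,9.0,1.3,8.3,0.8,12.9,0.9,0.428,0.013,0.244,0.042,134.9,9.1
6,0.25,75,7.5,10.0,1.5,5.2,0.7,5.2,0.7,7.2,0.6,0.270,0.022,0.273,0.025,71.3,3.9
7,0.82,167,0.0,0.0,1.5,,,,,,,0.467,0.054,0.097,0.021,15.2,3.2
8,1.00,21,15.0,0.0,1.5,,,,,,,0.260,0.015,0.133,0.024,23.2,1.9
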