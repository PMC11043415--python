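source,df,plant_height,tiller_number,panicle_length,grains_per_panicle,thousand_grain_weight,paddy_yield
GEN,19,2152.1,40.96,36.58,4727,61.88,4575140
REP,2,10219,1.09,10.49,856,5.06,53350000
ENV,11,6768.5,439.73,120.76,102783,881.35,189000000
GEN:ENV,209,158.5,31.34,7.40,1259,9.292,2049467
ERROR,456,30.1,22.79,3.71,400,2.658,1315995
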