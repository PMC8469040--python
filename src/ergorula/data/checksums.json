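{
 "table_a.csv": "df532be358a1dc0ba06e13a94494e2fa4a81ba602977e2d78c77e6d68fc07047",
 "table_b.csv": "86dae3fd548cf74653e0aa58b91997243f8a10ca2bfcc27bcb3252e3116cf69d",
 "table_c.csv": "751a9e804a664040168257af747a2929cab4ccbf7750577dc777ae4f7603c557"
}
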