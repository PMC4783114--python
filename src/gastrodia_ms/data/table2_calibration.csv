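standard,slope,intercept,r2,range_low,range_high,lod,loq
gastrodin,79899,-1108.1,0.9999,8.89,44.48,0.024,0.081
parishin E,19656,-12538,0.9915,6.08,60.8,0.143,0.475
parishin B,19656,-12538,0.9981,34.5,138.0,0.104,0.345
parishin,315580,-7052.4,0.9999,40.66,203.3,0.359,1.196
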