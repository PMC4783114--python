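standard,initial,added,detected_mean,detected_sd,printed_recovery,printed_rsd,consistent
gastrodin,1.09,0.62,1.62,0.01,88.02,1.26,0
gastrodin,1.09,2.24,3.35,0.03,100.91,1.54,1
gastrodin,1.09,3.86,4.93,0.01,99.65,0.3,1
parishin E,1.22,0.42,1.62,0.02,94.65,0.57,0
parishin E,1.22,2.04,3.33,0.03,105.38,1.46,0
parishin E,1.22,4.11,5.01,0.03,92.15,0.7,1
parishin B,1.14,0.32,1.43,0.0,89.88,0.52,0
parishin B,1.14,1.72,2.88,0.01,101.96,0.58,0
parishin B,1.14,3.45,4.35,0.0,92.85,0.13,1
parishin,2.55,2.87,5.34,0.01,97.66,0.34,0
parishin,2.55,8.23,10.78,0.02,100.43,0.0,0
parishin,2.55,13.86,16.21,0.01,98.49,0.07,1
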