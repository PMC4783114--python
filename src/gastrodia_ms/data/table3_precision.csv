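standard,design,level,mean,sd,printed_rsd,consistent
gastrodin,intra,low,9.48,0.38,4.0,1
gastrodin,intra,middle,15.85,0.59,3.72,1
gastrodin,intra,high,27.09,0.34,1.25,1
gastrodin,inter,low,9.3,0.23,2.46,1
gastrodin,inter,middle,15.15,0.3,2.01,1
gastrodin,inter,high,27.09,0.45,1.34,0
parishin H,intra,low,6.4,0.21,3.35,0
parishin H,intra,middle,8.99,0.23,2.72,0
parishin H,intra,high,20.58,0.66,3.18,1
parishin H,inter,low,6.29,0.15,2.42,1
parishin H,inter,middle,8.98,0.15,1.48,0
parishin H,inter,high,20.02,0.81,4.05,1
parishin B,intra,low,35.82,0.59,1.67,1
parishin B,intra,middle,57.56,0.74,1.28,1
parishin B,intra,high,118.34,0.6,0.51,1
parishin B,inter,low,35.76,0.67,1.87,1
parishin B,inter,middle,59.52,0.78,1.3,1
parishin B,inter,high,118.39,0.66,0.21,0
parishin,intra,low,50.88,0.85,1.66,1
parishin,intra,middle,83.8,0.61,0.72,1
parishin,intra,high,167.23,0.94,0.56,1
parishin,inter,low,51.77,0.41,0.8,1
parishin,inter,middle,84.08,0.27,0.32,1
parishin,inter,high,167.9,0.81,0.48,1
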