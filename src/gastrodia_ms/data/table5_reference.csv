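peak,rt_min,printed_mz,adduct,polarity,printed_name,candidate,family,trusted
1,2.44,191.0198,[M-H]-,-,Citric Acid,citric acid,0,1
2,3.17,243.0123,[M-H]-,-,Uridine,uridine,0,0
3,3.51,180.1078,[M-H]-,-,Tyrosine,tyrosine,0,0
4,3.74,132.1020,[M+H]+,+,Leucine,leucine,0,1
5,4.82,266.1567,[M-H]-,-,Adenosine,adenosine,0,0
6,6.36,331.1044,[M+HCOO]-,-,Gastrodin,gastrodin,0,1
7,8.12,127.1091,[M+H]+,+,5-hydroxymethyl fural,5-hydroxymethylfurfural,0,0
8,11.37,123.1098,[M-H]-,-,P-hydroxybenzyl alcohol,p-hydroxybenzyl alcohol,0,0
9,21.83,621.1660,[M-H]-,-,Mono-substituted parishin glucoside,mono-substituted parishin glucoside,1,1
10,23.25,459.1145,[M-H]-,-,parishin H,mono-substituted parishin,1,1
11,25.15,459.1145,[M-H]-,-,parishin E,mono-substituted parishin,1,1
12,25.72,412.1178,[M-H]-,-,S-(4-hydroxybenzyl)-glutathione,S-(4-hydroxybenzyl)-glutathione,0,1
13,27.94,489.1247,[M-H]-,-,Methoxy mono-substituted parishin,methoxy mono-substituted parishin,1,1
14,30.82,518.1593,[M-H]-,-,P-hydroxybenzyl s-(4-hydroxybenzyl)-glutathione,p-hydroxybenzyl-S-(4-hydroxybenzyl)-glutathione,1,1
15,32.91,889.2617,[M-H]-,-,Di-substituted parishin glucoside,di-substituted parishin glucoside,1,1
16,35.5,727.2083,[M-H]-,-,Di-substituted parishin,di-substituted parishin,1,1
17,36.13,727.2092,[M-H]-,-,parishin B,di-substituted parishin,1,1
18,36.22,889.2617,[M-H]-,-,Di-substituted parishin glucoside isomer,di-substituted parishin glucoside,1,1
19,37.26,757.2189,[M-H]-,-,Methoxy di-substituted parishin,methoxy di-substituted parishin,1,1
20,37.98,727.2070,[M-H]-,-,parishin C,di-substituted parishin,1,1
21,39.11,757.2189,[M-H]-,-,Methoxy di-substituted parishin isomer,methoxy di-substituted parishin,1,1
22,39.51,741.2240,[M-H]-,-,Methyl di-substituted parishin,methyl di-substituted parishin,1,1
23,40.59,787.2303,[M+HCOO]-,-,Methyl di-substituted parishin isomer,methyl di-substituted parishin,1,1
24,42.02,1157.3546,[M-H]-,-,Parishin glucoside,parishin glucoside,1,1
25,42.39,995.3034,[M-H]-,-,Parishin,parishin,1,1
26,42.81,1025.3138,[M-H]-,-,Methyl parishin,methoxy parishin,1,1
27,43.01,565.1553,[M-H]-,-,P-hydroxybenzyl mono-substituted parishin,p-hydroxybenzyl mono-substituted parishin,1,1
28,43.89,565.1556,[M-H]-,-,P-hydroxybenzyl mono-substituted parishin isomer,p-hydroxybenzyl mono-substituted parishin,1,1
29,44.34,833.2500,[M-H]-,-,P-hydroxybenzyl di-substituted parishin,p-hydroxybenzyl di-substituted parishin,1,1
30,45.91,833.2501,[M-H]-,-,P-hydroxybenzyl di-substituted parishin isomer,p-hydroxybenzyl di-substituted parishin,1,1
31,46.18,1101.3436,[M-H]-,-,P-hydroxybenzyl parishin,p-hydroxybenzyl parishin,1,1
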