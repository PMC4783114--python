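peak,candidate,adduct,printed_fragment_mz,printed_assignment,losses,h2,include,reason
1,citric acid,[M-H]-,111.1,[M-H-2H2O-CO2]-,H2O;H2O;CO2,0,1,
1,citric acid,[M-H]-,173.1,[M-H-H2O]-,H2O,0,1,
6,gastrodin,[M+HCOO]-,123.12,[M-Glu-H]-,HCOOH;glucosyl,0,1,
6,gastrodin,[M+HCOO]-,161.12,[Glu-H]-,,0,0,"charged glucose fragment, not a neutral-loss path"
9,mono-substituted parishin glucoside,[M-H]-,441.1,[M-H-162-H2O]-,glucosyl;H2O,0,1,
9,mono-substituted parishin glucoside,[M-H]-,459.1,[M-H-162]-,glucosyl,0,1,
9,mono-substituted parishin glucoside,[M-H]-,397.1,[M-H-162-H2O-CO2]-,glucosyl;H2O;CO2,0,1,
9,mono-substituted parishin glucoside,[M-H]-,369.1,[M-H-162-CO2]-,,0,0,printed arithmetic inconsistent: -162-CO2 computes 415.12
10,mono-substituted parishin,[M-H]-,173.1,[M-H-268-H2O]-,gastrodinyl;H2O,0,1,
10,mono-substituted parishin,[M-H]-,129.1,[M-H-268-H2O-CO2]-,gastrodinyl;H2O;CO2,0,1,
11,mono-substituted parishin,[M-H]-,173.1,[M-H-268-H2O]-,gastrodinyl;H2O,0,1,
11,mono-substituted parishin,[M-H]-,129.1,[M-H-268-H2O-CO2]-,gastrodinyl;H2O;CO2,0,1,
12,S-(4-hydroxybenzyl)-glutathione,[M-H]-,306.1,[M-H-106]-,hydroxybenzyl,0,1,
13,methoxy mono-substituted parishin,[M-H]-,427.1,[M-H-H2O-CO2]-,H2O;CO2,0,1,
13,methoxy mono-substituted parishin,[M-H]-,173.1,[M-H-268-H2O-30]-,gastrodinyl;H2O;CH2O,0,1,
14,p-hydroxybenzyl-S-(4-hydroxybenzyl)-glutathione,[M-H]-,412.1,[M-H-162-106]-,,0,0,printed string lists a spurious -162; the m/z corresponds to -106
14,p-hydroxybenzyl-S-(4-hydroxybenzyl)-glutathione,[M-H]-,306.1,[M-H-162-106-106]-,,0,0,printed string lists a spurious -162; the m/z corresponds to -106-106
15,di-substituted parishin glucoside,[M-H]-,621.1,[M-H-268]-,gastrodinyl,0,1,
15,di-substituted parishin glucoside,[M-H]-,603.1,[M-H-268-H2O]-,gastrodinyl;H2O,0,1,
15,di-substituted parishin glucoside,[M-H]-,585.1,[M-H-268-2H2O]-,gastrodinyl;H2O;H2O,0,1,
15,di-substituted parishin glucoside,[M-H]-,559.1,[M-H-268-H2O-CO2]-,gastrodinyl;H2O;CO2,0,1,
15,di-substituted parishin glucoside,[M-H]-,531.1,[M-3H-268-2CO2]-,gastrodinyl;CO2;CO2,1,1,
15,di-substituted parishin glucoside,[M-H]-,423.1,[M-H-268-2H2O-162]-,gastrodinyl;H2O;H2O;glucosyl,0,1,
15,di-substituted parishin glucoside,[M-H]-,397.1,[M-H-268-H2O-CO2-162]-,gastrodinyl;H2O;CO2;glucosyl,0,1,
16,di-substituted parishin,[M-H]-,471.1,[M-H-268-H2O]-,,0,0,fragment list copied from peak 19; inconsistent with a CH2O-free candidate
17,di-substituted parishin,[M-H]-,459.1,[M-H-268]-,gastrodinyl,0,1,
17,di-substituted parishin,[M-H]-,441.1,[M-H-268-H2O]-,gastrodinyl;H2O,0,1,
17,di-substituted parishin,[M-H]-,423.1,[M-H-268-2H2O]-,gastrodinyl;H2O;H2O,0,1,
17,di-substituted parishin,[M-H]-,397.1,[M-H-268-H2O-CO2]-,gastrodinyl;H2O;CO2,0,1,
17,di-substituted parishin,[M-H]-,369.1,[M-3H-268-2CO2]-,gastrodinyl;CO2;CO2,1,1,
19,methoxy di-substituted parishin,[M-H]-,471.1,[M-H-268-H2O]-,gastrodinyl;H2O,0,1,
19,methoxy di-substituted parishin,[M-H]-,453.1,[M-H-268-2H2O]-,gastrodinyl;H2O;H2O,0,1,
19,methoxy di-substituted parishin,[M-H]-,423.11,[M-H-268-2H2O-30]-,gastrodinyl;H2O;H2O;CH2O,0,1,
19,methoxy di-substituted parishin,[M-H]-,397.1,[M-H-268-H2O-CO2]-,,0,0,printed arithmetic inconsistent: computes 427.12 (a -30 is missing)
19,methoxy di-substituted parishin,[M-H]-,369.1,[M-3H-268-2CO2-30]-,gastrodinyl;CO2;CO2;CH2O,1,1,
20,di-substituted parishin,[M-H]-,459.1,[M-H-268]-,gastrodinyl,0,1,
20,di-substituted parishin,[M-H]-,441.1,[M-H-268-H2O]-,gastrodinyl;H2O,0,1,
20,di-substituted parishin,[M-H]-,369.1,[M-3H-268-2CO2]-,gastrodinyl;CO2;CO2,1,1,
21,methoxy di-substituted parishin,[M-H]-,423.1,[M-H-268-2H2O-30]-,gastrodinyl;H2O;H2O;CH2O,0,1,
21,methoxy di-substituted parishin,[M-H]-,369.1,[M-3H-268-2CO2-30]-,gastrodinyl;CO2;CO2;CH2O,1,1,
22,methyl di-substituted parishin,[M-H]-,741.1,[M-H]-,,0,1,
22,methyl di-substituted parishin,[M-H]-,473.1,[M-H-268]-,gastrodinyl,0,1,
22,methyl di-substituted parishin,[M-H]-,441.1,[M-H-268-H2O-14]-,gastrodinyl;H2O;CH2,0,1,
23,methyl di-substituted parishin,[M+HCOO]-,741.1,[M-H]-,HCOOH,0,1,
23,methyl di-substituted parishin,[M+HCOO]-,473.1,[M-H-268]-,HCOOH;gastrodinyl,0,1,
23,methyl di-substituted parishin,[M+HCOO]-,441.1,[M-H-268-H2O-14]-,HCOOH;gastrodinyl;H2O;CH2,0,1,
24,parishin glucoside,[M-H]-,889.1,[M-H-268]-,gastrodinyl,0,1,
24,parishin glucoside,[M-H]-,727.1,[M-H-268-162]-,gastrodinyl;glucosyl,0,1,
24,parishin glucoside,[M-H]-,585.1,[M-H-2TMS]-,,0,0,unparseable TMS token
25,parishin,[M-H]-,727.1,[M-H-268]-,gastrodinyl,0,1,
25,parishin,[M-H]-,441.1,[M-H-268-268-H2O]-,gastrodinyl;gastrodinyl;H2O,0,1,
25,parishin,[M-H]-,423.1,[M-H-268-268-2H2O]-,gastrodinyl;gastrodinyl;H2O;H2O,0,1,
25,parishin,[M-H]-,397.1,[M-H-268-268-H2O-CO2]-,gastrodinyl;gastrodinyl;H2O;CO2,0,1,
25,parishin,[M-H]-,379.1,[M-H-268-268-2H2O-CO2]-,gastrodinyl;gastrodinyl;H2O;H2O;CO2,0,1,
26,methoxy parishin,[M-H]-,757.1,[M-H-268]-,gastrodinyl,0,1,
26,methoxy parishin,[M-H]-,727.1,[M-H-268-30]-,gastrodinyl;CH2O,0,1,
27,p-hydroxybenzyl mono-substituted parishin,[M-H]-,529.1,[M-H-2H2O]-,H2O;H2O,0,1,
27,p-hydroxybenzyl mono-substituted parishin,[M-H]-,503.1,[M-H-CO2-H2O]-,CO2;H2O,0,1,
27,p-hydroxybenzyl mono-substituted parishin,[M-H]-,459.1,[M-H-106]-,hydroxybenzyl,0,1,
27,p-hydroxybenzyl mono-substituted parishin,[M-H]-,397.1,[M-H-106-H2O-CO2]-,hydroxybenzyl;H2O;CO2,0,1,
27,p-hydroxybenzyl mono-substituted parishin,[M-H]-,173.1,[M-H-268-H2O-106]-,gastrodinyl;H2O;hydroxybenzyl,0,1,
28,p-hydroxybenzyl mono-substituted parishin,[M-H]-,459.1,[M-H-106]-,hydroxybenzyl,0,1,
28,p-hydroxybenzyl mono-substituted parishin,[M-H]-,173.1,[M-H-268-H2O-106]-,gastrodinyl;H2O;hydroxybenzyl,0,1,
29,p-hydroxybenzyl di-substituted parishin,[M-H]-,727.1,[M-H-106]-,hydroxybenzyl,0,1,
29,p-hydroxybenzyl di-substituted parishin,[M-H]-,441.1,[M-H-268-H2O-106]-,gastrodinyl;H2O;hydroxybenzyl,0,1,
29,p-hydroxybenzyl di-substituted parishin,[M-H]-,397.1,[M-H-268-H2O-CO2-106]-,gastrodinyl;H2O;CO2;hydroxybenzyl,0,1,
30,p-hydroxybenzyl di-substituted parishin,[M-H]-,423.1,[M-H-268-2H2O-106]-,gastrodinyl;H2O;H2O;hydroxybenzyl,0,1,
30,p-hydroxybenzyl di-substituted parishin,[M-H]-,369.1,[M-3H-268-2CO2-106]-,gastrodinyl;CO2;CO2;hydroxybenzyl,1,1,
30,p-hydroxybenzyl di-substituted parishin,[M-H]-,263.1,[M-3H-268-2CO2-106-106]-,gastrodinyl;CO2;CO2;hydroxybenzyl;hydroxybenzyl,1,1,
31,p-hydroxybenzyl parishin,[M-H]-,995.1,[M-H-106]-,hydroxybenzyl,0,1,
31,p-hydroxybenzyl parishin,[M-H]-,833.1,[M-H-268]-,gastrodinyl,0,1,
31,p-hydroxybenzyl parishin,[M-H]-,727.1,[M-H-268-106]-,gastrodinyl;hydroxybenzyl,0,1,
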