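BEGIN IONS
TITLE=peak01 Citric Acid
PEPMASS=191.0198
CHARGE=1-
RTINSECONDS=146.4
111.1 100.0 
173.1 100.0 
END IONS

BEGIN IONS
TITLE=peak02 Uridine
PEPMASS=243.0123
CHARGE=1-
RTINSECONDS=190.2
END IONS

BEGIN IONS
TITLE=peak03 Tyrosine
PEPMASS=180.1078
CHARGE=1-
RTINSECONDS=210.6
END IONS

BEGIN IONS
TITLE=peak04 Leucine
PEPMASS=132.102
CHARGE=1+
RTINSECONDS=224.4
86.1 100.0 
115.1 100.0 
END IONS

BEGIN IONS
TITLE=peak05 Adenosine
PEPMASS=266.1567
CHARGE=1-
RTINSECONDS=289.2
134.12 100.0 
END IONS

BEGIN IONS
TITLE=peak06 Gastrodin
PEPMASS=331.1044
CHARGE=1-
RTINSECONDS=381.6
123.12 100.0 
161.12 100.0 
END IONS

BEGIN IONS
TITLE=peak07 5-hydroxymethyl fural
PEPMASS=127.1091
CHARGE=1+
RTINSECONDS=487.2
108.1 100.0 
END IONS

BEGIN IONS
TITLE=peak08 P-hydroxybenzyl alcohol
PEPMASS=123.1098
CHARGE=1-
RTINSECONDS=682.2
105.12 100.0 
END IONS

BEGIN IONS
TITLE=peak09 Mono-substituted parishin glucoside
PEPMASS=621.166
CHARGE=1-
RTINSECONDS=1309.8
369.1 100.0 
397.1 100.0 
441.1 100.0 
459.1 100.0 
END IONS

BEGIN IONS
TITLE=peak10 parishin H
PEPMASS=459.1145
CHARGE=1-
RTINSECONDS=1395.0
129.1 100.0 
173.1 100.0 
END IONS

BEGIN IONS
TITLE=peak11 parishin E
PEPMASS=459.1145
CHARGE=1-
RTINSECONDS=1509.0
129.1 100.0 
173.1 100.0 
END IONS

BEGIN IONS
TITLE=peak12 S-(4-hydroxybenzyl)-glutathione
PEPMASS=412.1178
CHARGE=1-
RTINSECONDS=1543.2
306.1 100.0 
END IONS

BEGIN IONS
TITLE=peak13 Methoxy mono-substituted parishin
PEPMASS=489.1247
CHARGE=1-
RTINSECONDS=1676.4
173.1 100.0 
427.1 100.0 
END IONS

BEGIN IONS
TITLE=peak14 P-hydroxybenzyl s-(4-hydroxybenzyl)-glutathione
PEPMASS=518.1593
CHARGE=1-
RTINSECONDS=1849.2
306.1 100.0 
412.1 100.0 
END IONS

BEGIN IONS
TITLE=peak15 Di-substituted parishin glucoside
PEPMASS=889.2617
CHARGE=1-
RTINSECONDS=1974.6
397.1 100.0 
423.1 100.0 
531.1 100.0 
559.1 100.0 
585.1 100.0 
603.1 100.0 
621.1 100.0 
END IONS

BEGIN IONS
TITLE=peak16 Di-substituted parishin
PEPMASS=727.2083
CHARGE=1-
RTINSECONDS=2130.0
369.1 100.0 
397.1 100.0 
423.1 100.0 
453.1 100.0 
471.1 100.0 
END IONS

BEGIN IONS
TITLE=peak17 parishin B
PEPMASS=727.2092
CHARGE=1-
RTINSECONDS=2167.8
369.1 100.0 
397.1 100.0 
423.1 100.0 
441.1 100.0 
459.1 100.0 
END IONS

BEGIN IONS
TITLE=peak18 Di-substituted parishin glucoside isomer
PEPMASS=889.2617
CHARGE=1-
RTINSECONDS=2173.2
397.1 100.0 
423.1 100.0 
531.1 100.0 
559.1 100.0 
585.1 100.0 
603.1 100.0 
621.1 100.0 
END IONS

BEGIN IONS
TITLE=peak19 Methoxy di-substituted parishin
PEPMASS=757.2189
CHARGE=1-
RTINSECONDS=2235.6
369.1 100.0 
397.1 100.0 
423.11 100.0 
453.1 100.0 
471.1 100.0 
END IONS

BEGIN IONS
TITLE=peak20 parishin C
PEPMASS=727.207
CHARGE=1-
RTINSECONDS=2278.8
369.1 100.0 
397.1 100.0 
423.1 100.0 
441.1 100.0 
459.1 100.0 
END IONS

BEGIN IONS
TITLE=peak21 Methoxy di-substituted parishin isomer
PEPMASS=757.2189
CHARGE=1-
RTINSECONDS=2346.6
369.1 100.0 
397.1 100.0 
423.1 100.0 
453.1 100.0 
471.1 100.0 
END IONS

BEGIN IONS
TITLE=peak22 Methyl di-substituted parishin
PEPMASS=741.224
CHARGE=1-
RTINSECONDS=2370.6
441.1 100.0 
473.1 100.0 
741.1 100.0 
END IONS

BEGIN IONS
TITLE=peak23 Methyl di-substituted parishin isomer
PEPMASS=787.2303
CHARGE=1-
RTINSECONDS=2435.4
441.1 100.0 
473.1 100.0 
741.1 100.0 
END IONS

BEGIN IONS
TITLE=peak24 Parishin glucoside
PEPMASS=1157.3546
CHARGE=1-
RTINSECONDS=2521.2
379.1 100.0 
423.1 100.0 
585.1 100.0 
727.1 100.0 
889.1 100.0 
END IONS

BEGIN IONS
TITLE=peak25 Parishin
PEPMASS=995.3034
CHARGE=1-
RTINSECONDS=2543.4
379.1 100.0 
397.1 100.0 
423.1 100.0 
441.1 100.0 
727.1 100.0 
END IONS

BEGIN IONS
TITLE=peak26 Methyl parishin
PEPMASS=1025.3138
CHARGE=1-
RTINSECONDS=2568.6
727.1 100.0 
757.1 100.0 
END IONS

BEGIN IONS
TITLE=peak27 P-hydroxybenzyl mono-substituted parishin
PEPMASS=565.1553
CHARGE=1-
RTINSECONDS=2580.6
173.1 100.0 
397.1 100.0 
459.1 100.0 
503.1 100.0 
529.1 100.0 
END IONS

BEGIN IONS
TITLE=peak28 P-hydroxybenzyl mono-substituted parishin isomer
PEPMASS=565.1556
CHARGE=1-
RTINSECONDS=2633.4
173.1 100.0 
397.1 100.0 
459.1 100.0 
503.1 100.0 
529.1 100.0 
END IONS

BEGIN IONS
TITLE=peak29 P-hydroxybenzyl di-substituted parishin
PEPMASS=833.25
CHARGE=1-
RTINSECONDS=2660.4
397.1 100.0 
441.1 100.0 
727.1 100.0 
END IONS

BEGIN IONS
TITLE=peak30 P-hydroxybenzyl di-substituted parishin isomer
PEPMASS=833.2501
CHARGE=1-
RTINSECONDS=2754.6
263.1 100.0 
369.1 100.0 
397.1 100.0 
423.1 100.0 
441.1 100.0 
727.1 100.0 
END IONS

BEGIN IONS
TITLE=peak31 P-hydroxybenzyl parishin
PEPMASS=1101.3436
CHARGE=1-
RTINSECONDS=2770.8
727.1 100.0 
833.1 100.0 
995.1 100.0 
END IONS

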