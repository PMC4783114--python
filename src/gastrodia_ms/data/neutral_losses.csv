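name,formula,mass,applicability
H2O,H2O,18.010565,"any candidate, up to 2x"
CO2,CO2,43.989829,"any candidate, up to 2x"
CH2O,CH2O,30.010565,per methoxy substituent
CH2,CH2,14.015650,per methyl substituent
ribosyl,C5H8O4,132.042259,nucleosides only
hydroxybenzyl,C7H6O,106.041865,per p-hydroxybenzyl or gastrodinyl unit; glutathione conjugates
glucosyl,C6H10O5,162.052823,per glucosyl or gastrodinyl unit; gastrodin
gastrodinyl,C13H16O6,268.094688,per gastrodinyl unit
glycyl,C2H5NO2,75.032028,glutathione conjugates only
glutamyl,C5H9NO4,147.053158,glutathione conjugates only
HCOOH,CH2O2,46.005479,[M+HCOO]- precursors only
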