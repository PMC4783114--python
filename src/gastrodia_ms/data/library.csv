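name,formula,class,trust
citric acid,C6H8O7,other,high
uridine,C9H12N2O6,nucleoside,low
tyrosine,C9H11NO3,amino acid,low
leucine,C6H13NO2,amino acid,high
adenosine,C10H13N5O4,nucleoside,low
gastrodin,C13H18O7,gastrodin,high
5-hydroxymethylfurfural,C6H6O3,other,low
p-hydroxybenzyl alcohol,C7H8O2,other,low
S-(4-hydroxybenzyl)-glutathione,C17H23N3O7S,S-(4-hydroxybenzyl)-glutathione,high
p-hydroxybenzyl-S-(4-hydroxybenzyl)-glutathione,C24H29N3O8S,S-(4-hydroxybenzyl)-glutathione,high
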