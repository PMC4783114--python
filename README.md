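# gastrodia-ms

Annotation, method validation, surrogate quantification and chemometrics for
UPLC–MS metabolite surveys of fresh *Gastrodia elata* root extracts.

*G. elata* ("tianma") roots accumulate a distinctive family of phenolic
glycosides around **parishin**, the triester of citric acid with three
gastrodin units (gastrodin = 4-hydroxybenzyl alcohol β-D-glucoside,
C13H18O7).  High-resolution LC–MS/MS identifies these compounds from two
signals: the accurate mass of the molecular ion (within a 5 ppm gate across
the adducts [M−H]⁻, [M+HCOO]⁻, [M+H]⁺, [M+Na]⁺) and characteristic neutral
losses in the fragment spectra — 268 Da (gastrodinyl, gastrodin − H₂O),
162 Da (glucosyl), 106 Da (*p*-hydroxybenzyl), 132 Da (ribosyl, for
nucleosides), plus water and CO₂.  This package implements that
identification logic end to end, together with the analytical statistics
that make the quantification defensible (calibration regression, S/N-based
LOD/LOQ, intra/inter-day RSD, spiked recovery) and a correlation-PCA /
varimax / KMO stage for comparing cultivars by their class-level
concentration profiles.

The core identification model: a candidate with neutral monoisotopic mass
*M* matches an observed precursor *m/z* under adduct *a* when

    |10⁶ · (mz_obs − (M + Δa)) / (M + Δa)| ≤ 5 ppm,

and a fragment at *f* is explained by a multiset *L* of structurally
licensed neutral losses when |f − (M + Δa − Σ_{ℓ∈L} m_ℓ)| ≤ 0.01 Da.
Candidates are the union of a curated small-molecule library and the
combinatorially enumerated parishin family (1–3 gastrodinyl residues on the
citryl core, optionally decorated with glucosyl, *p*-hydroxybenzyl, methyl
or methoxy residues).

## Worked example

The package bundles a 31-spectrum transcription of the survey's compound
table (`gastrodia_ms/data/table5.mgf`).  Annotating it from the shell:

```sh
gastrodia-ms annotate --spectra src/gastrodia_ms/data/table5.mgf --out ann.csv
# annotated 31/31 spectra (5 nominal-mass) -> ann.csv
```

or, through the analysis driver:

```sh
python analysis/02_annotate_table5.py
```

prints

```
annotated 31/31 spectra (5 at nominal-mass confidence)
per-class counts: {'S-(4-hydroxybenzyl)-glutathione': 2, 'amino acid': 2,
 'gastrodin': 1, 'nucleoside': 2, 'other': 3, 'parishin derivative': 21}
trusted family rows: 22; worst |ppm| = 2.89 (peak 20, di-substituted parishin)
```

meaning: every spectrum received a top-ranked (candidate, adduct) hit; 26
passed the 5 ppm accurate-mass gate, while five small polar metabolites
(uridine, tyrosine, adenosine, 5-HMF, *p*-hydroxybenzyl alcohol) matched
only at integer-mass resolution because their printed decimals are
irreconcilable with their textbook formulas — they are reported at reduced
confidence rather than silently accepted.  Across the 22 trustworthy
parishin-family and glutathione-conjugate rows, theory and print agree to
2.9 ppm or better.

The numbered scripts under `analysis/` walk the full study: candidate-space
construction (`01`), annotation (`02`), validation statistics (`03`),
surrogate quantification on a synthetic cultivar experiment (`04`) and
PCA/varimax/KMO chemometrics (`05`).  Each writes its tables under
`results/`.

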