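# Methods

## Mass arithmetic

All masses derive from one bundled table of IUPAC monoisotopic atomic masses
(C, H, N, O, S, Na to ≥ 9 decimals).  Ion m/z uses the proton-mass
convention — ±1.007276 Da for protonation/deprotonation, +22.989218 for
sodiation, +44.998201 for formate adduction — so electron mass is handled
implicitly; all ions are treated as singly charged, which holds for every
species in this chemistry.  Relative mass error is
10⁶·(observed − theoretical)/theoretical; nominal molecular weight is the
monoisotopic mass rounded half-up.  Display rounding is 4 decimals for m/z,
1 for ppm, integer for MW; full precision is kept internally.

## Candidate space

The parishin family is enumerated as citric acid (C6H8O7) plus *g* ∈ {1,2,3}
gastrodinyl residues (C13H16O6, +268.0947 Da; gastrodin minus the
condensation water) and at most one each of glucosyl (C6H10O5, +162.0528),
*p*-hydroxybenzyl (C7H6O, +106.0419), methyl (CH2, +14.0157) and a
methoxy-equivalent (CH2O, +30.0106).  Because glucosyl + *p*-hydroxybenzyl
equals gastrodinyl element-for-element, the 48 raw combinations collapse to
40 distinct formulas; deduplication keeps the representative with more
gastrodinyl units, matching the field's naming.  Names are systematic
(prefix order methyl < methoxy < *p*-hydroxybenzyl, glucoside as suffix) and
round-trip to the substituent multiset.  Note one naming quirk of the
source nomenclature: the +CH2O homolog of parishin is canonically "methoxy
parishin" here although it is conventionally called "methyl parishin";
the +CH2 homolog of the di-substituted scaffold is "methyl di-substituted
parishin".  Positional isomers (parishin B/C, E/H, and the printed "isomer"
rows) share one formula and are distinguished only by retention-time order,
never by mass.

The curated library covers the non-parishin metabolites (citric acid,
uridine, tyrosine, leucine, adenosine, gastrodin, 5-HMF, *p*-hydroxybenzyl
alcohol and the two glutathione conjugates).  Five entries carry a ``low``
trust flag: their published m/z values disagree with their textbook
formulas by far more than any plausible instrument error (only the integer
mass is preserved), so they are excluded from ppm-gated checks.

## Annotation

Precursor matching compares the observed m/z against every polarity-
compatible (candidate, adduct) pair and keeps hits within the gate
(default 5 ppm).  Fragments are explained as the theoretical precursor ion
minus a multiset of neutral losses, searched exhaustively up to a maximum
path depth with per-loss structural caps: gastrodinyl per gastrodinyl unit;
glucosyl and *p*-hydroxybenzyl per matching substituent *or* per
gastrodinyl unit (a gastrodinyl can shed either moiety partially); CH2O/CH2
per methoxy/methyl decoration; ribosyl for nucleosides; glycyl (75.0320)
and glutamyl (147.0532) for glutathione conjugates; water and CO₂ up to
twice each for any candidate.  Formate precursors may additionally lose
HCOOH (46.0055), which is how [M+HCOO]⁻ ions reach the [M−H]⁻ fragment
manifold.  Negative-ion paths may carry one H₂ deficit (the "[M−3H−…]⁻"
species repeatedly observed for parishins); the deficit does not count
toward depth, matching how such assignments are conventionally written.

Defaults: gate 5 ppm; fragment tolerance 0.01 Da; maximum depth **5** — the
deepest assignment this chemistry actually requires is five losses
(e.g. −268−268−H₂O−H₂O−CO₂ on parishin), so a depth-4 cap would silently
drop valid paths.  Ties between competing explanations break
deterministically: fewest losses, then no-H₂ before H₂, then smallest
|residual|, then lexicographic path.  There is no randomness anywhere in
annotation.

Spectra with no gated hit may fall back to a nominal-(integer)-mass match
restricted to low-trust library entries, reported with
``confidence="nominal"``.  This mirrors how small polar metabolites are in
practice identified from retention time and literature rather than accurate
mass, and it is what lets the bundled 31-row fixture annotate completely:
26 rows by accurate mass, 5 at reduced confidence.  The fallback never
competes with, or relaxes, the 5 ppm gate for trusted candidates.

## Validation statistics

Calibration is ordinary least squares of peak area on concentration with r²
as squared Pearson correlation (≥ 3 strictly positive, distinct levels
required).  LOD and LOQ are read off a serial-dilution (concentration, S/N)
series by log-log interpolation at S/N = 3 and 10 — the operational
definition used with a diode-array detector — with the 3.3σ/slope and
10σ/slope shortcut provided separately and labelled as such.  Precision is
RSD = SD/mean × 100 with sample SD (n−1); recovery is
(detected − original)/spiked × 100, scale-invariant by construction.

The bundled transcriptions of the printed precision and recovery tables
carry a consistency flag: 5 of 24 RSD cells and 7 of 12 recovery rows do
not recompute from their own printed inputs within rounding (the original
analysis evidently used unrounded raw data).  Flagged cells are reported,
not reproduced; the formulas themselves are asserted exactly on the
self-consistent cells.

## Quantification

Only four external standards exist (gastrodin, parishin E, parishin B,
parishin).  Compounds resolve to a standard in that order of preference:
own standard, parishin for parishin derivatives, gastrodin for everything
else; every value carries the standard used and a semi-quantitative flag
when a surrogate was involved, plus an extrapolation flag when the inverted
concentration falls outside the standard's linear range.  Class profiles
sum member concentrations into the five statistical groups; compounds not
detected in a sample contribute zero (the survey itself has such structural
zeros, e.g. gastrodin absent in one cultivar).  Units are carried through
unchanged; PCA standardizes columns, so the stage is unit-agnostic.

## Chemometrics

PCA runs on the correlation matrix (class concentrations span orders of
magnitude); loadings are eigenvectors scaled by √eigenvalue, scores are the
standardized data projected on the eigenvectors, explained variance is
eigenvalue/p.  Sign convention: the largest-|loading| entry of each
component is positive.  Two components are retained by default (a Kaiser
rule is available by passing a different count).  Varimax uses Kaiser's
SVD iteration on the raw criterion (variance of squared loadings), with a
relative convergence tolerance of 1e-10 and a 500-iteration cap; the
rotation is orthonormal, so communalities are preserved to numerical
precision — note the criterion is quadratically flat at its optimum, so
loadings converge to ~1e-4, not 1e-10.  KMO follows the anti-image
definition, Σr²/(Σr² + Σq²) over off-diagonal entries, with q the partial
correlations from the inverse correlation matrix; a condition number above
1e12 is treated as singular.  The pipeline drops constant (all-equal)
class columns before PCA and treats KMO as best-effort, since small or
collinear profile matrices make it undefined.

## Synthetic data

The generators emulate the survey's input structure, not its raw signals:

- **Spectra** — per candidate, precursor m/z = theoretical × (1 + ε/10⁶)
  with ε ~ N(0, σ) and σ = 1 ppm by default (Orbitrap-scale relative error,
  comfortably inside the 5 ppm gate); fragments are every licensed loss
  path to depth 3, thinned by 10% dropout, with log-normal intensities
  (shape 0.5).  The ground-truth table records every planted assignment.
- **Calibration** — a 6-level geometric dilution series spanning a
  gastrodin-like range (8.89–44.48 µg/mL), 3 replicates, response =
  79899·x − 1108.1 + N(0, 500); the noise SD is ~0.1% of the mid-range
  response, matching the r² ≥ 0.99 regime of real curves.
- **Cultivar matrix** — 8 cultivars × 3 replicates × 5 classes with four
  planted groups (high amino acids + nucleosides; high glutathione
  conjugate + gastrodin; moderately high amino acids; uniformly low),
  multiplicative effects of 2.5–5× against a 15% within-group CV, and an
  optional structural zero (gastrodin absent in one cultivar).  Effects of
  this size keep the cluster-recovery property well away from its decision
  boundary while remaining within the concentration contrasts such surveys
  report.

What passing on synthetic data does **not** show: robustness to
chromatographic coelution, isotope interference, matrix effects, intensity-
dependent mass error, or peak-integration error — none of which the
generators model.  The printed-table fixtures exercise the real chemistry
but inherit the publication's transcription errors, which is why
inconsistent cells are flagged rather than fitted.

## Known limitations

- The published PCA percentages and LOD/LOQ values cannot be reproduced:
  the underlying concentration matrix and chromatograms are unpublished.
  The chemometric stage is therefore validated structurally (trace and
  communality identities, planted-cluster recovery) rather than numerically.
- Positional isomery is outside scope: isomer labels come from retention
  order only, and no positional assignment on the citryl core is attempted.
- Fragment scoring ignores intensity; the score is the explained fraction
  of fragment peaks.
- Charge states above 1 and isotope envelopes are not modelled.
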