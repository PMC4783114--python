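#!/usr/bin/env python
"""Build the candidate-compound space and write it out.

Enumerates the parishin family (1-3 gastrodinyl residues on a citryl core,
optionally decorated with glucosyl / p-hydroxybenzyl / methyl / methoxy)
and merges it with the curated small-molecule library.  The interesting
finding is the exact formula degeneracy glucosyl + p-hydroxybenzyl ==
gastrodinyl: 48 raw combinations collapse to 40 distinct formulas.
"""

import csv
from pathlib import Path

from gastrodia_ms.chemcore import ion_mz
from gastrodia_ms.compound_space import default_library, enumerate_parishin_family

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

raw = enumerate_parishin_family(deduplicate=False)
family = enumerate_parishin_family()
library = default_library()
candidates = sorted(library + family, key=lambda c: c.mass)

with open(OUT / "candidates.csv", "w", newline="", encoding="utf-8") as fh:
    writer = csv.writer(fh)
    writer.writerow(["name", "formula", "class", "provenance", "trust",
                     "monoisotopic_mass", "mz_M-H", "mz_M+HCOO", "mz_M+H", "mz_M+Na"])
    for c in candidates:
        writer.writerow([
            c.name, str(c.formula), c.compound_class, c.provenance, c.trust,
            f"{c.mass:.4f}",
            f"{ion_mz(c.mass, '[M-H]-'):.4f}", f"{ion_mz(c.mass, '[M+HCOO]-'):.4f}",
            f"{ion_mz(c.mass, '[M+H]+'):.4f}", f"{ion_mz(c.mass, '[M+Na]+'):.4f}",
        ])

print(f"parishin-family combinations: {len(raw)} raw -> {len(family)} distinct formulas")
print(f"library compounds: {len(library)} ({sum(c.trust == 'low' for c in library)} low-trust)")
print(f"wrote {len(candidates)} candidates -> {OUT / 'candidates.csv'}")
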