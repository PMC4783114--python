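"""Candidate-compound space: curated library + combinatorial parishin family.

Parishin is the triester of citric acid with three gastrodin units; the
survey's phenolic assignments are all members of a small combinatorial family
around that scaffold — one to three gastrodinyl residues (gastrodin minus
water, C13H16O6, 268.0947 Da) on the citryl core, optionally decorated with a
glucosyl (C6H10O5), a p-hydroxybenzyl (C7H6O), a methyl (CH2) or a
methoxy-equivalent (CH2O) residue.  Enumerating that family, together with a
curated library of the small polar metabolites (nucleosides, amino acids,
glutathione conjugates), yields the candidate set that precursor matching
runs against.

Note one exact mass degeneracy of the chemistry: glucosyl + p-hydroxybenzyl
= gastrodinyl element-for-element, so some substituent combinations collapse
onto the same formula.  Enumeration deduplicates by formula, keeping the
representative with the most gastrodinyl units (the paper's naming).

Library entries carry a trust flag: several of the paper's printed masses for
small polar metabolites are irreconcilable with their textbook formulas
(only the integer mass survives printing); those rows are flagged ``low`` and
excluded from ppm-gated checks downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .chemcore import ElementalFormula, combine_ester, monoisotopic_mass

__all__ = [
    "BuildingBlock",
    "BUILDING_BLOCKS",
    "CITRIC_ACID",
    "CandidateCompound",
    "COMPOUND_CLASSES",
    "enumerate_parishin_family",
    "parse_candidate_name",
    "load_library",
    "default_library",
    "default_candidates",
]

#: The five statistical groups of the quantification stage, plus "other".
COMPOUND_CLASSES = (
    "amino acid",
    "nucleoside",
    "S-(4-hydroxybenzyl)-glutathione",
    "gastrodin",
    "parishin derivative",
    "other",
)

CITRIC_ACID = ElementalFormula.parse("C6H8O7")


@dataclass(frozen=True)
class BuildingBlock:
    """A pre-condensed residue delta attachable to the citryl scaffold."""

    name: str
    delta: ElementalFormula
    max_multiplicity: int

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.delta)


BUILDING_BLOCKS: dict[str, BuildingBlock] = {
    b.name: b
    for b in (
        BuildingBlock("gastrodinyl", ElementalFormula.parse("C13H16O6"), 3),
        BuildingBlock("glucosyl", ElementalFormula.parse("C6H10O5"), 1),
        BuildingBlock("p-hydroxybenzyl", ElementalFormula.parse("C7H6O"), 1),
        BuildingBlock("methyl", ElementalFormula.parse("CH2"), 1),
        BuildingBlock("methoxy", ElementalFormula.parse("CH2O"), 1),
    )
}

_SCAFFOLD_NAMES = {1: "mono-substituted parishin", 2: "di-substituted parishin", 3: "parishin"}
# prefix order is fixed so that canonical names are unambiguous
_PREFIX_ORDER = ("methyl", "methoxy", "p-hydroxybenzyl")


@dataclass(frozen=True)
class CandidateCompound:
    """A named candidate structure with formula, mass and class."""

    name: str
    formula: ElementalFormula
    compound_class: str
    substituents: tuple[tuple[str, int], ...] = ()
    provenance: str = "library"  # library | enumerated
    trust: str = "high"  # high | low

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(
                f"unknown compound class {self.compound_class!r} for {self.name!r}"
            )
        if self.trust not in ("high", "low"):
            raise ValueError(f"trust must be high/low, got {self.trust!r}")

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)

    def substituent_count(self, block: str) -> int:
        return dict(self.substituents).get(block, 0)

    @property
    def n_substituents(self) -> int:
        return sum(n for _, n in self.substituents)


def _canonical_name(g: int, optional: dict[str, int]) -> str:
    parts = [f"{p} " for p in _PREFIX_ORDER if optional.get(p, 0)]
    name = "".join(parts) + _SCAFFOLD_NAMES[g]
    if optional.get("glucosyl", 0):
        name += " glucoside"
    return name


def parse_candidate_name(name: str) -> tuple[int, dict[str, int]]:
    """Invert :func:`_canonical_name`; raises ``ValueError`` on foreign names."""
    optional: dict[str, int] = {}
    rest = name
    if rest.endswith(" glucoside"):
        optional["glucosyl"] = 1
        rest = rest[: -len(" glucoside")]
    for prefix in _PREFIX_ORDER:
        if rest.startswith(prefix + " "):
            optional[prefix] = 1
            rest = rest[len(prefix) + 1 :]
    for g, scaffold in _SCAFFOLD_NAMES.items():
        if rest == scaffold:
            return g, optional
    raise ValueError(f"not a canonical parishin-family name: {name!r}")


def enumerate_parishin_family(
    max_gastrodinyl: int = 3,
    allow: set[str] | None = None,
    deduplicate: bool = True,
) -> list[CandidateCompound]:
    """Enumerate citryl-core candidates: g gastrodinyl plus optional residues.

    Parameters
    ----------
    max_gastrodinyl
        Largest number of gastrodinyl units on the core (1–3).
    allow
        Names of optional building blocks to combine (default: all four of
        glucosyl, p-hydroxybenzyl, methyl, methoxy).  An empty set yields the
        three bare scaffolds.
    deduplicate
        Collapse formula-identical candidates (glucosyl + p-hydroxybenzyl is
        isobaric *and* isoformulaic with gastrodinyl), keeping the
        representative with the fewest optional substituents.
    """
    if max_gastrodinyl not in (1, 2, 3):
        raise ValueError("max_gastrodinyl must be 1, 2 or 3")
    if allow is None:
        allow = {"glucosyl", "p-hydroxybenzyl", "methyl", "methoxy"}
    unknown = allow - set(BUILDING_BLOCKS)
    if unknown or "gastrodinyl" in allow:
        raise ValueError(f"invalid optional blocks: {sorted(unknown or {'gastrodinyl'})}")

    optional_blocks = [BUILDING_BLOCKS[n] for n in sorted(allow)]
    raw: list[CandidateCompound] = []
    for g in range(1, max_gastrodinyl + 1):
        combos: list[dict[str, int]] = [{}]
        for block in optional_blocks:
            combos = [
                {**c, block.name: k} if k else c
                for c in combos
                for k in range(block.max_multiplicity + 1)
            ]
        for optional in combos:
            deltas = [BUILDING_BLOCKS["gastrodinyl"].delta] * g
            for name, k in optional.items():
                deltas.extend([BUILDING_BLOCKS[name].delta] * k)
            formula = combine_ester(CITRIC_ACID, deltas)
            subs = (("gastrodinyl", g),) + tuple(
                (n, k) for n, k in sorted(optional.items()) if k
            )
            raw.append(
                CandidateCompound(
                    name=_canonical_name(g, optional),
                    formula=formula,
                    compound_class="parishin derivative",
                    substituents=subs,
                    provenance="enumerated",
                )
            )

    if deduplicate:
        best: dict[tuple, CandidateCompound] = {}
        for cand in raw:
            key = cand.formula.counts
            incumbent = best.get(key)
            if incumbent is None or cand.n_substituents < incumbent.n_substituents:
                best[key] = cand
        raw = list(best.values())
    return sorted(raw, key=lambda c: (c.mass, c.name))


def load_library(path: str | Path) -> list[CandidateCompound]:
    """Read a compound-library CSV (name, formula, class, trust)."""
    out: list[CandidateCompound] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "formula", "class", "trust"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"library CSV must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                formula = ElementalFormula.parse(row["formula"])
            except ValueError as exc:
                raise ValueError(f"row {i} ({row.get('name')!r}): {exc}") from exc
            out.append(
                CandidateCompound(
                    name=row["name"].strip(),
                    formula=formula,
                    compound_class=row["class"].strip(),
                    provenance="library",
                    trust=row["trust"].strip(),
                )
            )
    return out


def default_library() -> list[CandidateCompound]:
    """The bundled curated library of non-parishin metabolites."""
    ref = resources.files("gastrodia_ms.data").joinpath("library.csv")
    with resources.as_file(ref) as path:
        return load_library(path)


def default_candidates() -> list[CandidateCompound]:
    """Library plus the fully enumerated parishin family, sorted by mass."""
    cands = default_library() + enumerate_parishin_family()
    return sorted(cands, key=lambda c: (c.mass, c.name))
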