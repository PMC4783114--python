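"""Elemental-formula algebra, monoisotopic masses and adduct ion m/z.

Everything downstream of the mass spectrometer reduces to arithmetic on
elemental compositions: a candidate structure is a formula, an adduct shifts
its neutral monoisotopic mass by a fixed delta, and an identification is a
relative (ppm) comparison between a theoretical and an observed m/z.  This
module keeps that arithmetic in one place, backed by a single bundled table
of IUPAC monoisotopic atomic masses, so every m/z printed anywhere in the
pipeline traces back to the same constants.

Ion arithmetic uses the proton-mass convention (±1.007276 Da for protonation/
deprotonation): electron mass is then handled implicitly, which reproduces
the instrument's singly charged ion positions to well under 1 ppm.  All ions
are treated as singly charged.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASSES",
    "PROTON_MASS",
    "ElementalFormula",
    "Adduct",
    "ADDUCTS",
    "monoisotopic_mass",
    "ion_mz",
    "neutral_mass",
    "ppm_error",
    "nominal_mw",
]


def _load_atomic_masses() -> dict[str, float]:
    ref = resources.files("gastrodia_ms.data").joinpath("atomic_masses.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return {row["element"]: float(row["monoisotopic_mass"]) for row in csv.DictReader(fh)}


#: Monoisotopic atomic masses (Da), loaded once from the bundled resource.
ATOMIC_MASSES: Mapping[str, float] = _load_atomic_masses()

#: Mass of a proton in Da (H atom minus electron).
PROTON_MASS = 1.007276466

_ELEMENT_ORDER = ("C", "H", "N", "O", "S", "Na")


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts over C, H, N, O, S, Na.

    Supports element-wise addition/subtraction; subtraction that would drive
    any count negative raises ``ValueError``.
    """

    counts: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for element, n in dict(self.counts).items():
            if element not in ATOMIC_MASSES:
                raise ValueError(f"unknown element {element!r}")
            if n < 0:
                raise ValueError(f"negative count for {element}: {n}")
            if int(n) != n:
                raise ValueError(f"non-integer count for {element}: {n}")
            if n:
                cleaned[element] = int(n)
        ordered = tuple((e, cleaned[e]) for e in _ELEMENT_ORDER if e in cleaned)
        object.__setattr__(self, "counts", ordered)

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(counts.items()))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C13H18O7``."""
        counts: dict[str, int] = {}
        i, s = 0, text.strip()
        if not s:
            return cls()
        while i < len(s):
            if not s[i].isalpha() or not s[i].isupper():
                raise ValueError(f"cannot parse formula {text!r} at position {i}")
            sym = s[i]
            i += 1
            if i < len(s) and s[i].islower():
                sym += s[i]
                i += 1
            if sym not in ATOMIC_MASSES:
                raise ValueError(f"unknown element {sym!r} in formula {text!r}")
            j = i
            while j < len(s) and s[j].isdigit():
                j += 1
            counts[sym] = counts.get(sym, 0) + (int(s[i:j]) if j > i else 1)
            i = j
        return cls.from_dict(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        a, b = self.as_dict(), other.as_dict()
        return ElementalFormula.from_dict(
            {e: a.get(e, 0) + b.get(e, 0) for e in set(a) | set(b)}
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        a, b = self.as_dict(), other.as_dict()
        out = {e: a.get(e, 0) - b.get(e, 0) for e in set(a) | set(b)}
        bad = [e for e, n in out.items() if n < 0]
        if bad:
            raise ValueError(f"subtraction yields negative counts for {sorted(bad)}")
        return ElementalFormula.from_dict(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalFormula.from_dict({e: n * k for e, n in self.counts})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __str__(self) -> str:
        return "".join(f"{e}{n if n != 1 else ''}" for e, n in self.counts) or "∅"


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Sum of count × monoisotopic atomic mass over the formula, in Da."""
    return sum(n * ATOMIC_MASSES[e] for e, n in formula.counts)


def combine_ester(
    core: ElementalFormula, substituents: Iterable[ElementalFormula]
) -> ElementalFormula:
    """Element-wise sum of a core and pre-condensed residue deltas.

    Residues are expected water-free (the condensation water is already
    removed from each delta), so ester formation is plain addition.
    """
    out = core
    for sub in substituents:
        out = out + sub
    return out


@dataclass(frozen=True)
class Adduct:
    """A singly charged ion species: name, polarity and mass delta (Da)."""

    name: str
    polarity: int  # +1 or -1
    delta: float

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")


#: The four ion species observed in the survey, keyed by name.
ADDUCTS: Mapping[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +1, +PROTON_MASS),
    "[M+Na]+": Adduct("[M+Na]+", +1, +22.989218),
    "[M-H]-": Adduct("[M-H]-", -1, -PROTON_MASS),
    "[M+HCOO]-": Adduct("[M+HCOO]-", -1, +44.998201),
}


def get_adduct(name: str) -> Adduct:
    # tolerate the typographic minus used in printed tables
    key = name.replace("−", "-").replace("[M-H]−", "[M-H]-")
    if key not in ADDUCTS:
        raise KeyError(f"unknown adduct {name!r}; known: {sorted(ADDUCTS)}")
    return ADDUCTS[key]


def ion_mz(mass: float, adduct: Adduct | str) -> float:
    """m/z of the singly charged ion for a neutral monoisotopic mass."""
    if mass <= 0:
        raise ValueError("neutral mass must be positive")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return mass + adduct.delta


def neutral_mass(mz: float, adduct: Adduct | str) -> float:
    """Invert :func:`ion_mz`: neutral mass implied by an observed m/z."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return mz - adduct.delta


def ppm_error(theoretical: float, observed: float) -> float:
    """Signed relative error, 1e6 × (observed − theoretical) / theoretical."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def nominal_mw(mass: float) -> int:
    """Nominal molecular weight: monoisotopic mass rounded half-up."""
    if mass < 0:
        raise ValueError("mass must be non-negative")
    return int(math.floor(mass + 0.5))
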