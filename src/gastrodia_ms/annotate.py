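"""Precursor matching within a ppm gate and neutral-loss fragment explanation.

Identification follows the survey's two-step logic.  First, each precursor
m/z is compared against every (candidate, adduct) pair of matching polarity
and kept when the relative error is inside the gate (default 5 ppm).  Second,
each fragment peak is explained as the precursor ion minus a multiset of
characteristic neutral losses — water, CO2, and the moiety losses that the
candidate's structure licenses (268 Da gastrodinyl, 162 Da glucosyl, 106 Da
p-hydroxybenzyl, 132 Da ribosyl for nucleosides, 75/147 Da glycyl/glutamyl
for glutathione conjugates, 30/14 Da for methoxy/methyl decorations).

Loss applicability is structural: a gastrodinyl loss needs a gastrodinyl
substituent, and because a gastrodinyl residue is itself glucosyl +
p-hydroxybenzyl (268.0947 = 162.0528 + 106.0419 exactly), each gastrodinyl
also licenses one glucosyl and one p-hydroxybenzyl partial loss.  Formate
adducts may shed HCOOH (46.0055 Da), which is how [M+HCOO]- precursors reach
the [M-H]- fragment manifold.  Negative-mode paths may additionally carry an
H2 deficit (the "[M-3H-...]" ions seen for parishins); the deficit is not
counted toward search depth, mirroring how the assignments are written.

There is no randomness anywhere: ties are broken by documented sort keys.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .chemcore import (
    ADDUCTS,
    Adduct,
    ElementalFormula,
    get_adduct,
    ion_mz,
    monoisotopic_mass,
    nominal_mw,
    ppm_error,
)
from .compound_space import CandidateCompound
from .spectra_io import Spectrum

__all__ = [
    "NeutralLoss",
    "NEUTRAL_LOSSES",
    "H2_MASS",
    "PrecursorHit",
    "FragmentAnnotation",
    "AnnotationResult",
    "AnnotateConfig",
    "match_precursor",
    "explain_fragments",
    "annotate_dataset",
    "export_loss_dictionary",
]

#: Mass of the H2 deficit carried by "[M-3H-...]" negative ions.
H2_MASS = 2 * 1.00782503207


@dataclass(frozen=True)
class NeutralLoss:
    """A characteristic neutral loss with a structural applicability rule.

    ``applicability(candidate)`` returns the maximum number of times the loss
    may occur for that candidate (0 = not licensed).
    """

    name: str
    delta: ElementalFormula
    applicability: Callable[[CandidateCompound], int]
    label: str  # token used in assignment strings, e.g. "268" or "H2O"

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.delta)


def _n(block: str) -> Callable[[CandidateCompound], int]:
    return lambda c: c.substituent_count(block)


def _glucosyl_cap(c: CandidateCompound) -> int:
    cap = c.substituent_count("glucosyl") + c.substituent_count("gastrodinyl")
    if c.compound_class == "gastrodin":
        cap += 1
    return cap


def _hydroxybenzyl_cap(c: CandidateCompound) -> int:
    cap = c.substituent_count("p-hydroxybenzyl") + c.substituent_count("gastrodinyl")
    if c.compound_class == "S-(4-hydroxybenzyl)-glutathione":
        cap += 2  # S-benzyl plus a possible N-benzyl decoration
    if c.compound_class == "gastrodin":
        cap += 1
    return cap


NEUTRAL_LOSSES: dict[str, NeutralLoss] = {
    loss.name: loss
    for loss in (
        NeutralLoss("H2O", ElementalFormula.parse("H2O"), lambda c: 2, "H2O"),
        NeutralLoss("CO2", ElementalFormula.parse("CO2"), lambda c: 2, "CO2"),
        NeutralLoss("CH2O", ElementalFormula.parse("CH2O"), _n("methoxy"), "30"),
        NeutralLoss("CH2", ElementalFormula.parse("CH2"), _n("methyl"), "14"),
        NeutralLoss(
            "ribosyl",
            ElementalFormula.parse("C5H8O4"),
            lambda c: 1 if c.compound_class == "nucleoside" else 0,
            "132",
        ),
        NeutralLoss("hydroxybenzyl", ElementalFormula.parse("C7H6O"), _hydroxybenzyl_cap, "106"),
        NeutralLoss("glucosyl", ElementalFormula.parse("C6H10O5"), _glucosyl_cap, "162"),
        NeutralLoss("gastrodinyl", ElementalFormula.parse("C13H16O6"), _n("gastrodinyl"), "268"),
        NeutralLoss(
            "glycyl",
            ElementalFormula.parse("C2H5NO2"),
            lambda c: 1 if c.compound_class == "S-(4-hydroxybenzyl)-glutathione" else 0,
            "75",
        ),
        NeutralLoss(
            "glutamyl",
            ElementalFormula.parse("C5H9NO4"),
            lambda c: 1 if c.compound_class == "S-(4-hydroxybenzyl)-glutathione" else 0,
            "147",
        ),
        # formic acid, licensed per-adduct (formate precursors only), see below
        NeutralLoss("HCOOH", ElementalFormula.parse("CH2O2"), lambda c: 0, "HCOOH"),
    )
}


def export_loss_dictionary(path: str | Path) -> None:
    """Write the registered loss dictionary as a CSV resource."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "formula", "mass", "applicability"])
        notes = {
            "H2O": "any candidate, up to 2x",
            "CO2": "any candidate, up to 2x",
            "CH2O": "per methoxy substituent",
            "CH2": "per methyl substituent",
            "ribosyl": "nucleosides only",
            "hydroxybenzyl": "per p-hydroxybenzyl or gastrodinyl unit; glutathione conjugates",
            "glucosyl": "per glucosyl or gastrodinyl unit; gastrodin",
            "gastrodinyl": "per gastrodinyl unit",
            "glycyl": "glutathione conjugates only",
            "glutamyl": "glutathione conjugates only",
            "HCOOH": "[M+HCOO]- precursors only",
        }
        for loss in NEUTRAL_LOSSES.values():
            writer.writerow([loss.name, str(loss.delta), f"{loss.mass:.6f}", notes[loss.name]])


@dataclass(frozen=True)
class PrecursorHit:
    candidate: CandidateCompound
    adduct: Adduct
    ppm: float


def match_precursor(
    spectrum: Spectrum,
    candidates: Sequence[CandidateCompound],
    adducts: Sequence[Adduct] | None = None,
    gate_ppm: float = 5.0,
) -> list[PrecursorHit]:
    """All (candidate, adduct) pairs within the ppm gate, sorted by |ppm|."""
    if gate_ppm <= 0:
        raise ValueError("gate_ppm must be positive")
    if adducts is None:
        adducts = list(ADDUCTS.values())
    adducts = [a for a in adducts if a.polarity == spectrum.polarity]
    hits = []
    for cand in candidates:
        for adduct in adducts:
            ppm = ppm_error(ion_mz(cand.mass, adduct), spectrum.precursor_mz)
            if abs(ppm) <= gate_ppm:
                hits.append(PrecursorHit(cand, adduct, ppm))
    return sorted(hits, key=lambda h: (abs(h.ppm), h.candidate.name, h.adduct.name))


@dataclass(frozen=True)
class FragmentAnnotation:
    """One fragment peak with its best loss-path explanation (if any)."""

    mz: float
    intensity: float
    losses: tuple[str, ...] = ()  # loss names, sorted; empty = precursor itself
    h2_deficit: bool = False
    predicted_mz: float | None = None
    residual: float | None = None  # observed - predicted, Da

    @property
    def explained(self) -> bool:
        return self.predicted_mz is not None

    def path_string(self, adduct: Adduct) -> str:
        """Render the assignment in the field's bracket notation."""
        if not self.explained:
            return ""
        base = {"[M+H]+": "M+H", "[M+Na]+": "M+Na", "[M-H]-": "M-H", "[M+HCOO]-": "M+HCOO"}[
            adduct.name
        ]
        if self.h2_deficit:
            base = base.replace("M-H", "M-3H") if "M-H" in base else base + "-H2"
        tokens = "".join(f"-{NEUTRAL_LOSSES[name].label}" for name in self.losses)
        sign = "+" if adduct.polarity > 0 else "-"
        return f"[{base}{tokens}]{sign}"


def _loss_multisets(
    caps: list[tuple[str, float, int]], max_depth: int
) -> Iterable[tuple[tuple[str, ...], float]]:
    """Yield every loss multiset up to max_depth respecting per-loss caps."""

    def rec(i: int, depth_left: int, chosen: tuple[str, ...], total: float):
        yield chosen, total
        for j in range(i, len(caps)):
            name, mass, cap = caps[j]
            used = sum(1 for c in chosen if c == name)
            if depth_left > 0 and used < cap:
                yield from rec(j, depth_left - 1, chosen + (name,), total + mass)

    yield from rec(0, max_depth, (), 0.0)


def explain_fragments(
    spectrum: Spectrum,
    candidate: CandidateCompound,
    adduct: Adduct | str,
    losses: dict[str, NeutralLoss] | None = None,
    frag_tol_da: float = 0.01,
    max_depth: int = 5,
) -> list[FragmentAnnotation]:
    """Explain each fragment as precursor-ion minus a multiset of losses.

    Search is exhaustive over multisets of applicable losses of size up to
    ``max_depth`` (each loss up to its structural multiplicity; H2O/CO2 up to
    2x), optionally carrying an H2 deficit in negative mode.  Among competing
    explanations the shortest path wins, then no-H2 before H2, then the
    smallest |residual|, then lexicographic order.  Unexplained fragments are
    returned with an empty path.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if frag_tol_da <= 0:
        raise ValueError("frag_tol_da must be positive")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    registry = losses if losses is not None else NEUTRAL_LOSSES

    caps = []
    for loss in registry.values():
        cap = loss.applicability(candidate)
        if loss.name == "HCOOH" and adduct.name == "[M+HCOO]-":
            cap = max(cap, 1)
        if cap > 0:
            caps.append((loss.name, loss.mass, cap))
    caps.sort()

    precursor_theo = ion_mz(candidate.mass, adduct)
    h2_options = (False, True) if adduct.polarity < 0 else (False,)

    # precompute all candidate paths once; fragment lists are short
    paths: list[tuple[tuple[str, ...], bool, float]] = []
    for multiset, total in _loss_multisets(caps, max_depth):
        for h2 in h2_options:
            paths.append((multiset, h2, precursor_theo - total - (H2_MASS if h2 else 0.0)))

    out: list[FragmentAnnotation] = []
    for peak in spectrum.fragments:
        best: tuple | None = None
        for multiset, h2, predicted in paths:
            residual = peak.mz - predicted
            if abs(residual) > frag_tol_da:
                continue
            key = (len(multiset), h2, abs(residual), multiset)
            if best is None or key < best[0]:
                best = (key, multiset, h2, predicted, residual)
        if best is None:
            out.append(FragmentAnnotation(peak.mz, peak.intensity))
        else:
            _, multiset, h2, predicted, residual = best
            out.append(
                FragmentAnnotation(
                    peak.mz, peak.intensity, tuple(sorted(multiset)), h2, predicted, residual
                )
            )
    return out


@dataclass(frozen=True)
class AnnotationResult:
    """Top-ranked identification of one spectrum."""

    spectrum_id: str
    candidate: CandidateCompound
    adduct: Adduct
    theoretical_mz: float
    observed_mz: float
    ppm: float
    fragments: tuple[FragmentAnnotation, ...]
    rt_min: float | None = None
    rank: int = 1
    confidence: str = "accurate-mass"  # accurate-mass | nominal
    label: str = ""  # candidate name, possibly with an isomer suffix

    @property
    def score(self) -> float:
        """Fraction of fragments explained (vacuously 1 with no fragments)."""
        if not self.fragments:
            return 1.0
        return sum(f.explained for f in self.fragments) / len(self.fragments)

    def to_record(self) -> dict:
        return {
            "spectrum_id": self.spectrum_id,
            "label": self.label or self.candidate.name,
            "candidate": self.candidate.name,
            "compound_class": self.candidate.compound_class,
            "adduct": self.adduct.name,
            "theoretical_mz": f"{self.theoretical_mz:.4f}",
            "observed_mz": f"{self.observed_mz:.4f}",
            "ppm": f"{self.ppm:.1f}",
            "score": f"{self.score:.3f}",
            "confidence": self.confidence,
            "n_fragments": len(self.fragments),
            "n_explained": sum(f.explained for f in self.fragments),
            "loss_paths": "; ".join(
                f"{f.mz:.2f}{f.path_string(self.adduct)}"
                for f in self.fragments
                if f.explained
            ),
        }


@dataclass(frozen=True)
class AnnotateConfig:
    gate_ppm: float = 5.0
    frag_tol_da: float = 0.01
    max_depth: int = 5
    nominal_fallback: bool = True


def annotate_dataset(
    spectra: Sequence[Spectrum],
    candidates: Sequence[CandidateCompound],
    config: AnnotateConfig = AnnotateConfig(),
) -> tuple[list[AnnotationResult], dict]:
    """Annotate every spectrum with its top-ranked (candidate, adduct) hit.

    Hits within the ppm gate are ranked by fragment score (desc), then |ppm|
    (asc), then fewer substituents, then name.  Spectra with no gated hit may
    fall back to a nominal-(integer)-mass match against low-trust library
    entries — the survey's small polar metabolites whose printed masses
    preserve only the integer part; such results are flagged
    ``confidence="nominal"``.  Identical (candidate, adduct) results at
    different retention times get ``isomer-k`` labels in RT order.
    """
    results: list[AnnotationResult] = []
    for spectrum in spectra:
        hits = match_precursor(spectrum, candidates, gate_ppm=config.gate_ppm)
        scored = []
        for hit in hits:
            frags = explain_fragments(
                spectrum, hit.candidate, hit.adduct,
                frag_tol_da=config.frag_tol_da, max_depth=config.max_depth,
            )
            res = AnnotationResult(
                spectrum_id=spectrum.identifier,
                candidate=hit.candidate,
                adduct=hit.adduct,
                theoretical_mz=ion_mz(hit.candidate.mass, hit.adduct),
                observed_mz=spectrum.precursor_mz,
                ppm=hit.ppm,
                fragments=tuple(frags),
                rt_min=spectrum.rt_min,
            )
            scored.append(res)
        scored.sort(
            key=lambda r: (-r.score, abs(r.ppm), r.candidate.n_substituents, r.candidate.name)
        )
        if scored:
            results.append(scored[0])
            continue
        if config.nominal_fallback:
            fallback = _nominal_match(spectrum, candidates, config)
            if fallback is not None:
                results.append(fallback)

    results = _label_isomers(results)
    summary = {
        "n_spectra": len(spectra),
        "n_annotated": len(results),
        "n_nominal": sum(r.confidence == "nominal" for r in results),
        "per_class": _per_class_counts(results),
    }
    return results, summary


def _nominal_match(
    spectrum: Spectrum, candidates: Sequence[CandidateCompound], config: AnnotateConfig
) -> AnnotationResult | None:
    pool = [c for c in candidates if c.provenance == "library" and c.trust == "low"]
    adducts = [a for a in ADDUCTS.values() if a.polarity == spectrum.polarity]
    best: AnnotationResult | None = None
    for cand in pool:
        for adduct in adducts:
            theo = ion_mz(cand.mass, adduct)
            if nominal_mw(theo) != nominal_mw(spectrum.precursor_mz):
                continue
            frags = explain_fragments(
                spectrum, cand, adduct,
                frag_tol_da=config.frag_tol_da, max_depth=config.max_depth,
            )
            res = AnnotationResult(
                spectrum_id=spectrum.identifier,
                candidate=cand,
                adduct=adduct,
                theoretical_mz=theo,
                observed_mz=spectrum.precursor_mz,
                ppm=ppm_error(theo, spectrum.precursor_mz),
                fragments=tuple(frags),
                rt_min=spectrum.rt_min,
                confidence="nominal",
            )
            if best is None or abs(res.observed_mz - res.theoretical_mz) < abs(
                best.observed_mz - best.theoretical_mz
            ):
                best = res
    return best


def _label_isomers(results: list[AnnotationResult]) -> list[AnnotationResult]:
    from collections import defaultdict
    from dataclasses import replace

    groups: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, res in enumerate(results):
        groups[(res.candidate.name, res.adduct.name)].append(i)

    out = list(results)
    for indices in groups.values():
        if len(indices) == 1:
            out[indices[0]] = replace(out[indices[0]], label=out[indices[0]].candidate.name)
            continue
        by_rt = sorted(indices, key=lambda i: (results[i].rt_min if results[i].rt_min is not None else float("inf"), i))
        for k, i in enumerate(by_rt, start=1):
            name = results[i].candidate.name
            out[i] = replace(out[i], label=name if k == 1 else f"{name} isomer-{k}")
    return out


def _per_class_counts(results: Sequence[AnnotationResult]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for res in results:
        counts[res.candidate.compound_class] = counts.get(res.candidate.compound_class, 0) + 1
    return dict(sorted(counts.items()))
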