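"""Seeded generators for spectra, calibration series and cultivar matrices.

Every downstream stage can be exercised without instrument data: the
generators emit inputs with the statistical structure the pipeline assumes —
precursors displaced by ppm-scale Gaussian mass error, fragments produced by
the registered neutral losses and thinned by dropout, calibration dilution
series with additive response noise, and an 8-cultivar × 3-replicate × 5-
class concentration matrix with planted geographic group structure (four
groups: one high in amino acids and nucleosides, one high in the glutathione
conjugate and gastrodin, one moderately high in amino acids, one uniformly
low).  Each generator also returns a ground-truth table sufficient to score
the stage that consumes its output.

All randomness flows from ``SynthConfig.seed`` through one
``numpy.random.default_rng``; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import NEUTRAL_LOSSES, _loss_multisets
from .chemcore import ion_mz
from .compound_space import CandidateCompound
from .spectra_io import FragmentPeak, Spectrum

__all__ = ["SynthConfig", "CULTIVAR_GROUPS", "gen_spectra", "gen_calibration", "gen_cultivar_matrix"]

#: Cultivar -> planted geographic group (structure mirrors the survey design:
#: 8 cultivars from 4 provinces falling into 4 concentration-profile groups).
CULTIVAR_GROUPS = {
    "cultivar-1": "IV",
    "cultivar-2": "III",
    "cultivar-3": "IV",
    "cultivar-4": "I",
    "cultivar-5": "II",
    "cultivar-6": "I",
    "cultivar-7": "III",
    "cultivar-8": "IV",
}

_CLASSES = (
    "amino acid",
    "nucleoside",
    "S-(4-hydroxybenzyl)-glutathione",
    "gastrodin",
    "parishin derivative",
)

#: Baseline class concentrations (µg/mL of extract) and multiplicative group
#: effects on designated classes.
_BASELINE = {
    "amino acid": 2.0,
    "nucleoside": 0.8,
    "S-(4-hydroxybenzyl)-glutathione": 0.5,
    "gastrodin": 8.0,
    "parishin derivative": 40.0,
}
_GROUP_EFFECTS = {
    "I": {"amino acid": 4.0, "nucleoside": 4.0},
    "II": {"S-(4-hydroxybenzyl)-glutathione": 5.0, "gastrodin": 3.0},
    "III": {"amino acid": 2.5},
    "IV": {cls: 0.5 for cls in _CLASSES},
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for all three generators; the defaults are the study conditions."""

    seed: int = 0
    # spectra
    mass_error_ppm: float = 1.0
    fragment_dropout: float = 0.1
    intensity_sigma: float = 0.5  # log-normal shape of fragment intensities
    fragment_depth: int = 3
    # calibration (defaults mirror a gastrodin-like standard)
    cal_levels: int = 6
    cal_replicates: int = 3
    cal_slope: float = 79899.0
    cal_intercept: float = -1108.1
    cal_low: float = 8.89
    cal_high: float = 44.48
    cal_noise_sd: float = 500.0
    # cultivar matrix
    n_replicates: int = 3
    within_cv: float = 0.15
    group_effects: dict = field(default_factory=lambda: _GROUP_EFFECTS)
    structural_zero: bool = True  # gastrodin absent in cultivar-7

    def __post_init__(self) -> None:
        if self.mass_error_ppm < 0 or self.intensity_sigma < 0 or self.within_cv < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.fragment_dropout <= 1:
            raise ValueError("fragment_dropout must be a probability")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def gen_spectra(
    config: SynthConfig,
    candidates: list[CandidateCompound],
    adduct_name: str = "[M-H]-",
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate one spectrum per candidate plus a ground-truth table.

    Precursor m/z = theoretical × (1 + ε/1e6) with ε ~ N(0, σ_ppm); the
    fragment list is every licensed loss path to the configured depth,
    thinned by the dropout probability, with log-normal intensities and the
    same relative mass-error model.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    truth_rows = []
    for i, cand in enumerate(candidates):
        theo = ion_mz(cand.mass, adduct_name)
        precursor = theo * (1 + rng.normal(0, config.mass_error_ppm) / 1e6)
        caps = sorted(
            (loss.name, loss.mass, cap)
            for loss in NEUTRAL_LOSSES.values()
            if (cap := loss.applicability(cand)) > 0
        )
        frags = []
        for multiset, total in _loss_multisets(caps, config.fragment_depth):
            if not multiset:
                continue
            if rng.random() < config.fragment_dropout:
                continue
            mz = (theo - total) * (1 + rng.normal(0, config.mass_error_ppm) / 1e6)
            if mz <= 50:
                continue
            frags.append(FragmentPeak(mz, float(rng.lognormal(4.0, config.intensity_sigma))))
        sid = f"synth-{i + 1:03d}"
        spectra.append(
            Spectrum(
                identifier=sid,
                precursor_mz=float(precursor),
                polarity=-1 if adduct_name.endswith("-") else 1,
                rt_min=float(1.0 + i),
                fragments=tuple(frags),
            )
        )
        truth_rows.append(
            {
                "spectrum_id": sid,
                "candidate": cand.name,
                "compound_class": cand.compound_class,
                "adduct": adduct_name,
                "theoretical_mz": theo,
                "n_fragments": len(frags),
            }
        )
    return spectra, pd.DataFrame(truth_rows)


def gen_calibration(config: SynthConfig, standard: str = "standard") -> pd.DataFrame:
    """Dilution-series responses y = slope·x + intercept + N(0, σ)."""
    if config.cal_levels < 3:
        raise ValueError("need at least 3 calibration levels")
    if config.cal_low <= 0 or config.cal_high <= config.cal_low:
        raise ValueError("calibration range must be positive and ordered")
    rng = np.random.default_rng(config.seed)
    conc = np.geomspace(config.cal_low, config.cal_high, config.cal_levels)
    rows = []
    for level, x in enumerate(conc, start=1):
        for rep in range(1, config.cal_replicates + 1):
            y = config.cal_slope * x + config.cal_intercept + rng.normal(0, config.cal_noise_sd)
            rows.append(
                {
                    "standard": standard,
                    "level": level,
                    "replicate": rep,
                    "concentration": float(x),
                    "response": float(y),
                }
            )
    return pd.DataFrame(rows)


def gen_cultivar_matrix(config: SynthConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Cultivar × replicate class-concentration matrix with planted groups.

    Returns (matrix, labels): matrix is (8 × n_replicates) samples by the 5
    classes; labels gives each sample's planted group.  Within-group spread
    is log-normal with the configured CV; optionally gastrodin is structurally
    absent in cultivar-7 (the survey's red cultivar from Shanxi).
    """
    groups = set(config.group_effects)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log(1 + config.within_cv**2))
    rows, labels = [], {}
    for cultivar, group in CULTIVAR_GROUPS.items():
        effects = config.group_effects.get(group, {})
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cultivar}-r{rep}"
            labels[sample] = group
            row = {}
            for cls in _CLASSES:
                mean = _BASELINE[cls] * effects.get(cls, 1.0)
                value = mean * rng.lognormal(-(sigma**2) / 2, sigma)
                if (
                    config.structural_zero
                    and cultivar == "cultivar-7"
                    and cls == "gastrodin"
                ):
                    value = 0.0
                row[cls] = value
            rows.append(pd.Series(row, name=sample))
    matrix = pd.DataFrame(rows)
    return matrix, pd.Series(labels, name="group")
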