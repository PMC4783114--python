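"""Analytical method-validation statistics.

Implements the validation scheme of a UPLC quantification method: ordinary
least-squares calibration with r², limits of detection and quantification
read off a signal-to-noise dilution series (S/N 3 and 10), intra-/inter-day
precision as relative standard deviation (RSD = SD/mean × 100, sample SD),
and spiked recovery ((detected − original)/spiked × 100).

LOD/LOQ follow the serial-dilution definition — concentration is
log-log-interpolated at the target S/N — matching how the values are read
off the instrument; the common 3.3·σ/slope shortcut is provided separately
and labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "PrecisionSummary",
    "RecoveryResult",
    "fit_calibration",
    "lod_loq_from_sn",
    "lod_loq_from_sigma_slope",
    "rsd",
    "precision_summary",
    "recovery",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear calibration y = slope·x + intercept with working range (µg/mL)."""

    standard: str
    slope: float
    intercept: float
    r2: float
    range_low: float | None = None
    range_high: float | None = None
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.r2 <= 1:
            raise ValueError("r² must lie in [0, 1]")
        if self.lod is not None and self.loq is not None and self.lod >= self.loq:
            raise ValueError("LOD must be below LOQ")
        if self.range_low is not None and self.range_high is not None:
            if not 0 < self.range_low < self.range_high:
                raise ValueError("linear range endpoints must be positive and ordered")

    def response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(
    concentrations: Sequence[float],
    responses: Sequence[float],
    standard: str = "",
) -> CalibrationModel:
    """OLS fit of peak area on concentration; r² is squared Pearson r."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.unique(x).size < 2 or np.allclose(y, y[0]):
        raise ValueError("degenerate calibration: zero variance in x or y")
    fit = stats.linregress(x, y)
    return CalibrationModel(
        standard=standard,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        range_low=float(x.min()),
        range_high=float(x.max()),
    )


def lod_loq_from_sn(
    series: Sequence[tuple[float, float]],
    lod_sn: float = 3.0,
    loq_sn: float = 10.0,
) -> tuple[float, float]:
    """Interpolate the concentrations at S/N = 3 and S/N = 10 (log-log)."""
    pts = sorted(series)
    if len(pts) < 2:
        raise ValueError("need at least 2 (concentration, S/N) points")
    conc = np.array([p[0] for p in pts], dtype=float)
    sn = np.array([p[1] for p in pts], dtype=float)
    if np.any(conc <= 0) or np.any(sn <= 0):
        raise ValueError("concentrations and S/N must be positive")
    if np.any(np.diff(sn) <= 0):
        raise ValueError("S/N must increase strictly with concentration")

    def at(target: float) -> float:
        if not sn[0] <= target <= sn[-1]:
            raise ValueError(
                f"target S/N {target} outside observed span [{sn[0]}, {sn[-1]}]"
            )
        return float(np.exp(np.interp(np.log(target), np.log(sn), np.log(conc))))

    return at(lod_sn), at(loq_sn)


def lod_loq_from_sigma_slope(residual_sd: float, slope: float) -> tuple[float, float]:
    """The 3.3·σ/slope and 10·σ/slope variant (explicitly not the S/N method)."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return 3.3 * residual_sd / abs(slope), 10.0 * residual_sd / abs(slope)


def rsd(mean: float, sd: float) -> float:
    """Relative standard deviation, SD/mean × 100 (%)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("SD must be non-negative")
    return sd / mean * 100.0


@dataclass(frozen=True)
class PrecisionSummary:
    standard: str
    design: str  # "intra" (n=6) or "inter" (n=3)
    level: str  # low / middle / high
    mean: float
    sd: float
    rsd: float

    def __post_init__(self) -> None:
        if self.rsd < 0:
            raise ValueError("RSD must be non-negative")


def precision_summary(
    replicates: Sequence[float],
    standard: str = "",
    design: str = "intra",
    level: str = "",
) -> PrecisionSummary:
    """Mean, sample SD (n−1) and RSD of replicate determinations."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return PrecisionSummary(standard, design, level, mean, sd, rsd(mean, sd))


@dataclass(frozen=True)
class RecoveryResult:
    standard: str
    initial: float
    added: float
    detected_mean: float
    detected_sd: float
    recovery_pct: float
    rsd_pct: float


def recovery(detected_total: float, original: float, spiked: float) -> float:
    """Spiked recovery %, (detected − original) / spiked × 100."""
    if spiked <= 0:
        raise ValueError("spiked amount must be positive")
    return (detected_total - original) / spiked * 100.0


def recovery_result(
    initial: float,
    added: float,
    detected_mean: float,
    detected_sd: float,
    standard: str = "",
) -> RecoveryResult:
    rec = recovery(detected_mean, initial, added)
    rec_sd = detected_sd / added * 100.0
    return RecoveryResult(
        standard, initial, added, detected_mean, detected_sd,
        rec, (rec_sd / rec * 100.0) if rec > 0 else float("nan"),
    )
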