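"""Surrogate-standard quantification and aggregation into compound classes.

Only four reference standards are available (gastrodin, parishin E,
parishin B, parishin).  Every other annotated compound is quantified
semi-quantitatively against a surrogate: parishin for the parishin
derivatives, gastrodin for everything else.  Each reported concentration
therefore carries the name of the standard actually used.

Class profiles aggregate per-sample concentrations into the five statistical
groups used downstream (amino acids, nucleosides,
S-(4-hydroxybenzyl)-glutathione, gastrodin, parishin derivatives); compounds
absent from a sample contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .validation import CalibrationModel

__all__ = [
    "QUANT_CLASSES",
    "SurrogateMap",
    "QuantifiedCompound",
    "quantify",
    "class_profile",
]

#: The five statistical groups of the quantification stage (no "other").
QUANT_CLASSES = (
    "amino acid",
    "nucleoside",
    "S-(4-hydroxybenzyl)-glutathione",
    "gastrodin",
    "parishin derivative",
)

#: Compounds with their own external standard, mapped to the standard's name.
_OWN_STANDARD = {
    "gastrodin": "gastrodin",
    "mono-substituted parishin": "parishin E",  # parishin E/H scaffold
    "di-substituted parishin": "parishin B",
    "parishin": "parishin",
}


@dataclass(frozen=True)
class SurrogateMap:
    """Resolve each compound to the calibration standard used to quantify it."""

    models: Mapping[str, CalibrationModel]
    overrides: Mapping[str, str] | None = None  # compound name -> standard name

    def standard_for(self, compound: str, compound_class: str) -> str:
        if self.overrides and compound in self.overrides:
            name = self.overrides[compound]
        elif compound in _OWN_STANDARD:
            name = _OWN_STANDARD[compound]
        elif compound_class == "parishin derivative":
            name = "parishin"
        else:
            name = "gastrodin"
        if name not in self.models:
            raise KeyError(f"no calibration model for standard {name!r} ({compound!r})")
        return name

    def model_for(self, compound: str, compound_class: str) -> CalibrationModel:
        return self.models[self.standard_for(compound, compound_class)]


@dataclass(frozen=True)
class QuantifiedCompound:
    sample: str
    compound: str
    compound_class: str
    area: float
    concentration: float
    standard: str
    extrapolated: bool
    semi_quantitative: bool  # True when a surrogate standard was used


def quantify(area: float, model: CalibrationModel) -> tuple[float, bool]:
    """Invert the calibration: x = (area − intercept)/slope.

    Returns (concentration, extrapolated); extrapolated is True when the
    concentration falls outside the model's linear range.
    """
    if model.slope == 0:
        raise ValueError("calibration slope must be nonzero")
    x = (area - model.intercept) / model.slope
    extrapolated = False
    if model.range_low is not None and model.range_high is not None:
        extrapolated = not (model.range_low <= x <= model.range_high)
    return x, extrapolated


def quantify_table(
    areas: pd.DataFrame,
    surrogates: SurrogateMap,
    class_of: Mapping[str, str],
) -> pd.DataFrame:
    """Quantify an areas table (columns: sample, compound, area).

    ``class_of`` maps compound name to its statistical class.
    """
    required = {"sample", "compound", "area"}
    if not required <= set(areas.columns):
        raise ValueError(f"areas table needs columns {sorted(required)}")
    records = []
    for row in areas.itertuples(index=False):
        cls = class_of.get(row.compound)
        if cls is None:
            raise KeyError(f"no class registered for compound {row.compound!r}")
        std = surrogates.standard_for(row.compound, cls)
        conc, extrapolated = quantify(row.area, surrogates.models[std])
        records.append(
            QuantifiedCompound(
                sample=row.sample,
                compound=row.compound,
                compound_class=cls,
                area=float(row.area),
                concentration=conc,
                standard=std,
                extrapolated=extrapolated,
                semi_quantitative=row.compound not in _OWN_STANDARD,
            )
        )
    return pd.DataFrame(records)


def class_profile(quantified: pd.DataFrame, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample 5-vector of summed class concentrations.

    Missing compounds contribute 0; unknown class labels raise.  Returns a
    DataFrame indexed by sample with one column per class in
    :data:`QUANT_CLASSES`.
    """
    unknown = set(quantified["compound_class"]) - set(QUANT_CLASSES)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    if (quantified["concentration"] < 0).any():
        raise ValueError("negative concentrations in quantified table")
    pivot = (
        quantified.pivot_table(
            index="sample", columns="compound_class", values="concentration",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(columns=list(QUANT_CLASSES), fill_value=0.0)
    )
    if samples is not None:
        pivot = pivot.reindex(index=list(samples), fill_value=0.0)
    pivot.columns.name = None
    return pivot
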