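"""Spectrum containers and readers/writers for MGF and CSV dialects.

The pipeline's unit of data is one precursor ion with its fragment peak
list.  MGF is parsed/written through :mod:`pyteomics.mgf`; the CSV dialect is
a long-format table (one row per fragment, spectrum metadata repeated) that
round-trips losslessly.  Polarity is inferred from the MGF CHARGE sign
("1-" → negative), since MGF has no standard polarity field.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from pyteomics import mgf as _mgf

__all__ = [
    "FragmentPeak",
    "Spectrum",
    "read_mgf",
    "write_mgf",
    "read_peaks_csv",
    "write_peaks_csv",
    "write_annotations",
]


@dataclass(frozen=True)
class FragmentPeak:
    """One fragment peak: m/z (Da) and relative intensity (arbitrary units)."""

    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"fragment m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("fragment intensity must be non-negative")


@dataclass(frozen=True)
class Spectrum:
    """One precursor with polarity, optional retention time and fragments."""

    identifier: str
    precursor_mz: float
    polarity: int  # +1 or -1
    rt_min: float | None = None
    fragments: tuple[FragmentPeak, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        object.__setattr__(
            self, "fragments", tuple(sorted(self.fragments, key=lambda p: p.mz))
        )


def _polarity_from_charge(charges, block: str) -> int:
    if not charges:
        raise ValueError(f"spectrum {block!r}: missing CHARGE sign (needed for polarity)")
    c = int(charges[0])
    if c == 0:
        raise ValueError(f"spectrum {block!r}: CHARGE of 0 carries no polarity")
    return 1 if c > 0 else -1


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak list; fragments are returned sorted, RT in minutes."""
    out: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"spectrum-{i + 1}"))
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"spectrum {title!r}: missing PEPMASS")
            polarity = _polarity_from_charge(params.get("charge"), title)
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else None
            frags = tuple(
                FragmentPeak(float(mz), float(inten))
                for mz, inten in zip(entry["m/z array"], entry["intensity array"])
            )
            out.append(
                Spectrum(
                    identifier=title,
                    precursor_mz=float(params["pepmass"][0]),
                    polarity=polarity,
                    rt_min=rt_min,
                    fragments=frags,
                )
            )
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (deterministic field order)."""
    entries = []
    for s in spectra:
        params = {
            "TITLE": s.identifier,
            "PEPMASS": s.precursor_mz,
            "CHARGE": "1+" if s.polarity > 0 else "1-",
        }
        if s.rt_min is not None:
            params["RTINSECONDS"] = round(s.rt_min * 60.0, 6)
        entries.append(
            {
                "params": params,
                "m/z array": [p.mz for p in s.fragments],
                "intensity array": [p.intensity for p in s.fragments],
            }
        )
    _mgf.write(entries, str(path), key_order=["TITLE", "PEPMASS", "CHARGE", "RTINSECONDS"])


_CSV_COLUMNS = ["id", "precursor_mz", "polarity", "rt_min", "fragment_mz", "fragment_intensity"]


def write_peaks_csv(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra in the long-format CSV dialect (one row per fragment)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for s in spectra:
            meta = [s.identifier, repr(s.precursor_mz), "+" if s.polarity > 0 else "-",
                    "" if s.rt_min is None else repr(s.rt_min)]
            if not s.fragments:
                writer.writerow(meta + ["", ""])
            for p in s.fragments:
                writer.writerow(meta + [repr(p.mz), repr(p.intensity)])


def read_peaks_csv(path: str | Path) -> list[Spectrum]:
    """Read the long-format spectra CSV written by :func:`write_peaks_csv`."""
    groups: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_COLUMNS:
            raise ValueError(f"peaks CSV must have columns {_CSV_COLUMNS}")
        for i, row in enumerate(reader, start=2):
            try:
                sid = row["id"]
                entry = groups.setdefault(
                    sid,
                    {
                        "precursor_mz": float(row["precursor_mz"]),
                        "polarity": {"+": 1, "-": -1}[row["polarity"]],
                        "rt_min": float(row["rt_min"]) if row["rt_min"] else None,
                        "fragments": [],
                    },
                )
                if row["fragment_mz"]:
                    entry["fragments"].append(
                        FragmentPeak(float(row["fragment_mz"]), float(row["fragment_intensity"]))
                    )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"peaks CSV row {i}: {exc}") from exc
    return [
        Spectrum(
            identifier=sid,
            precursor_mz=g["precursor_mz"],
            polarity=g["polarity"],
            rt_min=g["rt_min"],
            fragments=tuple(g["fragments"]),
        )
        for sid, g in groups.items()
    ]


_ANNOTATION_COLUMNS = [
    "spectrum_id", "label", "candidate", "compound_class", "adduct",
    "theoretical_mz", "observed_mz", "ppm", "score", "confidence",
    "n_fragments", "n_explained", "loss_paths",
]


def write_annotations(records: Iterable[Mapping], path: str | Path) -> None:
    """Write annotation records (see ``AnnotationResult.to_record``) as CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_ANNOTATION_COLUMNS, extrasaction="ignore")
        writer.writeheader()
        for rec in records:
            writer.writerow(dict(rec))
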