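"""End-to-end orchestration: annotate → validate → quantify → chemometrics.

A run is driven by one plain-text (YAML) config naming the inputs and
parameters; outputs land in one directory together with a JSON manifest
recording package version, parameters, seed and SHA-256 checksums of every
input, so identical configs reproduce identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotateConfig, annotate_dataset
from .chemometrics import kmo, pca
from .compound_space import default_candidates, enumerate_parishin_family, load_library
from .quant import SurrogateMap, class_profile, quantify_table
from .spectra_io import read_mgf, read_peaks_csv, write_annotations
from .validation import fit_calibration

logger = logging.getLogger("gastrodia_ms")

__all__ = ["PipelineConfig", "run"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters for one reproducible pipeline run."""

    spectra: str
    output_dir: str
    library: str | None = None  # default: bundled library + enumerated family
    areas: str | None = None  # sample/compound/area CSV -> quantification
    calibration: str | None = None  # standard/concentration/response CSV
    gate_ppm: float = 5.0
    frag_tol_da: float = 0.01
    max_depth: int = 5
    n_components: int = 2
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in list(raw) if k in cls.__dataclass_fields__}
        return cls(**known, extra=raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_spectra(path: Path):
    if path.suffix.lower() == ".mgf":
        return read_mgf(path)
    return read_peaks_csv(path)


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    out_dir = Path(config.output_dir)
    spectra_path = Path(config.spectra)
    if not spectra_path.exists():
        raise FileNotFoundError(f"spectra path does not exist: {spectra_path}")
    inputs = {"spectra": spectra_path}
    for name in ("library", "areas", "calibration"):
        value = getattr(config, name)
        if value is not None:
            p = Path(value)
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
            inputs[name] = p
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package": "gastrodia-ms",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("extra",)
        },
        "inputs": {name: _sha256(p) for name, p in inputs.items()},
        "stages": {},
    }

    # --- annotation ---------------------------------------------------
    logger.info("stage annotate: reading %s", spectra_path)
    spectra = _read_spectra(spectra_path)
    if config.library is not None:
        candidates = load_library(config.library) + enumerate_parishin_family()
    else:
        candidates = default_candidates()
    ann_cfg = AnnotateConfig(
        gate_ppm=config.gate_ppm,
        frag_tol_da=config.frag_tol_da,
        max_depth=config.max_depth,
    )
    results, summary = annotate_dataset(spectra, candidates, ann_cfg)
    write_annotations((r.to_record() for r in results), out_dir / "annotations.csv")
    manifest["stages"]["annotate"] = summary
    logger.info("stage annotate: %d/%d spectra annotated", summary["n_annotated"], summary["n_spectra"])

    # --- validation ----------------------------------------------------
    models = {}
    if config.calibration is not None:
        cal = pd.read_csv(inputs["calibration"])
        report_rows = []
        for std, grp in cal.groupby("standard"):
            model = fit_calibration(grp["concentration"], grp["response"], standard=str(std))
            models[str(std)] = model
            report_rows.append(
                {
                    "standard": std,
                    "slope": round(model.slope, 4),
                    "intercept": round(model.intercept, 4),
                    "r2": round(model.r2, 6),
                    "range_low": model.range_low,
                    "range_high": model.range_high,
                }
            )
        pd.DataFrame(report_rows).to_csv(out_dir / "calibration_report.csv", index=False)
        manifest["stages"]["validation"] = {"n_standards": len(models)}
        logger.info("stage validation: fitted %d calibration models", len(models))

    # --- quantification -----------------------------------------------
    profiles = None
    if config.areas is not None:
        if not models:
            raise ValueError("quantification requires a calibration table")
        areas = pd.read_csv(inputs["areas"])
        class_of = {c.name: c.compound_class for c in candidates}
        quantified = quantify_table(areas, SurrogateMap(models), class_of)
        quantified.to_csv(out_dir / "concentrations.csv", index=False)
        profiles = class_profile(quantified)
        profiles.to_csv(out_dir / "class_profiles.csv", index_label="sample")
        manifest["stages"]["quantify"] = {
            "n_samples": int(profiles.shape[0]),
            "n_compounds": int(quantified["compound"].nunique()),
        }
        logger.info("stage quantify: %d samples profiled", profiles.shape[0])

    # --- chemometrics --------------------------------------------------
    if profiles is not None and profiles.shape[0] >= 3:
        # classes with no observed variation carry no chemometric signal
        varying = profiles.loc[:, profiles.std(ddof=1) > 0]
        dropped = set(profiles.columns) - set(varying.columns)
        if dropped:
            logger.warning("stage chemometrics: dropping constant class(es) %s", sorted(dropped))
        profiles = varying
    if profiles is not None and profiles.shape[0] >= 3 and profiles.shape[1] >= 2:
        result = pca(
            profiles,
            n_components=min(config.n_components, profiles.shape[1]),
            compute_kmo=False,
        )
        try:
            kmo_value = kmo(profiles.to_numpy())
        except ValueError as exc:  # e.g. collinear or too few classes
            logger.warning("stage chemometrics: KMO unavailable (%s)", exc)
            kmo_value = None
        k = result.n_components
        pd.DataFrame(
            result.loadings[:, :k],
            index=profiles.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ).to_csv(out_dir / "pca_loadings.csv", index_label="variable")
        pd.DataFrame(
            result.scores[:, :k],
            index=profiles.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        ).to_csv(out_dir / "pca_scores.csv", index_label="sample")
        manifest["stages"]["chemometrics"] = {
            "explained_variance_pct": [
                round(float(v), 4) for v in result.explained_variance_pct[:k]
            ],
            "kmo": round(float(kmo_value), 4) if kmo_value is not None else None,
        }
        logger.info("stage chemometrics: PC1+PC2 explain %.1f%%",
                    float(result.explained_variance_pct[:k].sum()))

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
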