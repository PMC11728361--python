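"""End-to-end orchestration: simulate → extract → select → analyze.

Each stage is a plain function over library objects; :func:`run_pipeline`
chains them and writes one artifact per stage under a single run
directory:

* ``features.csv``      — 21 features per image + metadata
* ``selection.json``    — screened features and their directions
* ``correlations.csv``  — every feature vs grade and vs the reference
  feature (echovariation by default), with strength labels
* ``group_comparison.json`` — reference feature across Heckmatt grades
* ``ev_fit.json`` / ``ev_fit_residuals.csv`` — sorted-EV curve fit
* ``manifest.json``     — config, seed, package version

All randomness (cohort generation and the simulated raters) flows from
the single configured seed, so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import EchotexError, ValidationError
from .features import FEATURE_NAMES, extract_all
from .image_io import (
    CohortRecord,
    extract_roi,
    load_cohort_table,
    read_grey_image,
)
from .selection import (
    SelectionResult,
    apply_selection_criterion,
    simulate_rater,
    tally_assessments,
)
from .stats import GroupComparisonResult, grade_comparison, pearson_with_p
from .ev_model import EVFitResult, fit_ev_curve
from .synthetic import SyntheticCohortConfig, generate_cohort, write_cohort

logger = logging.getLogger("echotex")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "extract_features_table"]


@dataclass(frozen=True)
class PipelineConfig:
    mode: Literal["synthetic", "image_dir"] = "synthetic"
    synthetic: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    image_dir: Optional[str] = None  # image_dir mode: directory with cohort.csv
    cohort_csv: Optional[str] = None  # defaults to <image_dir>/cohort.csv
    k: int = 10
    reference_feature: str = "echovariation"
    comparison_method: Literal["auto", "kruskal", "anova"] = "auto"
    disagreement_rate: float = 0.0
    save_images: bool = False
    outdir: str = "echotex_run"

    @property
    def seed(self) -> int:
        return self.synthetic.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        if syn:
            profiles = syn.pop("profiles", None)
            from .synthetic import GradeProfile

            if profiles is not None:
                syn["profiles"] = tuple(GradeProfile(**p) for p in profiles)
            if "image_size" in syn:
                syn["image_size"] = tuple(syn["image_size"])
            raw["synthetic"] = SyntheticCohortConfig(**syn)
        return cls(**raw)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    selection: Optional[SelectionResult]
    correlations: Optional[pd.DataFrame]
    comparison: Optional[GroupComparisonResult]
    ev_fit: Optional[EVFitResult]


def extract_features_table(
    images: dict[str, np.ndarray], records: list[CohortRecord]
) -> pd.DataFrame:
    """All 21 features for every cohort record, metadata passed through."""
    rows = []
    for rec in records:
        roi = extract_roi(images[rec.image_id], rec.roi)
        try:
            vec = extract_all(roi)
        except EchotexError as exc:
            raise type(exc)(f"image {rec.image_id}: {exc}") from exc
        rows.append(
            {
                "image_id": rec.image_id,
                "subject_id": rec.subject_id,
                "limb": rec.limb,
                "grade": rec.grade,
                **vec,
            }
        )
    return pd.DataFrame(rows)


def _load_image_dir(config: PipelineConfig):
    image_dir = Path(config.image_dir)
    cohort_csv = Path(config.cohort_csv or image_dir / "cohort.csv")
    records = load_cohort_table(cohort_csv)
    images = {
        rec.image_id: read_grey_image(image_dir / f"{rec.image_id}.png")
        for rec in records
    }
    return images, records


def _correlation_table(
    features: pd.DataFrame, reference: str
) -> pd.DataFrame:
    """Feature-vs-grade and feature-vs-reference Pearson correlations."""
    rows = []
    grades = features["grade"].to_numpy(dtype=float)
    ref = features[reference].to_numpy()
    for name in FEATURE_NAMES:
        col = features[name].to_numpy()
        for against, other in (("grade", grades), (reference, ref)):
            if name == against:
                continue
            try:
                res = pearson_with_p(col, other, name=name)
            except ValidationError:
                continue  # constant column: correlation undefined
            rows.append(
                {
                    "feature": name,
                    "against": against,
                    "r": res.r,
                    "p_value": res.p_value,
                    "n": res.n,
                    "strength": res.strength,
                }
            )
    return pd.DataFrame(rows)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "setup"
    try:
        # ---- simulate / load -------------------------------------------
        stage = "simulate" if config.mode == "synthetic" else "load"
        logger.info("stage %s", stage)
        if config.mode == "synthetic":
            images, records, truths = generate_cohort(config.synthetic)
            if config.save_images:
                write_cohort(images, records, truths, outdir / "cohort", config.synthetic)
        elif config.mode == "image_dir":
            if config.image_dir is None:
                raise ValidationError("image_dir mode requires image_dir")
            images, records = _load_image_dir(config)
        else:
            raise ValidationError(f"unknown mode {config.mode!r}")

        # ---- extract ----------------------------------------------------
        stage = "extract"
        logger.info("stage extract: %d images", len(records))
        features = extract_features_table(images, records)
        features.to_csv(outdir / "features.csv", index=False)

        graded = features["grade"].notna().all() and len(features) > 0
        selection = correlations = comparison = ev_fit = None

        # ---- select -----------------------------------------------------
        stage = "select"
        if graded and len(features) >= 2 * config.k:
            rng = np.random.default_rng([config.seed, 2])
            grades = features["grade"].to_numpy(dtype=int)
            labels = [
                dict(zip(features["image_id"], simulate_rater(grades, config.disagreement_rate, rng)))
                for _ in range(2)
            ]
            assessments = tally_assessments(features, labels, FEATURE_NAMES, k=config.k)
            selection = apply_selection_criterion(assessments)
            _write_json(
                {
                    "selected": sorted(selection.selected),
                    "direction": dict(sorted(selection.direction.items())),
                    "k": config.k,
                    "disagreement_rate": config.disagreement_rate,
                },
                outdir / "selection.json",
            )
        else:
            logger.info("selection skipped: cohort ungraded or too small")

        # ---- analyze ----------------------------------------------------
        stage = "analyze"
        if graded:
            correlations = _correlation_table(features, config.reference_feature)
            correlations.to_csv(outdir / "correlations.csv", index=False)
            comparison = grade_comparison(
                features[config.reference_feature],
                features["grade"].astype(int),
                method=config.comparison_method,
            )
            _write_json(dataclasses.asdict(comparison), outdir / "group_comparison.json")
        else:
            logger.info("grade-dependent analysis skipped: cohort ungraded")

        stage = "fit"
        ev = features[config.reference_feature].to_numpy()
        if ev.size >= 10:
            ev_fit = fit_ev_curve(ev)
            _write_json(
                {**dataclasses.asdict(ev_fit), "reference_feature": config.reference_feature},
                outdir / "ev_fit.json",
            )
            y = np.sort(ev)[::-1]
            x = np.arange(1, y.size + 1)
            pd.DataFrame(
                {"x": x, "observed": y, "fitted": ev_fit.predict(x)}
            ).to_csv(outdir / "ev_fit_residuals.csv", index=False)
        else:
            logger.info("EV curve fit skipped: fewer than 10 images")

        # ---- manifest ---------------------------------------------------
        stage = "manifest"
        _write_json(
            {
                "package": "echotex",
                "version": __version__,
                "seed": config.seed,
                "config": dataclasses.asdict(config),
                "n_images": len(records),
                "elapsed_s": round(time.time() - t_start, 3),
            },
            outdir / "manifest.json",
        )
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise

    return PipelineResult(
        features=features,
        selection=selection,
        correlations=correlations,
        comparison=comparison,
        ev_fit=ev_fit,
    )
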