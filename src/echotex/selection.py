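"""Informativeness screening of echotexture features.

The screen assumes an informative feature should place the most and the
least affected tissue at opposite ends of its value range: images are
ranked per feature, the top-k and bottom-k are shown to two blinded
raters who count how many of each extreme look "more affected", and a
feature is kept only when, for *both* raters, one extreme scores k/k and
the other 0/k.  A feature whose both extremes look affected (or any
intermediate count) is rejected.  Applied to the published two-rater
counts for the 130-image post-stroke gastrocnemius cohort this yields
exactly {echointensity, echovariation, kurtosis}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "RaterAssessment",
    "SelectionResult",
    "REFERENCE_RATER_COUNTS",
    "rank_extremes",
    "tally_assessments",
    "apply_selection_criterion",
    "simulate_rater",
    "load_assessments",
]

Direction = Literal["high_values_affected", "low_values_affected"]


@dataclass(frozen=True)
class RaterAssessment:
    """Per-feature counts of extreme images judged "more affected"."""

    feature: str
    top_counts: tuple[int, int]  # (rater 1, rater 2) among the top-k values
    bottom_counts: tuple[int, int]  # among the bottom-k values
    k: int = 10

    def __post_init__(self) -> None:
        for c in (*self.top_counts, *self.bottom_counts):
            if not 0 <= c <= self.k:
                raise ValidationError(
                    f"{self.feature}: count {c} outside 0..{self.k}"
                )


@dataclass(frozen=True)
class SelectionResult:
    selected: frozenset[str]
    direction: Mapping[str, Direction]


#: Published two-rater assessment counts for the 21 features of the
#: 130-image post-stroke cohort (top-10 / bottom-10 "more affected"
#: counts for each rater).  Used as a fixed reference input.
REFERENCE_RATER_COUNTS: tuple[RaterAssessment, ...] = tuple(
    RaterAssessment(feature, (t1, t2), (b1, b2))
    for feature, t1, t2, b1, b2 in [
        ("echointensity", 10, 10, 0, 0),
        ("variance", 8, 10, 7, 8),
        ("standard_deviation", 9, 10, 7, 7),
        ("echovariation", 0, 0, 10, 10),
        ("skew", 2, 3, 10, 10),
        ("kurtosis", 0, 0, 10, 10),
        ("correlation", 8, 8, 4, 3),
        ("dissimilarity", 1, 1, 5, 5),
        ("contrast", 3, 4, 5, 5),
        ("homogeneity", 2, 2, 5, 5),
        ("asm", 3, 4, 7, 9),
        ("energy", 0, 0, 5, 7),
        ("max_probability", 0, 0, 7, 8),
        ("entropy", 7, 7, 8, 8),
        ("cluster_shade", 8, 10, 2, 2),
        ("cluster_prominence", 7, 10, 1, 1),
        ("sre", 8, 9, 7, 8),
        ("lre", 3, 3, 7, 9),
        ("glu", 8, 8, 10, 10),
        ("rlu", 10, 10, 10, 10),
        ("rpc", 10, 10, 9, 9),
    ]
)


def rank_extremes(
    table: pd.DataFrame, feature: str, k: int = 10, id_column: str = "image_id"
) -> tuple[list[str], list[str]]:
    """Image ids with the top-k (descending) and bottom-k (ascending)
    values of ``feature``; ties broken by ascending image id."""
    if feature not in table.columns:
        raise ValidationError(f"feature {feature!r} not in table")
    if len(table) < 2 * k:
        raise ValidationError(
            f"need at least {2 * k} rows to take top/bottom {k}, got {len(table)}"
        )
    # ascending id is the secondary key in both directions
    by_desc = table.sort_values([feature, id_column], ascending=[False, True])
    by_asc = table.sort_values([feature, id_column], ascending=[True, True])
    top = list(by_desc[id_column].head(k))
    bottom = list(by_asc[id_column].head(k))
    return top, bottom


def tally_assessments(
    table: pd.DataFrame,
    rater_labels: Sequence[Mapping[str, bool]],
    features: Sequence[str],
    k: int = 10,
    id_column: str = "image_id",
) -> list[RaterAssessment]:
    """Count "more affected" labels in each feature's extremes per rater.

    ``rater_labels`` maps image id -> affected? for each of two raters.
    """
    if len(rater_labels) != 2:
        raise ValidationError("exactly two raters expected")
    out = []
    for feature in features:
        top, bottom = rank_extremes(table, feature, k=k, id_column=id_column)
        tc = tuple(sum(labels[i] for i in top) for labels in rater_labels)
        bc = tuple(sum(labels[i] for i in bottom) for labels in rater_labels)
        out.append(RaterAssessment(feature, tc, bc, k=k))
    return out


def _rater_direction(a: RaterAssessment, rater: int) -> Direction | None:
    top, bottom = a.top_counts[rater], a.bottom_counts[rater]
    if top == a.k and bottom == 0:
        return "high_values_affected"
    if top == 0 and bottom == a.k:
        return "low_values_affected"
    return None  # any intermediate count, or both extremes affected


def apply_selection_criterion(
    assessments: Sequence[RaterAssessment],
) -> SelectionResult:
    """Keep a feature only when both raters score one extreme k/k and the
    other 0/k, in the same direction."""
    names = [a.feature for a in assessments]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate feature names in assessments")
    selected = {}
    for a in assessments:
        d1, d2 = _rater_direction(a, 0), _rater_direction(a, 1)
        if d1 is not None and d1 == d2:
            selected[a.feature] = d1
    return SelectionResult(selected=frozenset(selected), direction=selected)


def simulate_rater(
    grades: Sequence[int],
    disagreement_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Impairment labels a blinded rater would assign from ground truth.

    "More affected" means grade >= 3; each label is flipped
    independently with probability ``disagreement_rate``.
    """
    grades = np.asarray(grades)
    if np.any((grades < 1) | (grades > 4)):
        raise ValidationError("grades must be in 1..4")
    if not 0 <= disagreement_rate < 1:
        raise ValidationError("disagreement_rate must be in [0, 1)")
    labels = grades >= 3
    flips = rng.random(grades.shape) < disagreement_rate
    return labels ^ flips


def load_assessments(path: str | Path) -> list[RaterAssessment]:
    """Read an assessment CSV: feature, top_r1, top_r2, bottom_r1, bottom_r2, k."""
    df = pd.read_csv(path)
    required = ["feature", "top_r1", "top_r2", "bottom_r1", "bottom_r2", "k"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"assessment table missing column(s): {', '.join(missing)}")
    return [
        RaterAssessment(
            str(r.feature), (int(r.top_r1), int(r.top_r2)),
            (int(r.bottom_r1), int(r.bottom_r2)), k=int(r.k),
        )
        for r in df.itertuples(index=False)
    ]
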