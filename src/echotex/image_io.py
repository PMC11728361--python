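"""Greyscale image and cohort-table I/O.

Images are held as 2-D ``uint8`` numpy arrays ("grey images"): the pixel
matrix all echotexture features are computed from.  Regions of interest
(ROIs) are axis-aligned rectangles in 0-based, half-open pixel
coordinates, so that ``area = (row_end - row_start) * (col_end - col_start)``.
Cropping never rescales intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import FormatError, InputError, ValidationError

__all__ = [
    "ROIBox",
    "CohortRecord",
    "as_grey_image",
    "read_grey_image",
    "write_grey_image",
    "extract_roi",
    "load_cohort_table",
    "save_cohort_table",
    "COHORT_COLUMNS",
]

#: Minimum ROI area; guards degenerate texture statistics.
MIN_ROI_AREA = 64

COHORT_COLUMNS = [
    "image_id",
    "row_start",
    "row_end",
    "col_start",
    "col_end",
    "subject_id",
    "limb",
    "grade",
]

# integer-rounded ITU-R BT.601 luma weights
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ROIBox:
    """Rectangular ROI in 0-based, half-open pixel coordinates."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (self.row_start < self.row_end and self.col_start < self.col_end):
            raise ValidationError(f"ROI box must have positive extent: {self}")
        if self.row_start < 0 or self.col_start < 0:
            raise ValidationError(f"ROI box coordinates must be non-negative: {self}")
        if self.area < MIN_ROI_AREA:
            raise ValidationError(
                f"ROI area {self.area} < {MIN_ROI_AREA} pixels: {self}"
            )

    @property
    def area(self) -> int:
        return (self.row_end - self.row_start) * (self.col_end - self.col_start)


@dataclass(frozen=True)
class CohortRecord:
    """One image of a cohort: ROI plus subject/limb/grade metadata.

    ``grade`` is the modified Heckmatt grade (1 = normal echotexture,
    4 = severely affected) or ``None`` for an ungraded cohort.
    """

    image_id: str
    roi: ROIBox
    subject_id: str
    limb: str
    grade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.limb not in ("left", "right"):
            raise ValidationError(
                f"limb must be 'left' or 'right', got {self.limb!r} "
                f"(image {self.image_id})"
            )
        if self.grade is not None and self.grade not in (1, 2, 3, 4):
            raise ValidationError(
                f"grade must be in 1..4, got {self.grade!r} (image {self.image_id})"
            )


def as_grey_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D uint8 pixel matrix."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"grey image must be 2-D and non-empty, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValidationError("grey image values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def read_grey_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an 8-bit grey matrix.

    RGB(A) input is converted by integer-rounded BT.601 luminance;
    16-bit input is rescaled by 255/65535 and rounded.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc

    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    if arr.ndim == 3:  # RGB or RGBA: ignore alpha, BT.601 luma
        arr = np.rint(arr[..., :3].astype(np.float64) @ _BT601)
    elif arr.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {arr.ndim}: {path}")
    if arr.dtype == np.uint16:
        arr = np.rint(arr.astype(np.float64) * (255.0 / 65535.0))
    return as_grey_image(np.clip(arr, 0, 255))


def write_grey_image(image: np.ndarray, path: str | Path) -> None:
    """Write a grey image losslessly (PNG or TIFF by extension)."""
    Image.fromarray(as_grey_image(image), mode="L").save(path)


def extract_roi(image: np.ndarray, box: ROIBox) -> np.ndarray:
    """Crop the rectangular ROI; the full rectangle is the pixel population."""
    image = as_grey_image(image)
    rows, cols = image.shape
    if box.row_end > rows or box.col_end > cols:
        raise ValidationError(
            f"ROI box {box} exceeds image extent ({rows} rows, {cols} cols)"
        )
    return image[box.row_start : box.row_end, box.col_start : box.col_end]


def _parse_grade(raw, row_number: int) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return None
    try:
        grade = int(float(raw))
    except (TypeError, ValueError):
        raise ValidationError(f"row {row_number}: grade {raw!r} is not an integer")
    if grade not in (1, 2, 3, 4):
        raise ValidationError(f"row {row_number}: grade {grade} outside 1..4")
    return grade


def load_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Load the per-image cohort CSV (image id, ROI box, subject, limb, grade)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort table not found: {path}")
    df = pd.read_csv(path, dtype={"image_id": str, "subject_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table {path} missing column(s): {', '.join(missing)}")

    records = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.image_id in seen:
            raise ValidationError(f"row {i}: duplicate image_id {row.image_id!r}")
        seen.add(row.image_id)
        box = ROIBox(int(row.row_start), int(row.row_end), int(row.col_start), int(row.col_end))
        records.append(
            CohortRecord(
                image_id=row.image_id,
                roi=box,
                subject_id=row.subject_id,
                limb=str(row.limb),
                grade=_parse_grade(row.grade, i),
            )
        )
    return records


def save_cohort_table(records: list[CohortRecord], path: str | Path) -> None:
    rows = [
        {
            "image_id": r.image_id,
            "row_start": r.roi.row_start,
            "row_end": r.roi.row_end,
            "col_start": r.roi.col_start,
            "col_end": r.roi.col_end,
            "subject_id": r.subject_id,
            "limb": r.limb,
            "grade": "" if r.grade is None else r.grade,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
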