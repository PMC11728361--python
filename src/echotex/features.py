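"""The 21 echotexture features of a rectangular muscle ROI.

Three families:

* **First-order** (6): echointensity (EI, mean brightness), variance,
  standard deviation, echovariation (EV = 100·σ/μ, the percent
  coefficient of variation of pixel intensity), skewness, kurtosis.
  Moments are population moments (divisor *n*): the ROI is the full
  pixel population, not a sample from it.
* **GLCM** (10): Haralick-style statistics of the grey-level
  co-occurrence matrix at offset (0, +5) — i.e. distance 5, angle 0° —
  with 256 levels, non-symmetric, normalised by the pair count.
* **GLRLM** (5): run-length statistics at 16 grey levels, averaged over
  the five scan directions 0°, 45°, 90°, 135° and 180°.  The 180°
  direction yields a run-length matrix identical to 0°; it is still
  computed and averaged in, reproducing the original 5-angle protocol
  (a ``angles`` override allows the conventional 4-angle average).

Conventions the source libraries leave open are pinned here: skewness is
Fisher–Pearson g1 and kurtosis is Fisher excess, both biased (population)
estimators; GLCM entropy uses the natural logarithm over nonzero entries;
GLCM correlation of a zero-variance marginal is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps
from skimage.feature import graycomatrix, graycoprops

from .errors import ValidationError
from .image_io import as_grey_image

__all__ = [
    "FEATURE_NAMES",
    "FirstOrderFeatures",
    "GLCMMatrix",
    "GLCMFeatures",
    "GLRLMFeatures",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_features",
    "extract_all",
]

#: Canonical names of the 21 features, in reporting order.
FEATURE_NAMES = (
    "echointensity",
    "variance",
    "standard_deviation",
    "echovariation",
    "skew",
    "kurtosis",
    "correlation",
    "dissimilarity",
    "contrast",
    "homogeneity",
    "asm",
    "energy",
    "max_probability",
    "entropy",
    "cluster_shade",
    "cluster_prominence",
    "sre",
    "lre",
    "glu",
    "rlu",
    "rpc",
)

GLRLM_ANGLES = (0, 45, 90, 135, 180)


# ---------------------------------------------------------------------------
# first order


@dataclass(frozen=True)
class FirstOrderFeatures:
    echointensity: float
    variance: float
    sd: float
    echovariation: float
    skew: float
    kurtosis: float
    degenerate: bool = False  # True when sd == 0 (skew/kurtosis set to 0)


def first_order_features(roi: np.ndarray) -> FirstOrderFeatures:
    """Population moments of the ROI pixel intensities; EV in percent."""
    roi = as_grey_image(roi)
    x = roi.astype(np.float64).ravel()
    mean = float(x.mean())
    var = float(x.var())  # divisor n
    sd = float(np.sqrt(var))
    if sd == 0.0:
        return FirstOrderFeatures(mean, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    ev = 100.0 * sd / mean
    return FirstOrderFeatures(
        echointensity=mean,
        variance=var,
        sd=sd,
        echovariation=ev,
        skew=float(sps.skew(x)),
        kurtosis=float(sps.kurtosis(x)),
    )


# ---------------------------------------------------------------------------
# GLCM

_ANGLE_RAD = {0: 0.0, 45: np.pi / 4, 90: np.pi / 2, 135: 3 * np.pi / 4}


@dataclass(frozen=True)
class GLCMMatrix:
    """Normalised, non-symmetric grey-level co-occurrence matrix."""

    p: np.ndarray
    distance: int
    angle: int
    levels: int


def glcm_matrix(
    roi: np.ndarray, distance: int = 5, angle: int = 0, levels: int = 256
) -> GLCMMatrix:
    """Co-occurrence probabilities of ordered pixel pairs at the given offset.

    For angle 0 the offset is (0, +distance): each pixel paired with the
    one ``distance`` columns to its right.  Intensities are used directly
    as matrix levels (no rescaling of 8-bit input).
    """
    roi = as_grey_image(roi)
    if angle not in _ANGLE_RAD:
        raise ValidationError(f"angle must be one of {sorted(_ANGLE_RAD)}, got {angle}")
    if roi.max() >= levels:
        raise ValidationError(
            f"ROI contains level {roi.max()} >= levels={levels}"
        )
    rows, cols = roi.shape
    rad = _ANGLE_RAD[angle]
    off_r = abs(int(round(np.sin(rad) * distance)))
    off_c = abs(int(round(np.cos(rad) * distance)))
    if cols <= off_c or rows <= off_r:
        raise ValidationError(
            f"ROI of shape {roi.shape} has no pixel pair at distance {distance}, "
            f"angle {angle}"
        )
    p = graycomatrix(
        roi,
        distances=[distance],
        angles=[_ANGLE_RAD[angle]],
        levels=levels,
        symmetric=False,
        normed=True,
    )[:, :, 0, 0]
    return GLCMMatrix(p=p, distance=distance, angle=angle, levels=levels)


@dataclass(frozen=True)
class GLCMFeatures:
    correlation: float
    dissimilarity: float
    contrast: float
    homogeneity: float
    asm: float
    energy: float
    max_probability: float
    entropy: float
    cluster_shade: float
    cluster_prominence: float


def glcm_features(m: GLCMMatrix) -> GLCMFeatures:
    """Ten texture statistics of a normalised co-occurrence matrix."""
    p = np.asarray(m.p, dtype=np.float64)
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"GLCM not normalised: entries sum to {total!r}")

    p4 = p[:, :, np.newaxis, np.newaxis]  # shape skimage.graycoprops expects
    props = {
        name: float(graycoprops(p4, name)[0, 0])
        for name in ("correlation", "dissimilarity", "contrast", "homogeneity",
                     "ASM", "energy")
    }

    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    # marginal means/deviations of the normalised matrix
    idx = np.arange(p.shape[0], dtype=np.float64)
    mu_i = float(idx @ p.sum(axis=1))
    mu_j = float(idx @ p.sum(axis=0))
    dev = idx[:, None] + idx[None, :] - mu_i - mu_j  # (i + j - mu_i - mu_j)
    cluster_shade = float((p * dev**3).sum())
    cluster_prominence = float((p * dev**4).sum())

    return GLCMFeatures(
        correlation=props["correlation"],
        dissimilarity=props["dissimilarity"],
        contrast=props["contrast"],
        homogeneity=props["homogeneity"],
        asm=props["ASM"],
        energy=props["energy"],
        max_probability=float(p.max()),
        entropy=entropy,
        cluster_shade=cluster_shade,
        cluster_prominence=cluster_prominence,
    )


# ---------------------------------------------------------------------------
# GLRLM


@dataclass(frozen=True)
class GLRLMFeatures:
    sre: float
    lre: float
    glu: float
    rlu: float
    rpc: float


def _line_runs(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of equal values along a 1-D line → (values, lengths)."""
    if line.size == 0:
        return line, np.empty(0, dtype=np.int64)
    breaks = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [line.size]))
    return line[starts], ends - starts


def _direction_lines(q: np.ndarray, angle: int) -> list[np.ndarray]:
    rows, cols = q.shape
    if angle in (0, 180):  # horizontal; 180° scans right-to-left → same runs
        lines = [q[r] for r in range(rows)]
        return [l[::-1] for l in lines] if angle == 180 else lines
    if angle == 90:  # vertical
        return [q[:, c] for c in range(cols)]
    if angle == 45:  # up-right: anti-diagonals
        flipped = q[::-1]
        return [np.diagonal(flipped, offset=k) for k in range(-(rows - 1), cols)]
    if angle == 135:  # up-left: main diagonals
        return [np.diagonal(q, offset=k) for k in range(-(rows - 1), cols)]
    raise ValidationError(f"unsupported GLRLM angle {angle}")


def glrlm_matrix(roi: np.ndarray, angle: int, levels: int = 16) -> np.ndarray:
    """Run-length matrix r(g, l): counts of maximal runs of quantised level
    g with length l (columns indexed from length 1)."""
    roi = as_grey_image(roi)
    q = (roi.astype(np.int64) * levels) // 256  # 16 equal-width bins by default
    max_len = max(roi.shape)
    r = np.zeros((levels, max_len), dtype=np.int64)
    for line in _direction_lines(q, angle):
        vals, lens = _line_runs(np.ascontiguousarray(line))
        np.add.at(r, (vals, lens - 1), 1)
    return r


def _glrlm_stats(r: np.ndarray, n_pixels: int) -> np.ndarray:
    n_runs = r.sum()
    lengths = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    run_by_len = r.sum(axis=0).astype(np.float64)
    run_by_level = r.sum(axis=1).astype(np.float64)
    sre = (run_by_len / lengths**2).sum() / n_runs
    lre = (run_by_len * lengths**2).sum() / n_runs
    glu = (run_by_level**2).sum() / n_runs
    rlu = (run_by_len**2).sum() / n_runs
    rpc = n_runs / n_pixels
    return np.array([sre, lre, glu, rlu, rpc])


def glrlm_features(
    roi: np.ndarray, levels: int = 16, angles: tuple[int, ...] = GLRLM_ANGLES
) -> GLRLMFeatures:
    """Run-length statistics, averaged arithmetically over the scan angles."""
    roi = as_grey_image(roi)
    per_angle = np.stack(
        [_glrlm_stats(glrlm_matrix(roi, a, levels), roi.size) for a in angles]
    )
    sre, lre, glu, rlu, rpc = per_angle.mean(axis=0)
    return GLRLMFeatures(sre=sre, lre=lre, glu=glu, rlu=rlu, rpc=rpc)


# ---------------------------------------------------------------------------
# all 21


def extract_all(
    roi: np.ndarray,
    glcm_distance: int = 5,
    glcm_angle: int = 0,
    glrlm_levels: int = 16,
    glrlm_angles: tuple[int, ...] = GLRLM_ANGLES,
) -> dict[str, float]:
    """The full 21-entry feature vector of one ROI, keyed by canonical name."""
    fo = first_order_features(roi)
    gl = glcm_features(glcm_matrix(roi, distance=glcm_distance, angle=glcm_angle))
    rl = glrlm_features(roi, levels=glrlm_levels, angles=glrlm_angles)
    vec = {
        "echointensity": fo.echointensity,
        "variance": fo.variance,
        "standard_deviation": fo.sd,
        "echovariation": fo.echovariation,
        "skew": fo.skew,
        "kurtosis": fo.kurtosis,
        **asdict(gl),
        **asdict(rl),
    }
    assert tuple(vec) == FEATURE_NAMES
    return vec
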