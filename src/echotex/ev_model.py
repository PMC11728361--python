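"""Double-exponential model of the sorted echovariation distribution.

When the cohort's EV values are sorted in descending order and plotted
against image rank x = 1..n, the resulting curve is well described by

    y = a·exp(b·x) + c·exp(d·x) + E,      b, d <= 0,

a fast head exponential riding on a slow near-linear tail.  The slow
term is typically extremely ill-conditioned: a huge ``c`` with a tiny
``|d|`` and a large negative ``E`` is numerically indistinguishable from
a straight line, so the (c, d, E) trio is not identifiable and only the
fitted *function* (and its R²) is meaningful.  Evaluation therefore uses
the cancellation-safe form  a·e^(bx) + c·(e^(dx) − 1) + (c + E),  and
the fit reports an ill-conditioning flag instead of parameter errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .errors import EchotexError, FitError, ValidationError

__all__ = ["EVFitResult", "evaluate_model", "fit_ev_curve", "r_squared"]

#: Exponent magnitude beyond which evaluation refuses to run.
_MAX_EXPONENT = 700.0


@dataclass(frozen=True)
class EVFitResult:
    a: float
    b: float
    c: float
    d: float
    E: float
    r_squared: float
    condition_flag: bool  # True when the scaled Jacobian is ill-conditioned
    n: int
    x_convention: int = 1  # first image rank

    @property
    def params(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.E)

    def predict(self, x) -> np.ndarray:
        return evaluate_model(self.params, x)


def evaluate_model(params: Sequence[float], x) -> np.ndarray:
    """y = a·e^(bx) + c·e^(dx) + E, safe against (c, E) cancellation."""
    a, b, c, d, E = (float(p) for p in params)
    x = np.asarray(x, dtype=np.float64)
    for expo in (b * x, d * x):
        bad = np.atleast_1d(expo > _MAX_EXPONENT)  # underflow is harmless
        if bad.any():
            raise EchotexError(
                f"exponent overflow at x = {np.atleast_1d(x)[np.argmax(bad)]}"
            )
    return a * np.exp(b * x) + c * np.expm1(d * x) + (c + E)


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 − SSE/SST."""
    o = np.asarray(observed, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if o.shape != p.shape or o.ndim != 1:
        raise ValidationError("observed and predicted must be 1-D of equal length")
    sst = float(((o - o.mean()) ** 2).sum())
    if sst == 0:
        raise ValidationError("constant observed values: R² undefined")
    sse = float(((o - p) ** 2).sum())
    return 1.0 - sse / sst


def _initial_guesses(
    x: np.ndarray, y: np.ndarray, n_starts: int, seed: int
) -> list[np.ndarray]:
    """Structured starts: line through the tail gives (c, d, E); a single
    exponential through the head residual gives (a, b); jittered."""
    half = x.size // 2
    tail = linregress(x[half:], y[half:])
    slope, intercept = tail.slope, tail.intercept
    c0 = 1e5
    d0 = min(slope / c0, -1e-12)  # c·e^(dx)+E ≈ (c·d)x + c+E for small |d|
    e0 = intercept - c0

    resid = y[:half] - (intercept + slope * x[:half])
    pos = resid > max(1e-9, 1e-6 * np.abs(y).max())
    if pos.sum() >= 2:
        head = linregress(x[:half][pos], np.log(resid[pos]))
        a0 = float(np.exp(head.intercept))
        b0 = float(np.clip(head.slope, -9.9, -1e-6))
    else:
        a0, b0 = max(float(y[0] - y[half:].mean()), 1.0), -0.1

    rng = np.random.default_rng(seed)
    starts = [np.array([a0, b0, c0, d0, e0])]
    for _ in range(n_starts - 1):
        ja = a0 * np.exp(rng.normal(0, 0.5))
        jb = float(np.clip(b0 * np.exp(rng.normal(0, 0.5)), -9.9, -1e-9))
        starts.append(np.array([ja, jb, c0, d0, e0]))
    return starts


def fit_ev_curve(
    ev_values: Sequence[float],
    n_starts: int = 20,
    seed: int = 0,
    condition_threshold: float = 1e8,
) -> EVFitResult:
    """Fit the descending-sorted EV curve by multi-start nonlinear least
    squares with b, d constrained to [−10, 0].

    The input order is irrelevant (values are sorted internally) and the
    fit is deterministic for a fixed seed.
    """
    y = np.sort(np.asarray(ev_values, dtype=np.float64))[::-1]
    if y.size < 10:
        raise ValidationError(f"need at least 10 values to fit, got {y.size}")
    if np.ptp(y) == 0:
        raise FitError("constant EV values: SST = 0, fit undefined")
    x = np.arange(1, y.size + 1, dtype=np.float64)

    def residuals(p: np.ndarray) -> np.ndarray:
        return evaluate_model(p, x) - y

    lower = [-np.inf, -10.0, -np.inf, -10.0, -np.inf]
    upper = [np.inf, 0.0, np.inf, 0.0, np.inf]
    best = None
    for p0 in _initial_guesses(x, y, n_starts, seed):
        try:
            res = least_squares(
                residuals, p0, bounds=(lower, upper), method="trf",
                xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=1000,
            )
        except (ValueError, EchotexError):
            continue
        # status 0 means the evaluation budget ran out at a usable point;
        # only outright failure (-1) is discarded
        if res.status >= 0 and np.isfinite(res.cost) and (
            best is None or res.cost < best.cost
        ):
            best = res
    if best is None:
        raise FitError(
            f"no start converged (n = {y.size}, range {y.min():.2f}–{y.max():.2f})"
        )

    sse = float((best.fun**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    jac = best.jac
    norms = np.linalg.norm(jac, axis=0)
    norms[norms == 0] = 1.0
    cond = float(np.linalg.cond(jac / norms))
    a, b, c, d, e = (float(v) for v in best.x)
    return EVFitResult(
        a=a, b=b, c=c, d=d, E=e,
        r_squared=1.0 - sse / sst,
        condition_flag=cond > condition_threshold,
        n=int(y.size),
    )
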