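"""Four-parameter Richards (generalised logistic) identification fits.

The probability of a "voiceless" response at a stimulus VOT is modelled as

    P(vot) = K1 + (K2 - K1) * e^y / (1 + e^y),    y = I + S * vot

where K1 and K2 are the lower and upper asymptotes (proportions), I is the
intercept and S the slope of the linear predictor (logit/ms).  With K1 = 0
and K2 = 1 the model reduces to the plain logistic.  Categorical precision
is summarised by three derived measures: the *boundary* (VOT of the 50%
crossing between the asymptotes, -I/S), the *slope* S, and the *asymptotic
width* K2 - K1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "RichardsParams",
    "RichardsFit",
    "richards_probability",
    "fit_richards",
    "extract_precision",
    "detect_flat",
    "screen_practice",
    "fit_all",
]

# parameter bounds used by the optimizer: K1 in [0, .5], K2 in [.5, 1]
_BOUNDS_LO = np.array([-25.0, -2.0, 0.0, 0.5])
_BOUNDS_HI = np.array([25.0, 2.0, 0.5, 1.0])

#: observed endpoint difference below which a response curve carries no
#: usable stimulus information (mirrors the 75% practice-screening logic)
FLAT_THRESHOLD = 0.25


@dataclass(frozen=True)
class RichardsParams:
    I: float
    S: float
    K1: float
    K2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.K1 < self.K2 <= 1.0):
            raise ValueError(f"require 0 <= K1 < K2 <= 1, got K1={self.K1}, K2={self.K2}")
        if not math.isfinite(self.S):
            raise ValueError("S must be finite")


@dataclass(frozen=True)
class RichardsFit:
    params: RichardsParams | None
    boundary_ms: float
    slope: float
    asym_width: float
    rss: float
    converged: bool
    flat: bool


def richards_probability(params: RichardsParams, vot_ms) -> np.ndarray | float:
    """P("voiceless") at the given VOT(s); monotone in VOT when S > 0."""
    vot = np.asarray(vot_ms, dtype=float)
    y = params.I + params.S * vot
    # numerically stable logistic
    p = np.where(y >= 0, 1.0 / (1.0 + np.exp(-y)),
                 np.exp(np.clip(y, -700, 0)) / (1.0 + np.exp(np.clip(y, -700, 0))))
    out = params.K1 + (params.K2 - params.K1) * p
    return out if out.ndim else float(out)


def _proportions(counts: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = counts.sort_values("vot_ms")
    vot = c["vot_ms"].to_numpy(dtype=float)
    n = c["n_trials"].to_numpy(dtype=float)
    p = c["n_voiceless"].to_numpy(dtype=float) / n
    return vot, n, p


def detect_flat(counts: pd.DataFrame) -> bool:
    """True when the observed endpoint proportions differ by < 0.25.

    ``counts`` holds one row per VOT level with n_trials / n_voiceless.
    """
    vot, _, p = _proportions(counts)
    return bool(abs(p[-1] - p[0]) < FLAT_THRESHOLD)


def _residuals(theta: np.ndarray, vot: np.ndarray, p: np.ndarray) -> np.ndarray:
    I, S, K1, K2 = theta
    pars = RichardsParams.__new__(RichardsParams)
    object.__setattr__(pars, "I", I)
    object.__setattr__(pars, "S", S)
    object.__setattr__(pars, "K1", K1)
    object.__setattr__(pars, "K2", K2)
    return richards_probability(pars, vot) - p


def _start_grid(vot: np.ndarray, p: np.ndarray) -> list[np.ndarray]:
    """Deterministic multistart grid: 3 values per parameter, ranked by RSS."""
    span = vot[-1] - vot[0]
    starts = []
    for b, s, k1, k2 in itertools.product(
        (vot[0] + 0.25 * span, vot[0] + 0.5 * span, vot[0] + 0.75 * span),
        (0.05, 0.2, 0.6),
        (0.0, 0.1, 0.3),
        (0.7, 0.9, 1.0),
    ):
        starts.append(np.array([-b * s, s, k1, k2]))
    # moment-based heuristic start from the observed extremes
    k1h = float(np.clip(p.min(), 0.0, 0.45))
    k2h = float(np.clip(p.max(), 0.55, 1.0))
    mid = 0.5 * (k1h + k2h)
    cross = vot[int(np.argmin(np.abs(p - mid)))]
    starts.append(np.array([-cross * 0.2, 0.2, k1h, k2h]))
    rank = sorted(starts, key=lambda t: float(np.sum(_residuals(
        np.clip(t, _BOUNDS_LO, _BOUNDS_HI), vot, p) ** 2)))
    return rank[:4]


def fit_richards(counts: pd.DataFrame) -> RichardsFit:
    """Least-squares Richards fit to per-stimulus response proportions.

    ``counts`` must contain columns vot_ms, n_trials, n_voiceless with at
    least 6 distinct VOT levels.  Fitting minimises the unweighted residual
    sum of squares of the proportions, restarting from a deterministic grid
    of initial values and keeping the best local solution.  Degenerate
    (flat) data yield ``converged=False`` with an undefined boundary.
    """
    vot, n, p = _proportions(counts)
    if len(np.unique(vot)) < 6:
        raise ValueError("need >= 6 distinct VOT levels to fit")
    if (n < 1).any():
        raise ValueError("every VOT level needs at least one trial")

    flat = detect_flat(counts)
    if np.allclose(p, p[0]):
        return RichardsFit(None, math.nan, math.nan, math.nan,
                           rss=0.0, converged=False, flat=True)

    best = None
    for x0 in _start_grid(vot, p):
        x0 = np.clip(x0, _BOUNDS_LO, _BOUNDS_HI)
        sol = least_squares(
            _residuals, x0, args=(vot, p),
            bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol)
    rss, sol = best
    I, S, K1, K2 = sol.x
    converged = bool(sol.success)
    if K1 >= K2:  # bounds make this impossible except exactly at 0.5/0.5
        K1, K2 = 0.499, 0.5
    params = RichardsParams(I=float(I), S=float(S), K1=float(K1), K2=float(K2))
    boundary = -I / S if converged and abs(S) > 1e-12 else math.nan
    flat = flat or not converged
    return RichardsFit(params, float(boundary), float(S), float(K2 - K1),
                       rss=rss, converged=converged, flat=flat)


def extract_precision(fit: RichardsFit) -> tuple[float, float, float]:
    """(boundary_ms, slope, asym_width); NaN triple when unconverged."""
    if not fit.converged or fit.params is None:
        return (math.nan, math.nan, math.nan)
    return (fit.boundary_ms, fit.slope, fit.asym_width)


def screen_practice(n_correct: int, n_trials: int) -> bool:
    """Practice screening: pass iff >= 75% of endpoint items are correct."""
    if n_trials <= 0:
        raise ValueError("no endpoint trials to screen")
    return n_correct / n_trials >= 0.75


def fit_all(ident_counts: pd.DataFrame) -> pd.DataFrame:
    """Fit every subject x continuum and tabulate parameters and measures.

    Returns the ``ident_fits`` table: subject_id, group, grade, continuum,
    I, S, K1, K2, boundary_ms, slope, asym_width, rss, converged, flat.
    """
    rows = []
    keys = ["subject_id", "group", "grade", "continuum"]
    for key, sub in ident_counts.groupby(keys, sort=True):
        fit = fit_richards(sub)
        pars = fit.params
        rows.append(
            dict(
                zip(keys, key),
                I=pars.I if pars else math.nan,
                S=pars.S if pars else math.nan,
                K1=pars.K1 if pars else math.nan,
                K2=pars.K2 if pars else math.nan,
                boundary_ms=fit.boundary_ms,
                slope=fit.slope,
                asym_width=fit.asym_width,
                rss=fit.rss,
                converged=fit.converged,
                flat=fit.flat,
            )
        )
    return pd.DataFrame(rows)
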