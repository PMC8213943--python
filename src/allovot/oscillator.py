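"""Subharmonic-coupled oscillator model of VOT discrimination curves.

The discrimination sensitivity at a pair center (VOT, in ms) is modelled
as a linear trend plus two cosine components, one with a 30-ms period
(33.33 Hz) tracking the universal allophonic boundaries at +-30 ms, and
one at its binary subharmonic with a 60-ms period (16.67 Hz) tracking the
phonemic boundary at 0 ms:

    d'(vot) = k * vot + w33 * cos(2*pi*f_high*vot) + w17 * cos(2*pi*f_low*vot)

with f_low = f_high / 2.  The exact frequencies 1/30 and 1/60 cycles/ms
are used rather than rounded decimals.  With the frequencies fixed, the
model is linear in (k, w33, w17) and the least-squares fit has the
closed-form normal-equations solution; no standalone intercept is used.

An equivalent (D, C) parameterisation, with the two cosine weights written
as D + C and D - C, is emitted alongside for traceability:
D = (w33 + w17) / 2 and C = (w33 - w17) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import PAIR_CENTERS_MS
from .anova import two_within_interaction_F

__all__ = [
    "OscillatorParams",
    "F_HIGH_DEFAULT",
    "predict_dprime",
    "fit_oscillator",
    "fit_all_oscillator",
    "weight_tests",
    "model_vs_data_F",
    "frequency_sweep",
    "rank_sum_z",
    "signed_rank_z",
]

#: default high frequency: 30-ms period, i.e. 33.33 Hz
F_HIGH_DEFAULT = 1.0 / 30.0  # cycles per ms


@dataclass(frozen=True)
class OscillatorParams:
    k: float          # linear slope, d' per ms
    w33: float        # weight of the high-frequency cosine, d' units
    w17: float        # weight of the subharmonic cosine, d' units
    f_high: float = F_HIGH_DEFAULT   # cycles/ms
    f_low: float = F_HIGH_DEFAULT / 2

    def __post_init__(self) -> None:
        if not math.isclose(self.f_low, self.f_high / 2, rel_tol=1e-9):
            raise ValueError("f_low must be the binary subharmonic f_high/2")
        for v in (self.k, self.w33, self.w17):
            if not math.isfinite(v):
                raise ValueError("oscillator parameters must be finite")

    @property
    def D(self) -> float:
        return 0.5 * (self.w33 + self.w17)

    @property
    def C(self) -> float:
        return 0.5 * (self.w33 - self.w17)


def predict_dprime(params: OscillatorParams, center_vot_ms) -> np.ndarray | float:
    vot = np.asarray(center_vot_ms, dtype=float)
    out = (
        params.k * vot
        + params.w33 * np.cos(2 * np.pi * params.f_high * vot)
        + params.w17 * np.cos(2 * np.pi * params.f_low * vot)
    )
    return out if out.ndim else float(out)


def _design_matrix(vot: np.ndarray, f_high: float) -> np.ndarray:
    return np.column_stack([
        vot,
        np.cos(2 * np.pi * f_high * vot),
        np.cos(2 * np.pi * (f_high / 2) * vot),
    ])


def fit_oscillator(center_vot_ms, dprimes,
                   f_high: float = F_HIGH_DEFAULT) -> tuple[OscillatorParams, float]:
    """Least-squares fit of (k, w33, w17) to one discrimination curve.

    Missing (NaN) centers are dropped; at least 4 centers are required for
    a well-posed solve.  Returns the parameters and the residual sum of
    squares.
    """
    vot = np.asarray(center_vot_ms, dtype=float)
    y = np.asarray(dprimes, dtype=float)
    keep = np.isfinite(y)
    if keep.sum() < 4:
        missing = sorted(int(v) for v in vot[~keep])
        raise ValueError(
            f"need >= 4 non-missing centers to fit; missing centers: {missing}"
        )
    X = _design_matrix(vot[keep], f_high)
    beta, _, rank, _ = np.linalg.lstsq(X, y[keep], rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient design; centers do not separate the regressors")
    resid = y[keep] - X @ beta
    params = OscillatorParams(k=float(beta[0]), w33=float(beta[1]),
                              w17=float(beta[2]), f_high=f_high,
                              f_low=f_high / 2)
    return params, float(resid @ resid)


def fit_all_oscillator(curves: pd.DataFrame,
                       f_high: float = F_HIGH_DEFAULT) -> pd.DataFrame:
    """Per subject x continuum fits; emits k, w33, w17, D, C and rss."""
    rows = []
    keys = ["subject_id", "group", "grade", "continuum"]
    for key, sub in curves.groupby(keys, sort=True):
        pars, rss = fit_oscillator(sub["center_vot_ms"], sub["dprime"], f_high)
        rows.append(dict(zip(keys, key), k=pars.k, w33=pars.w33, w17=pars.w17,
                         D=pars.D, C=pars.C, rss=rss))
    return pd.DataFrame(rows)


def rank_sum_z(x, y) -> float:
    """Two-sample rank-sum z with midranks and tie-corrected variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = pd.Series(combined).rank().to_numpy()
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float((u - mu) / math.sqrt(var))


def signed_rank_z(d) -> float:
    """One-sample (or paired-difference) signed-rank z, zeros dropped."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (counts ** 3 - counts).sum() / 48
    if var <= 0:
        return 0.0
    return float((w_pos - mu) / math.sqrt(var))


def weight_tests(fits: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Nonparametric z tests on the fitted oscillator parameters.

    Between-group differences use the rank-sum normal approximation; tests
    against 0 and the paired w33-vs-w17 comparison use the signed-rank
    normal approximation.  Two-sided p values.
    """
    groups = sorted(fits[group_col].unique())
    rows = []

    def add(test, group, z):
        rows.append(dict(test=test, group=group, z=z,
                         p=float(2 * norm.sf(abs(z)))))

    if len(groups) == 2:
        g0 = fits[fits[group_col] == groups[0]]
        g1 = fits[fits[group_col] == groups[1]]
        if len(g0) < 2 or len(g1) < 2:
            raise ValueError("need >= 2 subjects per group")
        for par in ("w17", "w33", "k"):
            add(f"{par}_between_groups", f"{groups[0]}-vs-{groups[1]}",
                rank_sum_z(g0[par], g1[par]))
    for g in groups:
        sub = fits[fits[group_col] == g]
        for par in ("w17", "w33", "k"):
            add(f"{par}_vs_zero", g, signed_rank_z(sub[par]))
        add("w33_vs_w17_paired", g,
            signed_rank_z(sub["w33"].to_numpy() - sub["w17"].to_numpy()))
    return pd.DataFrame(rows)


def _predicted_observed(fits: pd.DataFrame, curves: pd.DataFrame,
                        f_high: float) -> pd.DataFrame:
    """Wide per-subject table of model-minus-data d' at each center."""
    merged = curves.merge(
        fits[["subject_id", "continuum", "k", "w33", "w17"]],
        on=["subject_id", "continuum"],
    )
    vot = merged["center_vot_ms"].to_numpy(dtype=float)
    pred = (
        merged["k"].to_numpy() * vot
        + merged["w33"].to_numpy() * np.cos(2 * np.pi * f_high * vot)
        + merged["w17"].to_numpy() * np.cos(2 * np.pi * (f_high / 2) * vot)
    )
    merged["delta"] = pred - merged["dprime"].to_numpy()
    wide = merged.pivot_table(index="subject_id", columns="center_vot_ms",
                              values="delta")
    return wide.dropna(axis=0)  # listwise deletion of incomplete subjects


def model_vs_data_F(fits: pd.DataFrame, curves: pd.DataFrame,
                    f_high: float = F_HIGH_DEFAULT) -> dict:
    """Score-type (model, data) x VOT interaction F, GG-adjusted df.

    For a two-level score-type factor the interaction is equivalent to a
    one-way repeated-measures ANOVA on the per-center model-minus-data
    differences, which is how it is computed here.  Identical predicted
    and observed curves give F = 0.
    """
    wide = _predicted_observed(fits, curves, f_high)
    return two_within_interaction_F(wide.to_numpy())


def frequency_sweep(curves: pd.DataFrame, f_grid_hz,
                    groups: tuple[str, ...] = ("NR", "DYS")) -> pd.DataFrame:
    """Refit every subject at each high frequency and index the group fit.

    Each high frequency is paired with its binary subharmonic.  The fit
    index is the Score-type x VOT interaction F per group: lower F means
    the model tracks the observed curves more closely.
    """
    rows = []
    for f_hz in f_grid_hz:
        f_high = f_hz / 1000.0  # Hz -> cycles per ms
        fits = fit_all_oscillator(curves, f_high=f_high)
        for g in groups:
            gc = curves[curves["group"] == g]
            gf = fits[fits["group"] == g]
            if gc.empty:
                continue
            res = model_vs_data_F(gf, gc, f_high=f_high)
            rows.append(dict(f_high_hz=float(f_hz), group=g,
                             fit_index_F=res["F"], df1=res["df1_gg"],
                             df2=res["df2_gg"], p=res["p"]))
    return pd.DataFrame(rows)


def default_sweep_grid() -> np.ndarray:
    """20-45 Hz in 1-Hz steps plus the exact 33.33-Hz anchor."""
    grid = np.arange(20.0, 46.0, 1.0)
    return np.sort(np.append(grid, 1000.0 * F_HIGH_DEFAULT))
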