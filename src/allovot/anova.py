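"""Repeated-measures ANOVA with Greenhouse-Geisser adjustment.

Implements the split-plot (one between-subject grouping factor x one
within-subject factor) and pure within-subject decompositions needed for
the discrimination analyses: the Group x VOT interaction, the planned
contrast group tests, and the Score-type (model, data) x VOT fit index.

The Greenhouse-Geisser epsilon is computed from the double-centered
sample covariance of the within-subject level scores,

    eps = tr(S~)^2 / ((k - 1) * tr(S~ @ S~)),    S~ = C S C,  C = I - J/k,

pooled within groups when a between factor is present, floored at
1/(k - 1) and capped at 1.  With two within levels sphericity holds
trivially and eps = 1.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

log = logging.getLogger(__name__)

__all__ = ["gg_epsilon", "rm_anova_gg", "two_within_interaction_F",
           "one_way_anova"]


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of an (n subjects x k levels) array."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k < 2:
        raise ValueError("need >= 2 within-subject levels")
    if k == 2:
        return 1.0
    S = np.cov(data, rowvar=False)
    return _eps_from_cov(S, k, n_eff=n)


def _eps_from_cov(S: np.ndarray, k: int, n_eff: int) -> float:
    C = np.eye(k) - np.ones((k, k)) / k
    St = C @ S @ C
    denom = (k - 1) * float(np.trace(St @ St))
    floor = 1.0 / (k - 1)
    if denom <= 0 or not math.isfinite(denom):
        log.warning("singular within-level covariance; epsilon floored at %.4f",
                    floor)
        return floor
    eps = float(np.trace(St)) ** 2 / denom
    if n_eff <= k:
        log.warning("more within levels than subjects; epsilon may be unstable")
    return min(max(eps, floor), 1.0)


def _f_p(F: float, df1: float, df2: float) -> float:
    if df2 <= 0 or not math.isfinite(F):
        return math.nan
    return float(f_dist.sf(F, df1, df2))


def two_within_interaction_F(delta: np.ndarray) -> dict:
    """F of a 2 x k within-within interaction from per-subject differences.

    ``delta`` is (n subjects x k levels) of level-wise differences between
    the two conditions.  The interaction of the 2-level factor with the
    k-level factor equals the one-way repeated-measures test of whether
    the mean difference varies over levels; identical conditions (all
    deltas equal per subject, in particular all zero) give F = 0.
    """
    d = np.asarray(delta, dtype=float)
    n, k = d.shape
    grand = d.mean()
    col = d.mean(axis=0)
    row = d.mean(axis=1)
    ss_eff = n * float(((col - grand) ** 2).sum())
    resid = d - row[:, None] - col[None, :] + grand
    ss_err = float((resid ** 2).sum())
    df1, df2 = k - 1.0, (n - 1.0) * (k - 1.0)
    eps = gg_epsilon(d)
    if ss_err < 1e-12:
        F = 0.0 if ss_eff < 1e-10 else math.inf
    else:
        F = (ss_eff / df1) / (ss_err / df2)
    return dict(F=F, df1=df1, df2=df2, eps=eps, df1_gg=eps * df1,
                df2_gg=eps * df2, p=_f_p(F, eps * df1, eps * df2),
                ss_effect=ss_eff, ss_error=ss_err,
                partial_eta2=ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0
                else 0.0)


def rm_anova_gg(wide: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Mixed-design ANOVA on a subject x within-level table.

    Parameters
    ----------
    wide:
        One row per subject, one column per within-subject level; rows
        with missing cells are dropped (listwise deletion).
    groups:
        Optional between-subject factor aligned with ``wide``'s index.

    Returns
    -------
    DataFrame with one row per effect (group, within, group x within) and
    columns SS, df1, df2, eps, df1_gg, df2_gg, F, p, partial_eta2.
    """
    wide = wide.dropna(axis=0)
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    if n < 2:
        raise ValueError("need >= 2 complete subjects")
    rows = []

    if groups is None:
        res = _within_only(y)
        eps = gg_epsilon(y)
        rows.append(_effect_row("within", res["ss_eff"], k - 1.0,
                                (n - 1.0) * (k - 1.0), eps, res["ss_err"]))
        return pd.DataFrame(rows)

    g = pd.Series(groups).loc[wide.index]
    labels = sorted(g.unique())
    ng = len(labels)
    if ng < 2:
        raise ValueError("between factor needs >= 2 groups")
    idx = [np.flatnonzero((g == lab).to_numpy()) for lab in labels]
    sizes = np.array([len(i) for i in idx])
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[i].mean() for i in idx])

    # between-subject stratum
    ss_group = k * float((sizes * (group_means - grand) ** 2).sum())
    ss_subj_err = k * sum(
        float(((subj_means[i] - gm) ** 2).sum())
        for i, gm in zip(idx, group_means)
    )
    rows.append(_effect_row("group", ss_group, ng - 1.0, float(n - ng),
                            1.0, ss_subj_err))

    # within-subject stratum on subject-centered profiles
    z = y - subj_means[:, None]
    col = z.mean(axis=0)
    ss_within = n * float((col ** 2).sum())
    cell = np.stack([z[i].mean(axis=0) for i in idx])  # ng x k
    ss_inter = float((sizes[:, None] * (cell - col[None, :]) ** 2).sum())
    ss_err = sum(float(((z[i] - cell[j][None, :]) ** 2).sum())
                 for j, i in enumerate(idx))

    # pooled within-group covariance for epsilon
    pooled = sum((len(i) - 1) * np.cov(y[i], rowvar=False) for i in idx)
    pooled = pooled / (n - ng)
    eps = 1.0 if k == 2 else _eps_from_cov(pooled, k, n_eff=n - ng + 1)

    df_err = (n - ng) * (k - 1.0)
    rows.append(_effect_row("within", ss_within, k - 1.0, df_err, eps, ss_err))
    rows.append(_effect_row("group_x_within", ss_inter, (ng - 1.0) * (k - 1.0),
                            df_err, eps, ss_err))
    return pd.DataFrame(rows)


def _within_only(y: np.ndarray) -> dict:
    n, k = y.shape
    grand = y.mean()
    col = y.mean(axis=0)
    row = y.mean(axis=1)
    ss_eff = n * float(((col - grand) ** 2).sum())
    resid = y - row[:, None] - col[None, :] + grand
    return dict(ss_eff=ss_eff, ss_err=float((resid ** 2).sum()))


def _effect_row(effect: str, ss: float, df1: float, df2: float,
                eps: float, ss_err: float) -> dict:
    if ss_err < 1e-12:
        F = 0.0 if ss < 1e-10 else math.inf
    else:
        F = (ss / df1) / (ss_err / df2)
    return dict(effect=effect, SS=ss, df1=df1, df2=df2, eps=eps,
                df1_gg=eps * df1, df2_gg=eps * df2, F=F,
                p=_f_p(F, eps * df1, eps * df2),
                partial_eta2=ss / (ss + ss_err) if ss + ss_err > 0 else 0.0)


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> dict:
    """Between-subject one-way ANOVA with partial eta^2 and Cohen's d.

    Cohen's d (mean difference over the pooled SD) is reported for the
    two-group case only, ordered by sorted group label (first - second).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    parts = [values[groups == lab] for lab in labels]
    if any(len(p) < 2 for p in parts):
        raise ValueError("every group needs >= 2 subjects")
    grand = values.mean()
    ss_eff = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ss_err = sum(((p - p.mean()) ** 2).sum() for p in parts)
    df1 = len(labels) - 1.0
    df2 = float(len(values) - len(labels))
    F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else (
        0.0 if ss_eff < 1e-10 else math.inf)
    out = dict(F=F, df1=df1, df2=df2, p=_f_p(F, df1, df2),
               partial_eta2=ss_eff / (ss_eff + ss_err)
               if ss_eff + ss_err > 0 else 0.0)
    if len(labels) == 2:
        a, b = parts
        pooled = math.sqrt(
            (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
            / (len(a) + len(b) - 2)
        )
        out["cohens_d"] = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        out["mean_diff"] = a.mean() - b.mean()
        out["group_order"] = tuple(labels)
    return out
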