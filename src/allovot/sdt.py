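"""Signal-detection scoring of AX same-different discrimination.

Per pair center the hit rate H is the proportion of "different" responses
to different pairs and the false-alarm rate F is 1 minus the proportion of
"same" responses to the pooled same pairs.  Sensitivity is the yes/no
z-difference

    d' = z(H) - z(F)

with extreme proportions (0 or 1) replaced by 1/(2N) and 1 - 1/(2N) before
the inverse-normal transform, which keeps d' finite and bounded by
2 * z(1 - 1/(2N)).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["correct_score", "dprime", "build_curves", "group_curve"]


def correct_score(n_diff_correct: int, n_diff: int,
                  n_same_correct: int, n_same: int) -> float:
    """Mean of the proportions correct on different and same pairs."""
    if n_diff <= 0 or n_same <= 0:
        return math.nan
    return 0.5 * (n_diff_correct / n_diff + n_same_correct / n_same)


def _clip_rate(k: int, n: int) -> float:
    r = k / n
    lo = 1.0 / (2 * n)
    return min(max(r, lo), 1.0 - lo)


def dprime(n_diff_correct: int, n_diff: int,
           n_same_correct: int, n_same: int) -> float:
    """d' = z(hit rate) - z(false-alarm rate) with the 1/(2N) correction."""
    if n_diff <= 0 or n_same <= 0:
        return math.nan
    hit = _clip_rate(n_diff_correct, n_diff)
    fa = _clip_rate(n_same - n_same_correct, n_same)
    return float(norm.ppf(hit) - norm.ppf(fa))


def build_curves(pair_center_counts: pd.DataFrame) -> pd.DataFrame:
    """Score every subject x continuum x center.

    Input is the aggregated pair-center count table; output adds hit_rate,
    fa_rate, correct_score and dprime columns (NaN at incomplete centers).
    """
    df = pair_center_counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["hit_rate"] = df["n_diff_correct"] / df["n_diff_trials"]
        df["fa_rate"] = 1.0 - df["n_same_correct"] / df["n_same_trials"]
    df["correct_score"] = [
        correct_score(dc, d, sc, s)
        for dc, d, sc, s in zip(df["n_diff_correct"], df["n_diff_trials"],
                                df["n_same_correct"], df["n_same_trials"])
    ]
    df["dprime"] = [
        dprime(dc, d, sc, s)
        for dc, d, sc, s in zip(df["n_diff_correct"], df["n_diff_trials"],
                                df["n_same_correct"], df["n_same_trials"])
    ]
    return df


def group_curve(curves: pd.DataFrame, group: str,
                grade: int | None = None) -> pd.DataFrame:
    """Mean, SD and n of d' per continuum x center within one group.

    Grades are collapsed unless ``grade`` is given.  Requires at least two
    subjects in the selection.
    """
    sel = curves[curves["group"] == group]
    if grade is not None:
        sel = sel[sel["grade"] == grade]
    if sel["subject_id"].nunique() < 2:
        raise ValueError("group_curve needs >= 2 subjects")
    out = (
        sel.groupby(["continuum", "center_vot_ms"], as_index=False)["dprime"]
        .agg(mean_dprime="mean", sd_dprime="std", n="count")
    )
    out.insert(0, "group", group)
    return out
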