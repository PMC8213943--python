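"""Planned peak contrasts on discrimination curves.

Two theoretically motivated contrasts summarise each subject's curve:

* *phonemic peak* — d' at the between-category pair (the center among
  {-10, 0, +10} ms nearest the subject's fitted identification boundary,
  defaulting to 0 on ties or a missing boundary) minus the mean d' of the
  reference pairs centered on -40, -20, +20 and +40 ms.  The +-10-ms
  centers are excluded because the phonemic boundary fluctuates around
  0 ms, and the +-30-ms centers because they straddle the allophonic
  boundaries.
* *allophonic peaks* — mean d' of the pairs straddling the universal
  +-30-ms boundaries minus the mean d' of the same four reference pairs.

Both contrasts are linear in the d' values: scaling the curve scales the
contrast, adding a constant leaves it unchanged.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .anova import one_way_anova, rm_anova_gg

__all__ = ["phonemic_peak", "allophonic_peaks", "contrast_table",
           "contrast_group_test", "rm_anova_gg"]

_REFERENCE_CENTERS = (-40, -20, 20, 40)
_PHONEMIC_CANDIDATES = (-10, 0, 10)
_ALLOPHONIC_CENTERS = (-30, 30)


def _curve_map(curve: pd.DataFrame) -> dict[int, float]:
    return dict(zip(curve["center_vot_ms"].astype(int), curve["dprime"]))


def select_phonemic_center(boundary_ms: float | None) -> int:
    """Center among {-10, 0, +10} nearest the fitted boundary (ties -> 0)."""
    if boundary_ms is None or not math.isfinite(boundary_ms):
        return 0
    dists = {c: abs(boundary_ms - c) for c in _PHONEMIC_CANDIDATES}
    best = min(dists.values())
    winners = [c for c, d in dists.items() if math.isclose(d, best)]
    return 0 if len(winners) > 1 else winners[0]


def phonemic_peak(curve: pd.DataFrame,
                  boundary_ms: float | None = None) -> tuple[float, int]:
    """(contrast value, selected center); NaN when required centers miss."""
    d = _curve_map(curve)
    center = select_phonemic_center(boundary_ms)
    ref = [d.get(c, math.nan) for c in _REFERENCE_CENTERS]
    peak = d.get(center, math.nan)
    if any(not math.isfinite(v) for v in ref) or not math.isfinite(peak):
        return (math.nan, center)
    return (peak - float(np.mean(ref)), center)


def allophonic_peaks(curve: pd.DataFrame) -> float:
    """Mean d' at +-30 ms minus mean d' at the four reference centers."""
    d = _curve_map(curve)
    allo = [d.get(c, math.nan) for c in _ALLOPHONIC_CENTERS]
    ref = [d.get(c, math.nan) for c in _REFERENCE_CENTERS]
    vals = allo + ref
    if any(not math.isfinite(v) for v in vals):
        return math.nan
    return float(np.mean(allo) - np.mean(ref))


def contrast_table(curves: pd.DataFrame,
                   ident_fits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per subject x continuum contrast scores.

    When ``ident_fits`` is given, the subject's fitted boundary on the
    same continuum steers the phonemic-center selection.
    """
    boundary: dict[tuple, float] = {}
    if ident_fits is not None:
        boundary = {
            (r.subject_id, r.continuum): r.boundary_ms
            for r in ident_fits.itertuples()
        }
    rows = []
    keys = ["subject_id", "group", "grade", "continuum"]
    for key, sub in curves.groupby(keys, sort=True):
        b = boundary.get((key[0], key[3]))
        phon, center = phonemic_peak(sub, b)
        rows.append(dict(zip(keys, key), phonemic_peak=phon,
                         allophonic_peaks=allophonic_peaks(sub),
                         selected_center_ms=center))
    return pd.DataFrame(rows)


def contrast_group_test(scores: pd.DataFrame, value_col: str,
                        group_col: str = "group") -> dict:
    """One-way ANOVA of a per-subject contrast score across groups.

    For two groups this is the planned Group x VOT interaction contrast;
    F then equals t^2.  Returns F, df, p, partial eta^2 and (two groups)
    Cohen's d with the group order used for the sign.
    """
    sub = scores.dropna(subset=[value_col])
    return one_way_anova(sub[value_col].to_numpy(), sub[group_col].to_numpy())


def group_by_vot_anova(curves: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Group x VOT mixed ANOVA on one continuum's d' curves (GG-adjusted)."""
    wide = curves.pivot_table(index="subject_id", columns="center_vot_ms",
                              values="dprime")
    groups = curves.groupby("subject_id")[group_col].first()
    return rm_anova_gg(wide, groups=groups)
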