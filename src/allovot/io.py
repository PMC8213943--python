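"""Trial-table readers, writers, validators and aggregators.

All tables are plain UTF-8 CSV, one row per trial:

``ident_trials.csv``
    subject_id, group, grade, continuum, trial_index, vot_ms, response

``discrim_trials.csv``
    subject_id, group, grade, continuum, trial_index, vot_a_ms, vot_x_ms,
    pair_type, response
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    CONTINUA,
    PAIR_CENTERS_MS,
    PAIR_SEPARATION_MS,
    VOT_LEVELS_MS,
    centers_for_same_pair,
)

log = logging.getLogger(__name__)

GROUPS = ("NR", "DYS")
GRADES = (2, 4)

IDENT_COLUMNS = ["subject_id", "group", "grade", "continuum", "trial_index",
                 "vot_ms", "response"]
DISCRIM_COLUMNS = ["subject_id", "group", "grade", "continuum", "trial_index",
                   "vot_a_ms", "vot_x_ms", "pair_type", "response"]

IDENT_RESPONSES = ("voiced", "voiceless")
DISCRIM_RESPONSES = ("same", "different")


class ValidationError(ValueError):
    """Malformed trial table; message lists the offending rows."""


def _check(df: pd.DataFrame, mask: pd.Series, message: str,
           problems: list[str]) -> None:
    bad = df.index[mask]
    if len(bad):
        rows = ", ".join(str(i) for i in bad[:10])
        more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
        problems.append(f"{message}: rows [{rows}]{more}")


def validate_ident(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type an identification trial table."""
    problems: list[str] = []
    missing = [c for c in IDENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    df = df.copy()
    df["grade"] = pd.to_numeric(df["grade"], errors="coerce")
    df["vot_ms"] = pd.to_numeric(df["vot_ms"], errors="coerce")
    _check(df, ~df["group"].isin(GROUPS), "illegal group label", problems)
    _check(df, ~df["grade"].isin(GRADES), "illegal grade", problems)
    _check(df, ~df["continuum"].isin(CONTINUA), "illegal continuum", problems)
    _check(df, ~df["vot_ms"].isin(VOT_LEVELS_MS), "VOT off the stimulus grid",
           problems)
    _check(df, ~df["response"].isin(IDENT_RESPONSES), "illegal response label",
           problems)
    if problems:
        raise ValidationError("; ".join(problems))
    df["grade"] = df["grade"].astype(int)
    df["vot_ms"] = df["vot_ms"].astype(int)
    return df


def validate_discrim(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a discrimination trial table."""
    problems: list[str] = []
    missing = [c for c in DISCRIM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    df = df.copy()
    df["grade"] = pd.to_numeric(df["grade"], errors="coerce")
    for col in ("vot_a_ms", "vot_x_ms"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        _check(df, ~df[col].isin(VOT_LEVELS_MS), f"{col} off the stimulus grid",
               problems)
    _check(df, ~df["group"].isin(GROUPS), "illegal group label", problems)
    _check(df, ~df["grade"].isin(GRADES), "illegal grade", problems)
    _check(df, ~df["continuum"].isin(CONTINUA), "illegal continuum", problems)
    _check(df, ~df["pair_type"].isin(("same", "different")),
           "illegal pair_type", problems)
    _check(df, ~df["response"].isin(DISCRIM_RESPONSES),
           "illegal response label", problems)
    sep = (df["vot_a_ms"] - df["vot_x_ms"]).abs()
    _check(df, (df["pair_type"] == "different") & (sep != PAIR_SEPARATION_MS),
           f"different pair not separated by {PAIR_SEPARATION_MS} ms", problems)
    _check(df, (df["pair_type"] == "same") & (sep != 0),
           "same pair with unequal stimuli", problems)
    if problems:
        raise ValidationError("; ".join(problems))
    df["grade"] = df["grade"].astype(int)
    df["vot_a_ms"] = df["vot_a_ms"].astype(int)
    df["vot_x_ms"] = df["vot_x_ms"].astype(int)
    return df


def read_trials(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Parameters
    ----------
    path:
        CSV file with the documented header.
    kind:
        ``"ident"`` or ``"discrim"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str, "continuum": str})
    if df.empty:
        log.warning("trial file %s is empty (header only)", path)
    if kind == "ident":
        return validate_ident(df) if not df.empty else df
    if kind == "discrim":
        return validate_discrim(df) if not df.empty else df
    raise ValueError(f"kind must be 'ident' or 'discrim', got {kind!r}")


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def aggregate_ident(trials: pd.DataFrame) -> pd.DataFrame:
    """Count trials and "voiceless" responses per subject x continuum x VOT.

    Returns a frame with columns subject_id, group, grade, continuum,
    vot_ms, n_trials, n_voiceless.  Trial totals are conserved exactly.
    """
    keys = ["subject_id", "group", "grade", "continuum", "vot_ms"]
    out = (
        trials.assign(voiceless=(trials["response"] == "voiceless").astype(int))
        .groupby(keys, as_index=False, sort=True)
        .agg(n_trials=("response", "size"), n_voiceless=("voiceless", "sum"))
    )
    return out


def aggregate_discrim(trials: pd.DataFrame) -> pd.DataFrame:
    """Pool AX responses into per-center counts.

    For a center c the "different" counts pool both presentation orders of
    the pair (c-10, c+10); the "same" counts pool the two constituent same
    pairs (c-10, c-10) and (c+10, c+10), so an interior same pair feeds two
    adjacent centers.  Correct means "different" on a different pair and
    "same" on a same pair.

    Centers with zero same or zero different trials are flagged
    ``incomplete``.
    """
    keys = ["subject_id", "group", "grade", "continuum"]
    records: list[dict] = []
    diff = trials[trials["pair_type"] == "different"]
    same = trials[trials["pair_type"] == "same"]

    dcounts: dict[tuple, np.ndarray] = {}
    for (sid, grp, grd, cont), sub in diff.groupby(keys, sort=True):
        center = ((sub["vot_a_ms"] + sub["vot_x_ms"]) // 2).to_numpy()
        correct = (sub["response"] == "different").to_numpy()
        for c in np.unique(center):
            m = center == c
            dcounts[(sid, grp, grd, cont, int(c))] = np.array(
                [m.sum(), correct[m].sum()]
            )

    scounts: dict[tuple, np.ndarray] = {}
    for (sid, grp, grd, cont), sub in same.groupby(keys, sort=True):
        vot = sub["vot_a_ms"].to_numpy()
        correct = (sub["response"] == "same").to_numpy()
        for v in np.unique(vot):
            m = vot == v
            for c in centers_for_same_pair(int(v)):
                key = (sid, grp, grd, cont, c)
                scounts[key] = scounts.get(key, np.zeros(2, dtype=int)) + np.array(
                    [m.sum(), correct[m].sum()]
                )

    subjects = sorted(set(k[:4] for k in dcounts) | set(k[:4] for k in scounts))
    for sub_key in subjects:
        for c in PAIR_CENTERS_MS:
            d = dcounts.get((*sub_key, c), np.zeros(2, dtype=int))
            s = scounts.get((*sub_key, c), np.zeros(2, dtype=int))
            records.append(
                dict(
                    zip(keys, sub_key),
                    center_vot_ms=c,
                    n_diff_trials=int(d[0]),
                    n_diff_correct=int(d[1]),
                    n_same_trials=int(s[0]),
                    n_same_correct=int(s[1]),
                    incomplete=bool(d[0] == 0 or s[0] == 0),
                )
            )
    return pd.DataFrame.from_records(records)
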