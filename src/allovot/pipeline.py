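"""End-to-end pipeline: simulate -> fit -> score -> contrast -> oscillator -> sweep.

Every stage reads and writes plain CSV so each module is independently
testable; a JSON manifest records the package version, master seed,
config hash and per-table row counts.  Reruns with an identical config
are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortSpec, FieldSpec, GroupParams, default_cohort_spec,
                     simulate_cohort)
from .contrasts import contrast_group_test, contrast_table, group_by_vot_anova
from .design import CONTINUA
from .io import (aggregate_discrim, aggregate_ident, read_trials, write_trials)
from .oscillator import (F_HIGH_DEFAULT, default_sweep_grid, fit_all_oscillator,
                         frequency_sweep, model_vs_data_F, weight_tests)
from .richards import FLAT_THRESHOLD, fit_all
from .sdt import build_curves, group_curve

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Switches and inputs for one pipeline run.

    Either ``ident_path``/``discrim_path`` point at existing trial CSVs,
    or ``simulate=True`` generates them from the cohort spec.
    """

    out_dir: str = "allovot_out"
    seed: int = 0
    simulate: bool = True
    ident_path: str | None = None
    discrim_path: str | None = None
    flat_threshold: float = FLAT_THRESHOLD
    sweep_grid_hz: list[float] = field(
        default_factory=lambda: [float(f) for f in default_sweep_grid()])
    oscillator_continuum: str = "ba_pa"
    exclude_flat: bool = True
    cohort_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        cells = raw.get("cohort_overrides", {}).get("n_per_cell")
        if cells:
            raw["cohort_overrides"]["n_per_cell"] = {
                _cell_key_str(k): v for k, v in cells.items()}
        return raw

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant config (the output path excluded,
        so reruns into different directories hash identically)."""
        raw = self.to_dict()
        raw.pop("out_dir", None)
        blob = json.dumps(raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cell_key_str(key) -> str:
    """Normalize a (group, grade) cell key to the serializable "NR,2" form."""
    if isinstance(key, str):
        return key
    group, grade = key
    return f"{group},{grade}"


def _cell_key_tuple(key) -> tuple[str, int]:
    if isinstance(key, str):
        group, grade = key.split(",")
        return (group.strip(), int(grade))
    return (key[0], int(key[1]))


def _cohort_spec(config: PipelineConfig) -> CohortSpec:
    ov = dict(config.cohort_overrides)
    if "n_per_cell" in ov:
        ov["n_per_cell"] = {_cell_key_tuple(k): v
                            for k, v in ov["n_per_cell"].items()}
    gp = ov.pop("group_params", None)
    spec = default_cohort_spec(seed=config.seed, **ov)
    if gp:
        groups = {
            name: GroupParams(**{f: FieldSpec(**fs) for f, fs in fields.items()})
            for name, fields in gp.items()
        }
        spec = dataclasses.replace(spec, group_params=groups)
    return spec


def run_all(config: PipelineConfig) -> dict:
    """Run every stage, writing tables and a manifest under ``out_dir``.

    Returns the manifest.  A stage failure raises :class:`StageError`
    naming the stage; tables already written are retained and a FAILED
    marker file records the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "statistics_notes": {
            "group_weight_tests": "rank-sum normal approximation (z)",
            "one_sample_weight_tests": "signed-rank normal approximation (z)",
        },
        "tables": {},
    }
    stage = "setup"

    def save(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / f"{name}.csv", index=False)
        manifest["tables"][name] = {"rows": int(len(df))}

    try:
        stage = "simulate" if config.simulate else "load"
        if config.simulate:
            spec = _cohort_spec(config)
            ident, discrim, truth = simulate_cohort(spec)
            write_trials(ident, out / "ident_trials.csv")
            write_trials(discrim, out / "discrim_trials.csv")
            save("truth", truth)
            manifest["tables"]["ident_trials"] = {"rows": int(len(ident))}
            manifest["tables"]["discrim_trials"] = {"rows": int(len(discrim))}
        else:
            if not config.ident_path or not config.discrim_path:
                raise StageError("load: ident_path and discrim_path required "
                                 "when simulate is false")
            ident = read_trials(config.ident_path, "ident")
            discrim = read_trials(config.discrim_path, "discrim")

        stage = "fit-ident"
        ident_counts = aggregate_ident(ident)
        fits = fit_all(ident_counts)
        save("ident_fits", fits)

        stage = "screen-flat"
        flat_subjects = sorted(fits.loc[fits["flat"], "subject_id"].unique())
        manifest["n_subjects"] = int(fits["subject_id"].nunique())
        manifest["n_flat_excluded"] = len(flat_subjects)
        manifest["n_retained"] = manifest["n_subjects"] - len(flat_subjects)
        if config.exclude_flat and flat_subjects:
            fits = fits[~fits["subject_id"].isin(flat_subjects)]
            discrim = discrim[~discrim["subject_id"].isin(flat_subjects)]

        stage = "score"
        counts = aggregate_discrim(discrim)
        curves = build_curves(counts)
        save("dprime", curves)

        stage = "contrasts"
        scores = contrast_table(curves, ident_fits=fits)
        save("contrasts", scores)
        anova_rows = []
        for cont in sorted(curves["continuum"].unique()):
            sub = curves[curves["continuum"] == cont]
            tab = group_by_vot_anova(sub)
            tab.insert(0, "continuum", cont)
            anova_rows.append(tab)
            sc = scores[scores["continuum"] == cont]
            for name in ("phonemic_peak", "allophonic_peaks"):
                t = contrast_group_test(sc, name)
                anova_rows.append(pd.DataFrame([{
                    "continuum": cont, "effect": f"{name}_group_contrast",
                    "SS": float("nan"), "df1": t["df1"], "df2": t["df2"],
                    "eps": 1.0, "df1_gg": t["df1"], "df2_gg": t["df2"],
                    "F": t["F"], "p": t["p"],
                    "partial_eta2": t["partial_eta2"],
                }]))
        save("anova", pd.concat(anova_rows, ignore_index=True))

        stage = "oscillator"
        osc_cont = config.oscillator_continuum
        osc_curves = curves[curves["continuum"] == osc_cont]
        osc_fits = fit_all_oscillator(osc_curves, f_high=F_HIGH_DEFAULT)
        save("oscillator_fits", osc_fits)
        save("weight_tests", weight_tests(osc_fits))
        fit_idx = []
        for g in sorted(osc_fits["group"].unique()):
            res = model_vs_data_F(osc_fits[osc_fits["group"] == g],
                                  osc_curves[osc_curves["group"] == g])
            fit_idx.append(dict(group=g, F=res["F"], df1=res["df1_gg"],
                                df2=res["df2_gg"], p=res["p"]))
        save("model_vs_data", pd.DataFrame(fit_idx))

        stage = "sweep"
        sweep = frequency_sweep(osc_curves, config.sweep_grid_hz)
        save("sweep", sweep)

        stage = "report"
        save("report_ident", report_ident(fits))
        save("report_curves", report_curves(curves))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    hashable = dict(manifest, config={k: v for k, v in manifest["config"].items()
                                      if k != "out_dir"})
    manifest_blob = json.dumps(hashable, indent=2, sort_keys=True)
    manifest["manifest_hash"] = hashlib.sha256(manifest_blob.encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    (out / "FAILED").unlink(missing_ok=True)
    return manifest


def report_ident(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of boundary (ms), asymptotic width (proportion) and slope
    (logit/ms) per group x grade x continuum."""
    rows = []
    ok = fits[fits["converged"]]
    for (grp, grd, cont), sub in ok.groupby(["group", "grade", "continuum"]):
        rows.append(dict(
            group=grp, grade=grd, continuum=cont, n=len(sub),
            boundary_ms_mean=sub["boundary_ms"].mean(),
            boundary_ms_sd=sub["boundary_ms"].std(),
            asym_width_mean=sub["asym_width"].mean(),
            asym_width_sd=sub["asym_width"].std(),
            slope_mean=sub["slope"].mean(),
            slope_sd=sub["slope"].std(),
        ))
    return pd.DataFrame(rows)


def report_curves(curves: pd.DataFrame) -> pd.DataFrame:
    """Group discrimination curves (grades collapsed) per continuum."""
    parts = [group_curve(curves, g) for g in sorted(curves["group"].unique())]
    return pd.concat(parts, ignore_index=True)
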