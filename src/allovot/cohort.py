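"""Synthetic cohort generator for the VOT perception tasks.

Simulates trial-level identification and AX-discrimination data with the
statistical structure the analysis pipeline assumes, so every stage can
be tested end to end without the original behavioral recordings.

Each simulated child carries, per continuum, Richards identification
parameters (the generative side of the psychometric model) and oscillator
parameters (the generative side of the discrimination model), plus a
same-different response criterion.  Identification responses are Bernoulli
draws from the Richards probability; discrimination responses follow a
yes/no signal-detection link to the oscillator-model sensitivity d'(c):

    P("different" | different pair at center c) = Phi(d'(c)/2 - criterion)
    P("different" | same pair at VOT v)         = Phi(-d'(v)/2 - criterion)

which preserves the z-difference identity z(H) - z(F) = d' used by the
scoring stage.

The shipped presets emulate the study conditions: two reader groups
(normal readers NR and dyslexic readers DYS) in two grades with group
sizes 64/43 (NR grades 2/4) and 57/40 (DYS), 11-step continua, 8
repetitions per identification stimulus and AX pair.  The NR preset has
almost all its cosine weight on the 16.67-Hz subharmonic, producing a
single discrimination peak at 0 ms; the DYS preset splits the weight
equally between the 33.33- and 16.67-Hz components, adding peaks at
+-30 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .design import CONTINUA, ContinuumDesign, enumerate_design
from .oscillator import OscillatorParams, predict_dprime
from .richards import RichardsParams, richards_probability

__all__ = [
    "FieldSpec",
    "GroupParams",
    "CohortSpec",
    "SubjectParams",
    "default_cohort_spec",
    "sample_subject",
    "simulate_ident",
    "simulate_discrim",
    "simulate_cohort",
    "true_dprime_curve",
]


class ConfigError(ValueError):
    """Impossible generative configuration (e.g. mean outside bounds, SD 0)."""


@dataclass(frozen=True)
class FieldSpec:
    """Truncated-normal spec for one generative parameter."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd < 0:
            raise ConfigError("SD must be >= 0")
        if self.sd == 0:
            if not (self.lo <= self.mean <= self.hi):
                raise ConfigError(
                    f"mean {self.mean} outside [{self.lo}, {self.hi}] with SD 0"
                )
            return self.mean
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   random_state=rng))


@dataclass(frozen=True)
class GroupParams:
    """Generative distributions for one reader group."""

    I: FieldSpec
    S: FieldSpec
    K1: FieldSpec
    K2: FieldSpec
    k: FieldSpec
    w33: FieldSpec
    w17: FieldSpec
    criterion: FieldSpec


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth parameters of one simulated subject."""

    subject_id: str
    group: str
    grade: int
    ident: dict[str, RichardsParams]       # per continuum
    osc: dict[str, OscillatorParams]       # per continuum
    criterion: float


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes, generative distributions, trial counts and seed."""

    n_per_cell: dict[tuple[str, int], int] = field(
        default_factory=lambda: {("DYS", 2): 57, ("NR", 2): 64,
                                 ("DYS", 4): 40, ("NR", 4): 43}
    )
    group_params: dict[str, GroupParams] = field(default_factory=dict)
    continua: tuple[str, ...] = CONTINUA
    ident_reps: int = 8
    pair_reps: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_cell.values()):
            raise ConfigError("every group x grade cell needs n >= 1")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_cell.values())


def _default_group_params() -> dict[str, GroupParams]:
    # NR: steep identification, wide asymptotes, cosine weight concentrated
    # on the 16.67-Hz subharmonic (single 0-ms discrimination peak).
    # DYS: shallower identification, narrower asymptotes, equal 33.33- and
    # 16.67-Hz weights (added +-30-ms peaks) with lower overall amplitude,
    # mirroring the smaller dyslexic phonemic peak.
    return {
        "NR": GroupParams(
            I=FieldSpec(-1.5, 2.0),
            S=FieldSpec(0.5, 0.2, lo=0.05, hi=1.5),
            K1=FieldSpec(0.08, 0.05, lo=0.0, hi=0.45),
            K2=FieldSpec(0.85, 0.08, lo=0.55, hi=1.0),
            k=FieldSpec(0.01, 0.005),
            w33=FieldSpec(0.0, 0.15),
            w17=FieldSpec(0.9, 0.15),
            criterion=FieldSpec(0.2, 0.2),
        ),
        "DYS": GroupParams(
            I=FieldSpec(-1.0, 2.0),
            S=FieldSpec(0.35, 0.2, lo=0.05, hi=1.5),
            K1=FieldSpec(0.15, 0.08, lo=0.0, hi=0.45),
            K2=FieldSpec(0.82, 0.08, lo=0.55, hi=1.0),
            k=FieldSpec(0.0, 0.005),
            w33=FieldSpec(0.35, 0.15),
            w17=FieldSpec(0.35, 0.15),
            criterion=FieldSpec(0.2, 0.2),
        ),
    }


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Cohort spec with the shipped NR/DYS presets and study cell sizes."""
    return CohortSpec(group_params=_default_group_params(), seed=seed,
                      **overrides)


def sample_subject(spec: CohortSpec, group: str, grade: int,
                   rng: np.random.Generator,
                   subject_id: str = "S000") -> SubjectParams:
    """Draw one subject's ground-truth parameters.

    Every field is drawn independently from its truncated normal; the
    K1 < K2 ordering is enforced by resampling (the default bounds make a
    violation impossible, but user-supplied specs may overlap).
    """
    gp = spec.group_params[group]
    ident: dict[str, RichardsParams] = {}
    osc: dict[str, OscillatorParams] = {}
    for cont in spec.continua:
        for _ in range(100):
            k1, k2 = gp.K1.draw(rng), gp.K2.draw(rng)
            if k1 < k2:
                break
        else:
            raise ConfigError("could not draw K1 < K2 in 100 attempts")
        ident[cont] = RichardsParams(I=gp.I.draw(rng), S=gp.S.draw(rng),
                                     K1=k1, K2=k2)
        osc[cont] = OscillatorParams(k=gp.k.draw(rng), w33=gp.w33.draw(rng),
                                     w17=gp.w17.draw(rng))
    return SubjectParams(subject_id=subject_id, group=group, grade=grade,
                         ident=ident, osc=osc,
                         criterion=gp.criterion.draw(rng))


def simulate_ident(subject: SubjectParams, design: ContinuumDesign,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Identification trials for one subject on one continuum."""
    params = subject.ident[design.label]
    vots = np.repeat(design.vot_levels_ms, design.ident_reps)
    vots = vots[rng.permutation(len(vots))]
    p = np.asarray(richards_probability(params, vots))
    voiceless = rng.random(len(vots)) < p
    return pd.DataFrame({
        "subject_id": subject.subject_id,
        "group": subject.group,
        "grade": subject.grade,
        "continuum": design.label,
        "trial_index": np.arange(len(vots)),
        "vot_ms": vots,
        "response": np.where(voiceless, "voiceless", "voiced"),
    })


def _same_pair_fa_probs(design: ContinuumDesign, targets: dict[int, float],
                        ) -> dict[int, float]:
    """Per-same-pair false-alarm probabilities matching the center targets.

    The scoring stage pools the same pairs (c-10, c-10) and (c+10, c+10)
    into center c, so the per-pair probabilities f_v must satisfy
    (f_{c-10} + f_{c+10}) / 2 = F*(c) for every center c.  The stimulus
    grid splits into two independent chains (odd and even multiples of
    10 ms) on which the constraints telescope, leaving one free constant
    per chain: f_j = a_j + (-1)^j f_0.  The constant is taken at the
    midpoint of the interval keeping every f_j inside (0, 1), so the
    pooled false-alarm rate at every center equals the signal-detection
    link at that center's sensitivity and the d' estimator is consistent
    for the generating curve.  (For extreme curves with an empty
    feasibility interval the midpoint compromise is used and the
    probabilities clipped, trading exactness for validity.)
    """
    levels = design.vot_levels_ms
    eps = 1e-3
    f: dict[int, float] = {}
    for start in (levels[0], levels[1]):
        chain = [v for v in levels if (v - start) % 20 == 0]
        # f_j = a_j + s_j * f0 along the chain
        a, s = [0.0], [1.0]
        for prev, cur in zip(chain, chain[1:]):
            a.append(2 * targets[(prev + cur) // 2] - a[-1])
            s.append(-s[-1])
        lo, hi = eps, 1.0 - eps
        for aj, sj in zip(a, s):
            if sj > 0:
                lo, hi = max(lo, eps - aj), min(hi, 1.0 - eps - aj)
            else:
                lo, hi = max(lo, aj - (1.0 - eps)), min(hi, aj - eps)
        f0 = 0.5 * (lo + hi)
        for v, aj, sj in zip(chain, a, s):
            f[v] = aj + sj * f0
    return {v: float(np.clip(p, eps, 1.0 - eps)) for v, p in f.items()}


def simulate_discrim(subject: SubjectParams, design: ContinuumDesign,
                     rng: np.random.Generator) -> pd.DataFrame:
    """AX discrimination trials for one subject on one continuum.

    Different pairs respond "different" with probability
    Phi(d'(c)/2 - criterion) at the pair center c; same pairs use the
    per-pair probabilities from :func:`_same_pair_fa_probs`, so the
    pooled rate at each center is Phi(-d'(c)/2 - criterion).
    """
    osc = subject.osc[design.label]
    crit = subject.criterion
    centers = np.asarray(design.pair_centers_ms, dtype=float)
    d_center = np.asarray(predict_dprime(osc, centers))
    fa_targets = dict(zip(design.pair_centers_ms,
                          norm.cdf(-d_center / 2.0 - crit)))
    fa_probs = _same_pair_fa_probs(design, fa_targets)
    hit_probs = dict(zip(design.pair_centers_ms,
                         norm.cdf(d_center / 2.0 - crit)))

    pairs = list(design.different_pairs) + list(design.same_pairs)
    kinds = ["different"] * len(design.different_pairs) + \
            ["same"] * len(design.same_pairs)
    a = np.repeat([p[0] for p in pairs], design.pair_reps)
    x = np.repeat([p[1] for p in pairs], design.pair_reps)
    kind = np.repeat(kinds, design.pair_reps)
    order = rng.permutation(len(a))
    a, x, kind = a[order], x[order], kind[order]
    p_diff = np.where(
        kind == "different",
        [hit_probs.get((ai + xi) // 2, 0.5) for ai, xi in zip(a, x)],
        [fa_probs.get(ai, 0.5) for ai in a],
    )
    resp = rng.random(len(a)) < p_diff
    return pd.DataFrame({
        "subject_id": subject.subject_id,
        "group": subject.group,
        "grade": subject.grade,
        "continuum": design.label,
        "trial_index": np.arange(len(a)),
        "vot_a_ms": a,
        "vot_x_ms": x,
        "pair_type": kind,
        "response": np.where(resp, "different", "same"),
    })


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame,
                                               pd.DataFrame]:
    """Simulate the full cohort.

    Returns (ident trials, discrim trials, ground-truth parameter table).
    Each subject draws from an independent substream spawned from the
    master seed, so the output is bit-identical under a fixed seed and
    insensitive to cell ordering.
    """
    designs = {c: enumerate_design(c, ident_reps=spec.ident_reps,
                                   pair_reps=spec.pair_reps)
               for c in spec.continua}
    master = np.random.SeedSequence(spec.seed)
    streams = master.spawn(spec.n_subjects)
    ident_parts: list[pd.DataFrame] = []
    discrim_parts: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    i = 0
    for (group, grade), n in sorted(spec.n_per_cell.items()):
        for j in range(n):
            sid = f"{group}{grade}_{j:03d}"
            rng = np.random.default_rng(streams[i])
            i += 1
            subj = sample_subject(spec, group, grade, rng, subject_id=sid)
            for cont, design in designs.items():
                ident_parts.append(simulate_ident(subj, design, rng))
                discrim_parts.append(simulate_discrim(subj, design, rng))
                rp, op = subj.ident[cont], subj.osc[cont]
                truth_rows.append(dict(
                    subject_id=sid, group=group, grade=grade, continuum=cont,
                    I=rp.I, S=rp.S, K1=rp.K1, K2=rp.K2,
                    boundary_ms=-rp.I / rp.S,
                    k=op.k, w33=op.w33, w17=op.w17,
                    criterion=subj.criterion,
                ))
    return (pd.concat(ident_parts, ignore_index=True),
            pd.concat(discrim_parts, ignore_index=True),
            pd.DataFrame(truth_rows))


def true_dprime_curve(osc: OscillatorParams,
                      centers=tuple(range(-40, 41, 10))) -> pd.DataFrame:
    """Noise-free d' curve implied by one subject's oscillator parameters."""
    c = np.asarray(centers, dtype=float)
    return pd.DataFrame({"center_vot_ms": c.astype(int),
                         "dprime": np.asarray(predict_dprime(osc, c))})
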