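# allovot

Analysis pipeline for **categorical perception of voice-onset-time (VOT)
continua** in school-aged readers, including children with dyslexia. It
implements, as tested library code plus a CLI:

- **Identification psychometrics** — per-subject fits of the 4-parameter
  Richards (generalised logistic) function to voiced/voiceless labelling of
  an 11-step VOT continuum (−50 … +50 ms, 10-ms steps),

  P(voiceless | VOT) = K1 + (K2 − K1) · e^y / (1 + e^y),  y = I + S·VOT,

  summarised by the category **boundary** (−I/S, ms), the **slope** S
  (logit/ms) and the **asymptotic width** K2 − K1 — the three standard
  indices of categorical precision — with flat-responder and 75%
  practice-criterion screening.
- **Discrimination scoring** — AX same–different trials on pairs separated
  by 20-ms VOT are pooled per pair center (−40 … +40 ms) and converted to
  sensitivity d′ = z(H) − z(F), with the 1/(2N) correction for extreme
  rates.
- **Planned peak contrasts** — the *phonemic peak* (d′ at the pair
  straddling the 0-ms phonemic boundary minus the mean of the ±40/±20-ms
  reference pairs) and the *allophonic peaks* (mean d′ at ±30 ms minus the
  same reference), tested across reader groups with one-way ANOVA /
  mixed-design repeated-measures ANOVA with Greenhouse–Geisser adjustment.
- **Subharmonic oscillator model** — the discrimination curve modelled as

  d′(VOT) = k·VOT + w33·cos(2π·VOT/30) + w17·cos(2π·VOT/60),

  a 33.33-Hz component tracking the universal allophonic boundaries at
  ±30 ms and its binary subharmonic at 16.67 Hz tracking the phonemic
  boundary at 0 ms. Per-subject closed-form fits, rank-based group tests on
  the weights, a model-vs-data fit index (Score-type × VOT interaction F),
  and a frequency sweep locating the best-fitting oscillator frequency.
- **Synthetic cohort generator** — trial-level identification and
  discrimination data for a two-group (NR/DYS) × two-grade cohort with the
  exact trial schedule of the task (88 identification and 232
  discrimination trials per continuum), used for end-to-end testing and
  parameter-recovery studies. The NR preset produces a single 0-ms
  discrimination peak; the DYS preset adds ±30-ms allophonic peaks.

## Worked example

```python
import dataclasses
from allovot import default_cohort_spec, simulate_cohort, fit_richards
from allovot.io import aggregate_ident, aggregate_discrim
from allovot.sdt import build_curves
from allovot.oscillator import fit_all_oscillator, weight_tests

spec = dataclasses.replace(default_cohort_spec(seed=42),
                           n_per_cell={("NR", 2): 20, ("DYS", 2): 20})
ident, discrim, truth = simulate_cohort(spec)

counts = aggregate_ident(ident)
one = counts[(counts.subject_id == "NR2_000") & (counts.continuum == "ba_pa")]
fit = fit_richards(one)
print(f"boundary = {fit.boundary_ms:+.1f} ms, slope = {fit.slope:.2f} "
      f"logit/ms, asymptotic width = {fit.asym_width:.2f}")

curves = build_curves(aggregate_discrim(discrim))
osc = fit_all_oscillator(curves[curves.continuum == "ba_pa"])
print(osc.groupby("group")[["k", "w33", "w17"]].mean().round(3))
wt = weight_tests(osc).set_index(["test", "group"])
print(f"17-Hz weight, DYS vs NR: z = "
      f"{wt.loc[('w17_between_groups', 'DYS-vs-NR'), 'z']:.2f}")
```

prints

```
boundary = +12.0 ms, slope = 0.17 logit/ms, asymptotic width = 0.94
           k    w33    w17
group
DYS    0.003  0.448  0.346
NR     0.012  0.021  0.967
17-Hz weight, DYS vs NR: z = -4.65
```

The first line is one simulated child's identification fit: the voicing
boundary sits 12 ms into the positive-VOT region, the shallow slope and
wide asymptotes describe how sharply labelling switches between categories.
The group table shows the oscillator decomposition of the discrimination
curves: the normal-reading preset concentrates its cosine weight on the
16.67-Hz subharmonic (single phonemic peak), the dyslexic-like preset
splits it between 33.33 Hz and 16.67 Hz (additional allophonic peaks); the
rank-sum z confirms the group difference in subharmonic weight.

The same stages are available from the shell:

```bash
allovot simulate --out run/ --seed 7
allovot run-all --out run/ --seed 7
```

`run-all` writes every stage table (`ident_fits.csv`, `dprime.csv`,
`contrasts.csv`, `anova.csv`, `oscillator_fits.csv`, `weight_tests.csv`,
`model_vs_data.csv`, `sweep.csv`, group report tables) plus a
`manifest.json` recording the seed, config hash and row counts; reruns
with the same seed are bit-identical.

## Layout

| module | contents |
| --- | --- |
| `allovot.design` | continuum/trial-schedule enumeration |
| `allovot.io` | trial-table CSV readers/writers, validation, aggregation |
| `allovot.cohort` | synthetic cohort generator and presets |
| `allovot.richards` | Richards psychometric fits and screening |
| `allovot.sdt` | d′ scoring of same–different data |
| `allovot.contrasts` | planned peak contrasts and group tests |
| `allovot.anova` | repeated-measures ANOVA engine with GG adjustment |
| `allovot.oscillator` | oscillator model, weight tests, frequency sweep |
| `allovot.pipeline` / `allovot.cli` | orchestration and the `allovot` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
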