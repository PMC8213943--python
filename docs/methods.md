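# Methods

## Task design

Each of the three consonant continua (ba/pa, de/te, di/ti) comprises 11
synthetic stimuli with VOT from −50 to +50 ms in 10-ms steps.
Identification presents every stimulus 8 times (88 trials per continuum).
AX discrimination uses "different" pairs separated by 20-ms VOT — 9
unordered combinations × 2 presentation orders = 18 pairs — plus the 11
"same" pairs, each presented 8 times (232 trials per continuum).
Discrimination is indexed by the pair *center*, the midpoint of a
different pair, giving 9 centers from −40 to +40 ms. When pooling, the
counts for center c combine both orders of (c−10, c+10) and the two
constituent same pairs (c−10, c−10) and (c+10, c+10); an interior same
pair therefore contributes to two adjacent centers. Centers missing
either pair type are flagged incomplete and propagate as missing values.

## Identification model

The probability of a "voiceless" response is the 4-parameter Richards
function P = K1 + (K2−K1)·e^y/(1+e^y) with y = I + S·VOT. Derived
measures: boundary −I/S (the VOT of the 50% crossing between the
asymptotes), slope S (logit/ms) and asymptotic width K2 − K1. Fitting is
unweighted least squares on the per-stimulus response proportions
(nonlinear regression on proportions, not trial-level likelihood), which
makes the fit a function of the aggregated counts only. Numerical
choices:

- parameter box: I ∈ [−25, 25], S ∈ [−2, 2], K1 ∈ [0, 0.5],
  K2 ∈ [0.5, 1] (the asymptote split at 0.5 guarantees K1 < K2 and an
  identifiable curve orientation);
- deterministic multistart: a 3×3×3×3 grid of initial values (boundary
  quartiles × slope decades × asymptote levels) plus a moment-based
  heuristic start, ranked by initial residual sum of squares; local
  trust-region optimisation from the best four, tolerances 10⁻¹².
  The multistart guards against the shallow, correlated I–S ridge of the
  Richards surface.
- a subject×continuum is *flat* when the observed endpoint proportions
  differ by less than 0.25 or the fit fails to converge. The threshold
  mirrors the 75% practice-screening criterion applied to the endpoint
  stimuli (pass iff ≥ 75% of endpoint items are labelled correctly).
  Constant response vectors short-circuit to flat with an undefined
  boundary. Flat subjects are excluded from group analyses by the
  pipeline, and the retained count is reported in the manifest, not
  asserted (it is data-dependent).

## Discrimination scoring

Per center, the hit rate H is the proportion of "different" responses to
different pairs and the false-alarm rate F is 1 minus the proportion of
"same" responses to the pooled same pairs; d′ = z(H) − z(F). Proportions
of 0 or 1 are replaced by 1/(2N) and 1 − 1/(2N) before the inverse-normal
transform — the standard correction, which bounds |d′| by 2·z(1 − 1/(2N)).
The correct score is the plain mean of the two proportions correct.
Positive d′ means better-than-chance discrimination.

## Planned contrasts and ANOVA

The *phonemic peak* is d′ at the between-category center — the member of
{−10, 0, +10} ms nearest the subject's fitted identification boundary,
with ties and missing boundaries defaulting to 0 — minus the mean d′ over
the reference centers {−40, −20, +20, +40}; ±10-ms centers are excluded
because the empirical boundary fluctuates around 0 ms, ±30-ms centers
because they straddle the allophonic boundaries. The *allophonic peaks*
contrast is the mean d′ at ±30 ms minus the same reference mean. Both are
linear in the curve. Group differences in the per-subject contrast scores
are tested by one-way ANOVA (equivalent to the planned Group × VOT
interaction contrast; F = t² for two groups) with partial η² =
SS_effect/(SS_effect+SS_error) and Cohen's d on the pooled SD.

The repeated-measures engine implements the split-plot decomposition (one
between-subject grouping factor × one within-subject factor) with the
Greenhouse–Geisser epsilon computed from the double-centered covariance
of the within-level scores — ε = tr(S̃)²/((k−1)·tr(S̃²)), pooled within
groups, floored at 1/(k−1), capped at 1, and exactly 1 for two levels —
applied to the within and interaction degrees of freedom. The engine is
written in-package because the model-vs-data fit index needs the
GG-adjusted interaction of *two* within factors, which no installed
library provides; for a two-level factor that interaction reduces to the
one-way repeated-measures test on the per-level condition differences,
which is how it is computed. The implementation is cross-checked against
pingouin (epsilon, within and mixed ANOVA) in the test suite. Rows with
missing cells are dropped listwise.

## Oscillator model

d′(VOT) = k·VOT + w33·cos(2π·f·VOT) + w17·cos(2π·(f/2)·VOT) with
f = 1/30 cycles/ms: a 33.33-Hz component whose period matches the 30-ms
spacing of the universal allophonic boundaries, and its binary
subharmonic at exactly 16.67 Hz carrying the single phonemic peak at
0 ms. The exact fractions are used rather than rounded decimals. The
linear term absorbs the overall rise of discriminability with positive
VOT. With frequencies fixed the model is linear in (k, w33, w17) and is
fitted by the normal equations (least squares, no intercept — the
cosines span the constant direction at the 9 centers closely enough that
an intercept would be nearly collinear). The equivalent (D, C)
parameterisation with cosine weights D + C and D − C, i.e.
D = (w33+w17)/2 and C = (w33−w17)/2, is emitted alongside. Fits require
≥ 4 non-missing centers.

Group inference on the fitted weights uses rank-based tests reported as
normal-approximation z: rank-sum (midranks, tie-corrected variance) for
between-group differences, signed-rank for one-sample and paired
(w33 vs w17) comparisons; the choice is recorded in the run manifest.
Model adequacy is indexed by the Score-type (model, data) × VOT
interaction F with GG-adjusted df — 0 when predictions equal
observations, small when the model tracks the curves. The frequency
sweep refits every subject on a grid of high frequencies (default
20–45 Hz in 1-Hz steps plus the exact 33.33-Hz anchor), each paired with
its binary subharmonic, and reports the per-group fit index; the minimum
locates the best-fitting oscillator frequency, and on noise-free data
generated at 33.33 Hz it falls exactly there.

## Synthetic cohort

The generator emulates the study conditions: cell sizes 57/64/40/43
(DYS-2/NR-2/DYS-4/NR-4; 204 children), three continua, 8 repetitions per
stimulus and pair. Each subject draws, independently per field and per
continuum, from truncated normal distributions (K1 ∈ [0, 0.45],
K2 ∈ [0.55, 1], S > 0.05; the disjoint asymptote ranges guarantee
K1 < K2, with a resampling guard for user-supplied overlapping bounds).
Identification responses are Bernoulli draws from the Richards
probability; trial order is pseudorandomised. Per-subject substreams are
spawned from the master seed, so cohorts are bit-identical under a fixed
seed.

Discrimination responses follow a yes/no signal-detection link that
preserves the z-difference identity: on a different pair at center c,
P("different") = Φ(d′(c)/2 − criterion) with d′(c) from the subject's
oscillator parameters; the pooled same-pair rate at center c is
Φ(−d′(c)/2 − criterion). Because each same pair is pooled into two
adjacent centers, per-pair probabilities are not free: they must satisfy
(f_{c−10} + f_{c+10})/2 = F*(c) at every center. These constraints
telescope along the two parity chains of the stimulus grid, leaving one
free constant per chain, chosen at the midpoint of the interval that
keeps every per-pair probability inside (0, 1). This makes the scoring
stage's d′ estimator consistent for the generating curve — the property
the recovery tests rely on. (A naive per-pair rule — generating each same
pair from the d′ at its own VOT — biases the recovered 33-Hz weight by a
factor ≈ 4, because the 30-ms-period cosine reverses sign between
adjacent centers and pooling averages it away.) For extreme curves whose
feasibility interval is empty the midpoint compromise is clipped,
trading exactness for valid probabilities; the shipped presets are
comfortably feasible.

Preset parameters (means; between-subject SDs in parentheses):

| group | I | S (logit/ms) | K1 | K2 | k (d′/ms) | w33 | w17 | criterion |
| --- | --- | --- | --- | --- | --- | --- | --- | --- |
| NR | −1.5 (2.0) | 0.50 (0.20) | 0.08 (0.05) | 0.85 (0.08) | 0.010 (0.005) | 0.00 (0.15) | 0.90 (0.15) | 0.2 (0.2) |
| DYS | −1.0 (2.0) | 0.35 (0.20) | 0.15 (0.08) | 0.82 (0.08) | 0.000 (0.005) | 0.35 (0.15) | 0.35 (0.15) | 0.2 (0.2) |

Rationale: NR identification is steeper with wider asymptotes and a
boundary near +3 ms; the NR discrimination curve is carried almost
entirely by the 16.67-Hz subharmonic (fully coupled oscillators, a single
phonemic peak, with a small positive linear trend), while the DYS curve
splits its weight equally between the 33.33- and 16.67-Hz components
(weak subharmonic coupling, hence allophonic peaks) at a lower total
amplitude, giving the dyslexic-like group the smaller phonemic peak and
the larger allophonic contrast on the noise-free curves. The equal-split
DYS weights are deliberately below half the NR subharmonic weight: if the
two groups' summed weights were equal the phonemic-peak contrast would be
degenerate between groups (it depends only on w33 + w17 at center 0), and
a sizable NR 33-Hz mean would make its one-sample test reliably
significant, contradicting the qualitative pattern the presets are meant
to reproduce. The mild positive criterion reflects a small conservative
("same") bias typical of children in AX tasks.

What the generator does *not* emulate: practice/learning and fatigue
effects, lapses, attention fluctuations, response times, grade effects
(grades share the group presets), correlations between identification
and discrimination ability within subject, and lexicality differences
between continua. Passing recovery tests therefore demonstrate that the
pipeline's estimators are consistent for data generated under its own
assumptions — not that real children satisfy those assumptions.

## Problem sizes and determinism

The shipped tests run the full 204-subject cohort once (session fixture,
seed 1) for group-level checks, 10³ repetitions per pair for the
signal-detection round trip, 60 noisy draws against the brute-force grid
oracle for the Richards fit, and a 27-point frequency sweep; the complete
suite finishes in well under a minute on one CPU. All randomness flows
from explicit seeds through numpy Generators; there is no hidden global
state, and identical seeds yield bit-identical trial tables, manifests
and results.

## Known limitations

- The Richards I–S ridge makes individual parameter estimates noisy at 8
  repetitions per stimulus even though the fitted curve (and the derived
  boundary) is stable; group comparisons should use the derived measures.
- The 1/(2N) correction biases d′ toward 0 at extreme performance; with
  16 trials per center the ceiling is |d′| ≤ 3.73.
- The same-pair pooling rule (each interior same pair feeding two
  centers) induces correlation between adjacent centers' false-alarm
  rates; the ANOVA treats centers as exchangeable within-subject levels
  and relies on the GG adjustment to absorb the resulting covariance
  structure.
- The oscillator model is a descriptive decomposition of behavioral
  curves; nothing here measures or claims actual neural oscillations.
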