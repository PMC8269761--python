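# Methods

## The measurement problem

Clinical visual acuity is scored in logMAR (log10 of the minimum angle
of resolution in arcmin; larger = worse, one chart line = 0.1). A chart
varies letter size at fixed distance; the distance-staircase protocol
inverts this, fixing the letter and varying viewing distance. Since the
subtended angle is inversely proportional to distance, demand in logMAR
is `v(d) = v_ref + log10(d_ref/d)` with the 300 cm ⇔ 0.0 logMAR
reference. Both approaches should measure the same threshold; this
package exists to make that claim testable *in silico* — as explicit
algorithms driven by simulated observers — and to provide the agreement
statistics used to evaluate it on real data.

## Distance scale

`AcuityScale` holds the reference pairing, the 15–300 cm range and the
0.1-logMAR line step. The legal grid contains the levels
`v_ref + k·line_step` while they do not exceed the demand at the nearest
legal distance (within 1e−9): fourteen levels, 0.0–1.3 logMAR, for the
defaults. The closest grid point is 15.036 cm; the nominal "15 cm"
bound is read as its rounded display, so the grid is exactly fourteen
lines. Distances are kept as exact floats throughout; rounding to whole
centimetres happens only in display code, because staircase arithmetic
must not accumulate rounding error. `optotype_physical_height` documents
the implied render size (a 5-arcmin letter at 300 cm is 4.36 mm); no
published value exists for the instrument, so this is a derivation, not
a datum.

## Observer model

Each eye is a four-parameter psychometric function on the demand axis:
`p(correct) = γ + (1−γ−λ)·F((v−t)/σ)` with logistic `F`. The logistic
(rather than a cumulative Gaussian) was chosen for its closed form; the
shape difference is absorbed into σ. Defaults:

| parameter | default | meaning |
|---|---|---|
| γ (guess) | 1/6 | six-letter forced choice |
| λ (lapse) | 0.01 | occasional misreport of a visible letter |
| σ (spread) | 0.05 logMAR | half a line; controls trial-to-trial noise |
| t (threshold) | per subject | RE ~ N(−0.088, 0.151²), LE ~ N(−0.089, 0.170²) |

The threshold distributions are the adult baseline acuities of the
study population the generator emulates. σ = 0.05 is a configuration
knob, not a measured quantity; it produces retest behaviour in the
range reported for these instruments and is the target of the
sensitivity checks in the test suite.

**Simulated amblyopia.** A Bangerter-style foil adds `blur_shift` to
the eye's threshold. Published data show the foils' nominal density
labels predict measured blur poorly and the material is optically
inhomogeneous, so the label→blur map here is an explicitly *synthetic
stand-in*: base blur `1.1 − label value` (label "<0.1" read as 0.05),
i.e. 0.1 logMAR for the weakest foil up to 1.05 for the strongest,
jittered per (subject, eye, label) with SD 0.1 and clipped at zero.
On top of this, each test session draws one threshold jitter per
filtered eye (`inhomogeneity_sd`, default 0.05 logMAR — half a line,
chosen as a plausible effect of looking through a non-uniform foil).
Session jitter is drawn once per (eye, protocol, repetition) and shared
by all trials of that test; it is the mechanism that generates
test-retest variability beyond Bernoulli noise.

Not modelled: optical transfer of the foils, crowding, accommodation
or presbyopia (the emulated population is 18–39 precisely to exclude
it), and child response behaviour (fatigue, fixation loss).

## Protocols

**Distance staircase.** Start at 30 cm (1.0 logMAR). Coarse phase: one
letter per distance; correct → three lines farther (clamped at 300 cm;
a correct answer *at* 300 cm ends the test at 0.0 logMAR); the first
error switches to the fine phase one line closer. Fine phase: blocks of
up to five letters with early stopping at three correct (pass → final
distance) or three incorrect (fail → one line closer). Failing the
block at the closest level returns a "worse than 1.3" sentinel rather
than 1.3, so floored scores can be excluded from analysis. Edge rules
the prose leaves open, resolved here: coarse moves clamp rather than
reflect at the ceiling; a coarse error at the closest level starts the
fine phase at that same level; the fine phase terminates on its first
pass (no upward retesting). A repeat test starts at the previous final
distance, mirroring the instrument's behaviour.

**Letter-size chart.** Lines 0.7 down to 0.0 logMAR, one crowded letter
each, at a calibrated fixed viewing distance (a letter on line *v*
simply has demand *v*; no distance error is modelled). Descend until an
error; an error on the very first letter returns an above-ceiling
sentinel (out of the instrument's range). Confirm the line above with
four more letters — the already-correct descent letter counts as one of
the five; the fresh-five alternative is configurable but off. A ≥ 3/5
line sends testing to the next smaller line with five fresh letters;
the first line below 3/5 ends the test and the score is the deepest
passing line, rounded to whole lines (raw letter counts stay in the
trial log; line rounding is what downstream analysis consumes). If the
first confirmation fails, testing moves back up one line at a time
(those lines each hold one correct descent letter) until a line passes.

Both sentinels ("worse than 1.3" and "worse than 0.7") are represented
as +inf measured logMAR, preserving the larger-is-worse ordering.

A deliberate structural asymmetry follows from the two procedures: the
chart's confirmation line inherits a credit letter while every
staircase block needs 3-of-5 from scratch, and the staircase approaches
threshold from the hard side. Under the default observer this makes the
staircase read ~0.03 logMAR worse with roughly twice the single-test
spread of the chart — visible in the cross-method bias the simulation
reports, and worth knowing before attributing such offsets to an
implementation.

## Study pipeline

Per subject: draw thresholds; screen with the chart's descend phase
only (last correct line = screening vision — a coarse screen, not a
threshold); greedily search the foil ladder (no foil, then weakest →
strongest) for the first combination putting both eyes at ≤ 0.7, the
better eye at ≥ 0.2, and ≥ 0.2 between the eyes. Which eye is pushed
worse is randomised per subject so laterality stays balanced. Subjects
with no satisfying combination are flagged unscreenable and excluded.
Then two repetitions of both protocols on both eyes, with app and eye
order each randomised uniformly per subject. Exclusion mirrors the
emulated design: any chart score better than 0.0 logMAR excludes the
subject (with the default 0.0-floored chart this cannot fire; the rule
is exercised with a configurable chart floor). Individual out-of-range
sentinel scores stay in the table and are dropped pairwise at analysis
time. The default study size is 36 subjects; everything is
deterministic given the config seed, with per-subject seed sequences
spawned from it.

## Agreement statistics

Differences follow explicit sign conventions: retest bias is first
minus second test; cross-method bias is chart minus staircase. Limits
of agreement are `bias ± 1.96·SD` with the sample SD (n−1, the
Bland-Altman convention); the identity holds exactly pre-rounding, and
display rounding (3 decimals, whole percent for within-one-line
proportions) happens only at the presentation layer. Published summary
tables rounded their inputs before deriving limits, so recomputed
limits can disagree with printed ones in the last digit; only
self-consistent cells are used as worked examples. Paired t-tests use
`t = mean/(sd/√n)` with n−1 df, two-sided; zero-variance input returns
p = 1 when the mean is also zero, p → 0 otherwise. Line differences bin
at `round(diff/0.1)` with round-half-even — ties cannot occur for
whole-line protocol scores, so the rule only matters for future
letter-scored inputs. Interocular difference is right minus left (a
choice; the report JSON records it). Normality testing is out of scope;
parametric tests are applied unconditionally.

## What the simulation does and does not show

Passing tests demonstrate that the two protocols, as specified, measure
the same underlying threshold up to a known small asymmetry, and that
the analysis pipeline reproduces the standard agreement statistics
exactly. They do not validate the instruments on humans: the observer
model has no crowding, attention, learning or distance-measurement
error, the foil model is a stand-in, and the cohort is stationary
within a session except for the foil jitter. The study-level test is
therefore a *plausibility band* (retest within one line in 70–100 % of
eyes, cross-method bias within ±0.05 logMAR) rather than a reproduction
of any particular human dataset.

## Problem sizes and numerics

The default suite runs the full n = 36 study, a 2¹²-pattern exhaustive
staircase/prose-oracle equivalence check, 1000 staircase recovery runs
(thresholds placed 0.03 inside a grid interval — a threshold exactly on
a line is a degenerate case where p = 0.5 at that line and no procedure
can recover it reliably), and 100-vector comparisons against scipy /
pure-Python reference implementations at 1e−10. Grid comparisons use
1e−9 relative tolerance; demand levels are stored as exact multiples of
the line step to 1e−12.
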