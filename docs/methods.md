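# Methods and design notes

This note documents the models implemented in `ctglab`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the known limitations. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

A CTG record is a pair of series on one 4 Hz time axis: fetal heart rate
(FHR, bpm) and uterine activity (UC, mm Hg). Monitors write signal loss
in-band as values of exactly 0 or −1; readers convert these to boolean
masks. As an additional guard (on by default, configurable off), FHR
values outside 30–250 bpm are treated as missing: such samples are not
physiological and would otherwise leak spikes into the filter bank.

Interior missing runs strictly shorter than `preprocess.max_gap_s`
(default 600 s) are filled by interpolation between the valid samples on
either side; runs touching a record boundary have no anchor on one side
and stay masked. Two interpolants are provided: linear (default) and a
cubic Hermite spline whose endpoint slopes are one-sided finite
differences on the valid side. On locally linear signals the two agree
exactly; elsewhere they differ slightly, and the pipeline's behaviour
downstream is insensitive to the choice.

The analysis window is the *latest* 30-min stretch in which neither FHR
nor UC has a missing sample (windows may start on any sample; "latest" is
taken literally at 4 Hz granularity). We require the UC series to be
gap-free too because the contraction features need it. A case is
discarded — as a value carrying a machine-readable reason, not an
exception — when no such window exists or when the window starts more
than 90 min before delivery (segment start relative to delivery is
`end_offset + (record end − segment start)`; an unknown `end_offset` is
treated as 0).

## Baseline estimation

The FHR baseline is the slowly varying mean level with accelerations and
decelerations excluded. Defining events needs a baseline and defining the
baseline needs the events, so the estimator breaks the circularity with a
per-sample probability of *stability*, `p_stab(t)`, learned from
expert-style annotations (stable = outside any annotated event).

**Stability variables.** The FHR is band-pass filtered (zero-phase,
6th-order Butterworth, forward–backward so events are not displaced in
time) in four modulation-frequency bands: 0–0.1, 0.1–1, 1–3 and
3–7 cycles/min, i.e. event time scales from ~10 min down to ~9 s; the
0-edged band is a pure low-pass. Cutoffs in cycles/min convert to Hz as
`f/60`. Eight per-sample descriptors feed a logistic regression: the
absolute first differences of the four filtered signals (event slopes)
and the absolute Hilbert envelopes of those derivatives (which stay high
through an event's trough, separating it from genuine baseline). Inputs
are standardized and the fit is lightly L2-regularized (`C = 1`) so that
separable traces cannot overflow; the training sampling rate is the
native 4 Hz, pooled across recordings.

**Weighted median.** The baseline at `t` is the *lower* weighted median —
the smallest value whose cumulative weight reaches half the total — of
the FHR over `|t − t′| < T`, with weights
`W_t(t′) = p_stab(t′) · max(0, 1 − |t − t′|/T)`. The lower-median
convention is a documented tie-break choice; an O(n²) brute-force oracle
in the tests pins the exact definition. A window whose weights sum to
zero falls back to the unweighted median (logged).

**Half-duration.** Fixed mode uses `T = T0 = 20 min`. Variable mode uses
`T(t) = T0 / (3 · p̄_stab(t))` with `p̄_stab(t)` the mean stability over
`[t − T0, t + T0]`: unstable stretches get a wider window, stable ones a
narrower, faster-adapting one. The formula diverges as `p̄_stab → 0`, so
`T` is clamped to [5 min, 60 min] (logged when active). At
`p̄_stab ≡ 1/3` the two modes coincide exactly — an algebraic identity the
tests assert; `T` is rounded at the nanosecond to keep float residue from
admitting a spurious edge sample into the window. Windows truncate at
segment edges. For tractability the median is evaluated every second
(stride 4 at 4 Hz) and linearly interpolated back to 4 Hz; stride 1
reproduces the literal definition and the stride is configurable.

## Event detection

Candidate accelerations are maximal runs with FHR strictly above the
baseline (equality breaks a run). A run is an acceleration when its
maximum deviation exceeds 15 bpm, its mean deviation exceeds 10 bpm, and
it lasts at least 15 s; decelerations are the mirror image, and those
longer than two minutes are flagged *late*. The 15-s rule follows the
clinical (FIGO-style) definition; it is configurable and on by default.
Contractions are maximal runs with UC strictly above 10 mm Hg lasting
strictly more than 30 s. Areas are time integrals (deviation × Δt,
Δt = 1/rate), reported in bpm·s and mm Hg·s so they are invariant to the
sampling rate; contraction area is measured above the 10 mm Hg threshold,
not above zero. Note that the mean-deviation criterion applies to the
*realized run*, not to any nominal event shape: slow noise around a flat
baseline can stretch a run far beyond an underlying bump and dilute its
mean below threshold — the correct behaviour given the definition, and
the reason the detector benchmark (below) injects events onto noise-free
FHR.

## Features

The 25-feature vector per segment: baseline min/median/max;
acceleration count, total duration, area, max depth; deceleration and
late-deceleration counts, durations, areas, and the max deceleration
depth; contraction count, duration, area; deceleration-outside-
contraction durations and areas (computed at sample resolution on the
set difference of each deceleration interval minus the union of
contraction intervals, for both all and late decelerations); summed
absolute offsets between each deceleration peak and the nearest
contraction peak (0 when the segment has no contraction — a documented
convention); STV (mean absolute difference of successive 3.75-s epoch
means) and LTV (mean per-minute max−min amplitude). Epochs that do not
fill completely at the segment end are dropped; a 30-min segment divides
evenly (480 STV epochs, 30 LTV minutes). Maximum depths are 0 when no
event exists. STV averages epoch differences directly over the segment,
without intermediate minute-wise averaging.

## Acidosis model

The outcome is `pH < 7.05` (7.15 supported as an alternative). Cases are
weighted `N / (2·N_class)` so each outcome class carries half the total
weight — necessary because acidosis prevalence is ~10%. Features are
standardized with center/scale estimated on the training data and stored
in the model file; coefficients therefore live on the standardized scale
and raw-scale equivalents are derivable. The fit is a logistic regression
with weak L2 (`C = 10⁴`, configurable) to prevent separation pathologies
on small cohorts, at a solver tolerance (1e−8) tight enough that
algebraically equivalent reweightings of the data reproduce coefficients
to ~1e−7. The default feature subset is `b_min, b_max, acc_area,
dec_area`.

Evaluation is by rank-based AUC (ties at ½), stratified k-fold
cross-validation (seeded shuffle, round-robin assignment per class,
pooled out-of-fold AUC as the headline), and leave-one-center-out
evaluation for transportability. A held-out center with a single outcome
class has no defined AUC; by default this raises, or reports NaN when
asked to skip.

Contributions: `cᵢ = βᵢxᵢ / Σⱼ βⱼxⱼ` on the standardized features (signed
variant, sums to 1 whenever the denominator is nonzero) or restricted to
positive terms and renormalized (positive-only variant: non-negative,
sums to 1 when any positive term exists, all-zero otherwise).

## Synthetic generator

`simulate_record` renders: a true baseline (uniform level in a plausible
110–160 bpm range plus low-pass drift, sd 8 bpm, periods ≥ 20 min,
clipped to range — within-record excursions of ~10–20 bpm over an hour,
as seen in late labor; this scale also keeps `b_min` and `b_max`
statistically distinguishable, consistent with their carrying opposite
risk associations); Hann-shaped accelerations (6/h, 15–30 bpm, 20–60 s)
and decelerations (8/h, 20–60 bpm, 30–180 s) placed by a thinned Poisson
process with overlap rejection (an event unplaceable after 200 draws is
dropped; rates implying > 60% expected occupancy are rejected up front);
decelerations contraction-locked with probability 0.7 at a 0–30 s lag;
band-limited variability noise per modulation band (sd 2.0/1.5/1.0 bpm in
the 0.1–1/1–3/3–7 cycles/min bands, giving STV ~1–3 bpm and LTV
~10–25 bpm); bell-shaped contractions every 120–300 s (60–100 s long,
peaks 30–80 mm Hg) over a 5 mm Hg tone; and signal-loss gaps (4/h,
5–120 s) written as 0-valued runs on both channels *after* ground truth
is captured.

Ground truth per record: the true baseline, injected event intervals,
stability labels (stable ⇔ outside every injected FHR event), and the
true feature vector of the final 30-min window — event features measured
on the noise-free rendering against the true baseline, variability
features on the rendered (noisy) trace.

`simulate_cohort` draws outcomes `Bernoulli(σ(β₀ + β·z))` with `z` the
true four default features standardized over the cohort and
`β = (−0.8, +0.8, +0.5, +1.0)` — signs matching the direction of risk for
each feature, magnitudes giving a Bayes-optimal AUC near 0.78; `β₀` is
tuned by bisection so the mean risk equals the target prevalence (0.10).
The drawn label fixes the recorded pH on the corresponding side of the
cutoff. The cohort's Bayes AUC is computed exactly from the true
probabilities as a soft-label Mann–Whitney statistic.
`simulate_annotated_set` produces gap-free `(fhr, stable-labels,
true-baseline)` triples for stability-model calibration and baseline-
error scoring; `simulate_event_benchmark` produces segments whose
injected events meet the detection criteria with ≥ 20% margin (amplitudes
≥ 24 bpm so the Hann mean deviation is ≥ 12 bpm, durations ≥ 18 s) and
*zero* FHR variability noise, because with noise the realized runs would
not preserve the margin (see the event-detection note above); UC noise is
kept, as contractions have 10 mm Hg of headroom.

What the generator does not emulate: maternal-heart-rate capture
artifacts, sensor-specific noise spectra, FIGO pattern taxonomies beyond
what the features need (e.g. sinusoidal patterns), or any causal
physiology linking contractions to hypoxia — the outcome link is a
statistical surrogate. Passing tests therefore demonstrate correctness of
the algorithms under controlled conditions, not clinical performance on
real cohorts.

## Problem sizes and tolerances

The test suite and acceptance script run the baseline-accuracy comparison
on a 66-record annotated set split 40/26 (records of 1 h at 4 Hz), the
detector benchmark on 200 30-min segments, and model recovery on cohorts
of 5,000 cases; these sizes give stable estimates while keeping a full
run in the low minutes on one CPU. Coefficient recovery is checked at 15%
relative error against features simulated directly from the known link;
under the full signal-level generator, individual coefficients of the
collinear baseline pair are identified more weakly (class-balanced
weighting at 10% prevalence leaves ~500 effective positives), so the
signal-level cohort is asserted on its cross-validated AUC (within 0.04
of the Bayes AUC) and on coefficient signs, and the acceptance script
reports the measured signal-level recovery error as is. Closed-form
feature checks use exact constructions (tiled epochs, sampled sines with
a 2% tolerance, Hann areas at 5%).

## Known limitations

- The stability model is trained at 4 Hz on pooled samples; temporal
  autocorrelation inflates its nominal sample size, which is harmless for
  point prediction but means its training AUC is not a generalization
  estimate.
- The weighted-median grid stride (1 s) introduces sub-bpm interpolation
  error relative to the literal per-sample definition; stride 1 removes
  it at 4× cost.
- WFDB support covers the common single-.dat format-16 layout used by
  the open CTG archives, not the full format zoo.
- The discard rule interprets "without missing data" as applying to both
  FHR and UC; archives with UC-only dropouts will discard more cases
  than an FHR-only reading would.
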