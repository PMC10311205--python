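# ctglab

Interpretable analysis of intrapartum cardiotocography (CTG): from paired
fetal-heart-rate (FHR) / uterine-activity (UC) recordings to a risk of
fetal acidosis with per-feature explanations.

During labor, the fetal heart rate and uterine pressure are monitored
continuously (4 Hz in routine monitors). Clinicians read these traces for
warning signs — a drifting baseline, absent accelerations, deep or
prolonged decelerations, abnormal variability — to decide whether the
fetus is at risk of hypoxia/acidosis (umbilical arterial pH < 7.05 at
birth). `ctglab` implements that reading as a transparent pipeline aimed
at researchers working with CTG archives (e.g. the open CTU-UHB database
on PhysioNet) and at method developers who need a fully controlled
synthetic test bed:

1. **Preprocessing** — in-band missing values (0/−1) are masked, interior
   gaps shorter than 10 min are interpolated, and the latest fully
   gap-free 30-min window is selected (cases whose window starts more than
   90 min before delivery are discarded).
2. **Baseline estimation** — the FHR baseline (the slow mean level with
   accelerations/decelerations excluded) is a *stability-weighted median*:

       baseline(t) = weighted_median{ FHR(t′) : |t − t′| < T }
       W_t(t′) = p_stab(t′) · max(0, 1 − |t − t′| / T)

   where `p_stab(t)` is a logistic model of the probability that the trace
   is in a stable (non-event) state, built on the absolute derivatives and
   Hilbert envelopes of the FHR band-passed in four modulation bands
   (0–0.1, 0.1–1, 1–3, 3–7 cycles/min). The half-duration `T` is either
   fixed (20 min) or adaptive, `T = 20 min / (3 · mean p_stab)`.
3. **Event detection** — accelerations (runs above baseline with max
   deviation > 15 bpm, mean deviation > 10 bpm, ≥ 15 s), the symmetric
   decelerations (those > 2 min flagged *late*), and contractions
   (UC > 10 mm Hg for > 30 s).
4. **Features** — a 25-value summary per segment: baseline min/median/max,
   event counts/durations/areas/depths, contraction summaries, joint
   deceleration–contraction features, and short/long-term variability
   (STV/LTV).
5. **Risk model** — a logistic regression on standardized features with
   class-balanced case weights (pathological and normal cases get equal
   total weight), by default on the four features `b_min`, `b_max`,
   `acc_area`, `dec_area`. The risk `p = σ(β₀ + Σᵢ βᵢxᵢ)` is reported with
   per-feature contributions `cᵢ = βᵢxᵢ / Σⱼ βⱼxⱼ` (or the positive-only
   renormalized variant), so each prediction says *why* the score is high.

A first-class synthetic generator (`ctglab.synthetic`) produces cohorts
with complete ground truth — true baseline, event intervals, stability
labels, true features and a pH outcome drawn through a known logistic link
— so every stage is testable without any clinical download.

## Worked example

Simulate a cohort, extract features, train, and score — all from the
shell (the `ctglab` console script) or the Python API:

```sh
cat > sim.yaml <<'YAML'
simulate:
  n_cases: 160
  duration_s: 2700.0
  seed: 11
  prevalence: 0.25
YAML
ctglab simulate --config sim.yaml --out cohort
ctglab extract --out features.csv --discards-out discards.csv cohort/records/*.csv
ctglab train --features features.csv --labels cohort/cohort.csv \
             --out model.yaml --seed 1 --report report.txt
ctglab predict --model model.yaml --features features.csv --out pred.csv
```

which prints (numbers from this exact run):

```
wrote 160 cases to cohort
160 cases extracted, 0 discarded
cases: 160
features: b_min,b_max,acc_area,dec_area
pooled_auc: 0.7154
fold0_auc: 0.6458
fold1_auc: 0.6875
fold2_auc: 0.7865
fold3_auc: 0.8021
fold4_auc: 0.6562
scored 160 cases
```

`pooled_auc` is the area under the ROC curve of the pooled out-of-fold
scores from stratified 5-fold cross-validation: 0.72 here means the model
ranks a random pathological case above a random normal one 72% of the
time (at this cohort size the per-fold AUCs scatter widely, which is why
the pooled value is the headline number). The first rows of `pred.csv`:

```
case_id,risk,contrib_b_min,contrib_b_max,contrib_acc_area,contrib_dec_area
case00000,0.8025,0.0567,0.2707,0.0000,0.6726
case00001,0.8446,0.0000,0.1196,0.2142,0.6662
```

`risk` is the modelled probability of acidosis; the `contrib_*` columns
are the positive-only contributions (non-negative, summing to 1): for
`case00000`, 67% of the elevated risk comes from the deceleration area
and 27% from a high baseline maximum — the kind of statement a clinician
can check directly against the trace.

Other subcommands: `ctglab baseline` (per-sample baseline, p_stab and
events for one record), `ctglab fit-stability` (calibrate the stability
model on annotated records), `ctglab eval-centers` (leave-one-center-out
AUCs).

## Layout

```
src/ctglab/
  types.py       core containers (CTGRecord, Segment, Event, FittedModel, ...)
  io.py          CSV + WFDB record readers, model serialization
  preprocess.py  gap interpolation, segment selection
  baseline.py    filter bank, stability model, weighted-median baseline
  events.py      acceleration / deceleration / contraction detectors
  features.py    STV, LTV, joint features, the 25-feature vector
  model.py       balanced logistic fit, AUC, k-fold and cross-center CV
  synthetic.py   cohort generator with full ground truth
  pipeline.py    record -> features glue
  cli.py         the `ctglab` command
docs/methods.md  modelling and design notes
```
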