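# Methods

## The question and the analysis design

Nulliparity (a first birth) is associated with longer labors and a higher
incidence of fetal acidosis and hypoxic-ischemic encephalopathy (HIE), but
the fetal cardiovascular response to hypoxia has no known dependence on
maternal parity. If the association runs through *exposure* (longer, more
contraction-dense labor) rather than through a parity-specific fetal
physiology, then a CTG classifier that knows parity should not outperform
one that does not. The pipeline operationalizes this as a comparison of
three decision-support systems built on the same epoch features:

* `DS_all` — one classifier for all births, no parity information;
* `DS_all+np` — one classifier with the nulliparity flag as a feature;
* `DS_np ∪ DS_mp` — separate classifiers per parity, routed at prediction
  time.

Because the clinical data the design targets are restricted, the package
ships a synthetic cohort generator whose parameters encode exactly the
structure the analysis assumes, so every downstream stage is testable and
the null and alternative hypotheses can both be materialized at will.

## Synthetic cohort model

**Labels.** Group prevalences default to a 37,546 / 3,056 / 374 split
(healthy / acidosis / HIE) rescaled to probabilities; per-group nulliparity
probabilities default to (0.578, 0.645, 0.668); Caesarean delivery is a
Bernoulli draw per group × parity with defaults near (41.6, 35.4 / 34.5,
43.0 / 51.6, 63.6) percent. These mirror the reference cohort's marginal
tables.

**Durations.** Labor duration is log-normal (σ_log = 0.35) with a
multiparous mean of 360 min and a nulliparous multiplier of 1.4, clipped to
[30, 900] min and rounded to whole seconds. The literature supports
"longer labors in nulliparous mothers" without giving a distribution;
log-normal is the standard choice for duration data.

**Event streams.** Each channel is a semi-Markov chain on the labeled CTG
event states, on a 0.25 s grid (UP boundaries on a 1 s grid, matching its
native 1 Hz sampling). Dwells are gamma(shape 4) around state means; the
FHR transition matrix has zero diagonal and rows summing to 1. Uterine
activity alternates contraction/rest; the FHR deceleration-entry weight is
multiplied by a coupling factor during a contraction and for 60 s after it
ends (contraction-stress physiology). Defaults per group differ mainly on
the deceleration side (baseline dwell 150/120/100 s, deceleration branch
weight 0.25/0.45/0.60, coupling 2/3/4, contraction rest 120/110/105 s).
No quantitative per-group event dynamics are published for the reference
cohort; these values are stand-ins chosen for physiological plausibility
and are documented as such.

**Per-birth heterogeneity.** Every birth draws lognormal random effects
(σ = 1.0 on the log scale, with smaller σ on secondary parameters) on the
group-distinguishing dynamics. Without this, the groups are near-perfectly
separable at the birth level, which real CTG — notorious for poor
specificity — is not; with it, pathological-group detection sits clearly
above the Caesarean-rate calibration target yet below saturation (the
tiny HIE test stratum remains coarse — see Known limitations), the
qualitative regime the clinical literature reports.

**Dropouts.** Invalid runs are inserted as a Poisson process of
exponential-length gaps (mean 45 s) at an expected invalid fraction of 6%,
the simplest model that exercises both the <15 s gap-healing rule and the
80% epoch-validity filter.

**The parity knob.** `parity_dynamics_effect = e` controls the conditional
law of the streams given duration. At e = 0 (default) parity affects only
prevalence, duration and Caesarean rates; the generator provably does not
consume parity in stream simulation, so a matched seed and duration yield
bit-identical streams across parity. At e > 0 nulliparous dynamics are
shifted along the same severity axis that separates the outcome groups
(deceleration-entry odds ×(1+e); baseline dwell, coupling and contraction
frequency shifted with exponents such that (1+e) = 4 maps the healthy
dynamics onto the HIE defaults). The shift is deliberately *collinear*
with the group axis: a deceleration-only effect would leave
parity-independent side channels through which a parity-blind classifier
could still separate the groups, and would not constitute a genuine
parity × dynamics confound.

**What the generator does not emulate:** raw beat-to-beat FHR waveforms,
event-detector idiosyncrasies, artifact morphology, gestational-age and
infection covariates, and any within-labor nonstationarity beyond the
contraction coupling. Passing tests therefore demonstrate correctness of
the pipeline and internal consistency of the statistical protocol on data
with the assumed structure — not clinical performance.

## Preprocessing and features

Epochs are anchored at delivery: epoch k spans [−20(k+1), −20k] minutes,
at most 36 (12 h). "Gaps shorter than 15 s" is read strictly (<15 s
healed, ≥15 s kept invalid); at the event level a healed gap is absorbed
into its flanking events, split at the midpoint. The 80% validity rule is
read inclusively (≥80% kept) and applied to both channels jointly — the
conservative reading. Features are computed on the joint 12-state space
(either channel changing state is a transition): the 12×12 transition-count
matrix, per-state visit counts, dwell totals and means, and occupancy
fractions (180 columns). Invalid samples inside a valid epoch are excised
and never create a transition across the excision. A 4 Hz sample-walk
oracle in the test suite verifies the run-length arithmetic exactly.

## Classification and calibration

Binary task: healthy vs pathological (acidosis ∪ HIE). Each tree of the
forest draws individuals without replacement at 2:1:1 — the whole HIE pool
(rarest group), an equal number of acidosis and twice that number of
healthy individuals — and trains on all their epochs; a tree is OOB for an
individual it did not draw. Consequences: every tree is exactly
class-balanced at the individual level, and HIE individuals have no OOB
trees (their `p_PAT` carries a missing marker); OOB-based metrics are
therefore driven by healthy and acidosis births, which is harmless here
because calibration uses only healthy births. Tree hyperparameters default
to depth 12 and √p features per split; a small OOB-scored grid search is
available (`select_hyperparameters`) but the replicated experiments use
the fixed defaults for comparability across resamples.

The decision threshold is calibrated per system on the OOB posteriors of
the *training* healthy births of the same subpopulation the classifier was
trained on (so `DS_np` calibrates to the nulliparous healthy Caesarean
rate, etc.). Candidates are the distinct OOB `p_PAT` values; the smallest
threshold whose false-positive recommendation rate does not exceed the
target is selected — exact matching is impossible on a finite grid, and
"at most the target, within one grid step" is the conservative reading.
Alerts use strict inequality `p_PAT > t_PAT`.

## Decision support

The 100-minute window slides from the earliest epoch toward delivery in
20-minute steps. A window with more than two of its five epoch slots
missing (excluded by the validity rule, absent, or carrying a missing OOB
marker) is skipped and the scan continues. A window recommends only if
every present epoch alerts; the decision time is the window's
delivery-proximal edge, and only decisions at ≥40 min before delivery
count. A birth's recommendation time is its earliest recommending in-time
window.

## Statistics

Relative risks use all births of each parity as denominators; the
"acidosis criterion" pools acidosis and HIE (HIE requires acidosis by
definition), which is the only reading consistent with the reference
cohort's published RR. CIs are Katz log-method; chi-square is Pearson
with 1 d.f. and no continuity correction (the reported significance bounds
hold either way). Median CIs use the notch formula median ± 1.57·IQR/√n
with linear-interpolation quartiles. The rank-sum test enumerates all
group assignments exactly (midranks for ties) when both arms have < 20
values and the enumeration is affordable, otherwise uses the tie-corrected
normal approximation; completely tied data give p = 1.

The replicated experiment runs n independent stratified 90/10 resamples of
one fixed population (in the full-scale protocol the population is the
clinical cohort and is likewise fixed; what is replicated is sampling and
training). Each resample retrains and recalibrates every system; a failing
resample is recorded and excluded rather than aborting the replication.

## Problem sizes

The package's standing configurations are scaled for a desk machine:
cohorts of 2,000 births (4,000 for the calibration check), 10 resamples,
200-tree forests, and 10 meta-replications of the null comparison run as
independent replications over one fixed population. The full-scale
protocol (40,831 births, 2,500 trees, 100 resamples) is reachable through
the same configuration objects.

## Known limitations

* The dynamics parameters are stand-ins; absolute recommendation rates on
  synthetic cohorts are not comparable to clinical tables, only the
  protocol's internal relationships are.
* With realistic prevalences, a 10% test set contains only a handful of
  HIE births, so per-resample HIE rates are coarse (steps of ~1/2 to 1/4);
  rank-sum comparisons on them are conservative under ties.
* OOB posteriors are undefined for HIE individuals under whole-pool
  sampling; any future OOB-based metric that needs HIE coverage would
  require bootstrapping the HIE pool per tree instead.
* The window scan treats a skipped window as "continue scanning"; the
  alternative reading (halt until a valid window appears) coincides with
  it under delivery-anchored indexing.
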