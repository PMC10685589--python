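# ctgds — parity-aware cardiotocography decision support

`ctgds` is an analysis pipeline for a question in intrapartum fetal
monitoring: **does knowing whether a mother is nulliparous (first birth)
improve the detection of fetuses at risk of hypoxic-ischemic encephalopathy
(HIE) from cardiotocography (CTG)?** Nulliparous labors are longer and
expose the fetus to more contractions, and nulliparity is associated with a
higher risk of acidosis and HIE — but if the fetal heart-rate response to
hypoxia itself does not depend on maternal parity, a parity-aware classifier
should offer no advantage. The pipeline implements the full chain needed to
study this question on synthetic cohorts:

1. **Synthetic cohort generation** (`ctgds.cohort`) — labeled births in
   three outcome groups (healthy / acidosis / HIE), with parity-dependent
   prevalence and labor duration, semi-Markov CTG *event streams* per birth
   (FHR: baseline / acceleration / deceleration; UP: contraction / rest) at
   4 Hz resolution, contraction-coupled deceleration hazards, per-birth
   physiological heterogeneity and signal dropouts. A
   `parity_dynamics_effect` knob injects a parity×dynamics interaction
   (0 = the physiological null).
2. **Preprocessing** (`ctgds.preprocessing`) — linear interpolation of
   FHR gaps shorter than 15 s, up-sampling of the 1 Hz uterine-pressure
   channel to 4 Hz, and tiling of 20-minute epochs backward from delivery
   (≤ 36 epochs, i.e. 12 h); epochs with less than 80% valid samples on
   either channel are excluded.
3. **Featurization** (`ctgds.features`) — per epoch, transition counts and
   dwell-time statistics over the 12 joint (FHR × UP) event states.
4. **Epoch classification** (`ctgds.forest`) — random forests (2,500 trees
   at full scale; 200 in the scaled configuration) in which *each tree*
   undersamples individuals at a fixed 2 healthy : 1 acidosis : 1 HIE
   ratio; out-of-bag (OOB) posteriors `p_PAT` are computed at the
   individual level. Four configurations: `C_all` (parity-blind),
   `C_all+np` (nulliparity as a feature), and the two-path pair
   `C_np`/`C_mp` routed by parity at prediction time.
5. **Decision support** (`ctgds.decision`) — a 100-minute sliding window
   over epoch alerts (`p_PAT > t_PAT`): a window with more than two missing
   epochs is skipped, a window recommends intervention only if *all* its
   valid epochs alert, and recommendations count only up to 40 minutes
   before delivery. The threshold `t_PAT` is calibrated on OOB posteriors
   so that the healthy-group false-positive rate matches that group's
   Caesarean delivery rate.
6. **Evaluation** (`ctgds.evaluation`) — relative risks with Katz 95%
   confidence intervals and chi-square tests on the group × parity
   contingency table; replicated system comparison over independent 90/10
   train/test resamples, summarized by medians with notch CIs
   (median ± 1.57·IQR/√n) and Wilcoxon rank-sum tests (exact enumeration
   for small samples).

## Worked example

```python
from ctgds import (CohortConfig, ForestConfig, sample_cohort,
                   features_table, run_replicated_experiment,
                   reference_table, relative_risk)
from ctgds.io import births_frame

# risk of HIE for nulliparous vs multiparous births, reference cohort
r = relative_risk(reference_table(), outcome="hie")
print(f"RR = {r.rr:.2f}, 95% CI [{r.ci_low:.2f}, {r.ci_high:.2f}], p = {r.p:.1e}")

# scaled synthetic system comparison
records = sample_cohort(CohortConfig(n_births=2000, seed=914))
births, features = births_frame(records), features_table(records)
res = run_replicated_experiment(features, births, n_runs=10, base_seed=20230,
                                forest_config=ForestConfig(n_trees=200))
print(res.summary.query("scope == 'all'")[["system", "group", "median"]])
```

This prints

```
RR = 1.44, 95% CI [1.16, 1.78], p = 8.2e-04
```

— nulliparity carries a significantly elevated relative risk of HIE — and a
median recommendation-rate table in which the healthy-group rate of every
system sits at its Caesarean-rate calibration target (≈ 0.38) while the
acidosis and HIE groups are detected at substantially higher rates, with no
meaningful difference between the parity-blind, parity-feature and two-path
systems under the generator's physiological null.

The numbered drivers under `analysis/` run the same stages as a narrative:
`01_simulate_cohort.py` (cohort → `scratch/cohort/`),
`02_cohort_statistics.py` (risk statistics), `03_system_comparison.py`
(replicated comparison + time courses) and
`04_parity_interaction_probe.py` (null vs injected parity×dynamics
interaction). Small JSON/CSV outputs land in `results/`.

A thin CLI wraps the same library calls:

```bash
ctgds simulate --n-births 500 --seed 7 --out scratch/demo
ctgds validate scratch/demo
ctgds run scratch/demo --n-runs 5 --trees 100 --out results/demo
```

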