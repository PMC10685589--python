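"""Replicated comparison of the decision-support systems.

On the cohort from 01_simulate_cohort.py, runs 10 independent 90/10
resamples: per resample the four epoch classifiers (C_all, C_all+np,
C_np, C_mp) are trained with 200-tree class-balanced forests, each
decision-support system is calibrated on out-of-bag posteriors to its
healthy-group Caesarean rate, and test-set intervention-recommendation
rates are collected per outcome group.  Writes per-system medians with
notch CIs, pairwise rank-sum p-values, and recommendation-rate time
courses to results/.
"""

import json
from pathlib import Path

import pandas as pd

from ctgds import ForestConfig, features_table, run_once, run_replicated_experiment
from ctgds.io import births_frame, read_cohort

ROOT = Path(__file__).resolve().parents[1]
BASE_SEED = 20230
N_RUNS = 10


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    if not cohort_dir.exists():
        raise SystemExit("run 01_simulate_cohort.py first")
    records = read_cohort(cohort_dir)
    births = births_frame(records)
    print(f"featurizing {len(records)} births ...")
    features = features_table(records)
    print(f"{len(features)} epochs; replicating over {N_RUNS} resamples ...")

    res = run_replicated_experiment(
        features, births, n_runs=N_RUNS, base_seed=BASE_SEED,
        forest_config=ForestConfig(n_trees=200), collect_time_course=True,
    )
    assert res.failed_runs == [], res.failed_runs

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    payload = {
        "n_runs": N_RUNS,
        "summary": res.summary.round(4).to_dict(orient="records"),
        "pairwise_p": res.pairwise_p.round(4).to_dict(orient="records"),
        "calibration": res.calibration.round(4).to_dict(orient="records"),
    }
    (results / "system_comparison.json").write_text(json.dumps(payload, indent=2))
    if res.time_courses is not None:
        tc = (
            res.time_courses.groupby(["system", "group", "time_min"])["rate"]
            .median()
            .reset_index()
        )
        tc.to_csv(results / "time_course.csv", index=False)

    # per-birth recommendations of one representative resample, for audit
    rep = run_once(features, births, seed=BASE_SEED,
                   forest_config=ForestConfig(n_trees=200))
    recs = pd.concat(
        [sr.recommendations.assign(system=name) for name, sr in rep.items()],
        ignore_index=True,
    )
    recs.to_csv(results / "recommendations.csv", index=False)

    print("median recommendation rates (all births):")
    s = res.summary
    for system in ("ds_all", "ds_all_np", "ds_two_path"):
        row = s[(s["system"] == system) & (s["scope"] == "all")].set_index("group")
        print(
            f"  {system:12s} healthy {row.loc['healthy','median']:.3f}  "
            f"acidosis {row.loc['acidosis','median']:.3f}  "
            f"HIE {row.loc['hie','median']:.3f}"
        )
    pw = res.pairwise_p
    hie = pw[(pw["scope"] == "all") & (pw["group"] == "hie")]
    print("rank-sum p-values on HIE recommendation rates:")
    for _, r in hie.iterrows():
        print(f"  {r['system_a']} vs {r['system_b']}: p = {r['p']:.3f}")
    print(
        "Under the parity-null generator the three systems are expected to be "
        "statistically indistinguishable."
    )


if __name__ == "__main__":
    main()
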