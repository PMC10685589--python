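"""Parity-interaction probe: when does routing by parity help?

Contrasts two generator regimes at the same scale (2,000 births, 10
resamples, 200 trees):

* the physiological null (parity affects labor duration and prevalence but
  not the conditional CTG dynamics) — parity-aware systems should offer no
  advantage;
* an injected parity-by-dynamics interaction (nulliparous deceleration-entry
  odds multiplied by 4) strong enough that a parity-blind classifier must
  confuse nulliparous-healthy with multiparous-pathological dynamics —
  the two-path system should now detect more HIE births.

Writes results/parity_interaction_probe.json.
"""

import json
from pathlib import Path

from ctgds import CohortConfig, ForestConfig, features_table, run_replicated_experiment, sample_cohort
from ctgds.cohort import with_positive_parity_effect
from ctgds.io import births_frame

ROOT = Path(__file__).resolve().parents[1]
N_BIRTHS = 2000
N_RUNS = 10


def run_condition(cfg: CohortConfig, base_seed: int) -> dict:
    records = sample_cohort(cfg)
    births = births_frame(records)
    features = features_table(records)
    res = run_replicated_experiment(
        features, births, n_runs=N_RUNS, base_seed=base_seed,
        systems=("ds_all", "ds_two_path"), forest_config=ForestConfig(n_trees=200),
    )
    hie = res.rates[(res.rates["scope"] == "all") & (res.rates["group"] == "hie")]
    means = hie.groupby("system")["rate"].mean().round(4).to_dict()
    p = res.pairwise_p[
        (res.pairwise_p["scope"] == "all") & (res.pairwise_p["group"] == "hie")
    ]["p"].iloc[0]
    return {"mean_hie_rate": means, "ranksum_p": round(float(p), 4)}


def main() -> None:
    out = {
        "null": run_condition(CohortConfig(n_births=N_BIRTHS, seed=616), 42),
        "interaction": run_condition(
            with_positive_parity_effect(CohortConfig(n_births=N_BIRTHS, seed=616)), 42
        ),
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "parity_interaction_probe.json").write_text(json.dumps(out, indent=2))

    for cond, r in out.items():
        m = r["mean_hie_rate"]
        print(
            f"{cond:12s} mean HIE detection: one-path {m['ds_all']:.3f}, "
            f"two-path {m['ds_two_path']:.3f} (rank-sum p = {r['ranksum_p']})"
        )
    print(
        "A two-path advantage appears only when parity genuinely modulates the "
        "CTG dynamics; under the null the systems coincide."
    )


if __name__ == "__main__":
    main()
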