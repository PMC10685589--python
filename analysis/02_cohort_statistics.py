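"""Nulliparity risk statistics.

Computes, from the packaged reference contingency table and from the
synthetic cohort generated by 01_simulate_cohort.py, the association
between nulliparity and adverse outcome: per-group nulliparity shares,
relative risks with Katz 95% confidence intervals, and chi-square tests
of independence.  Writes results/cohort_statistics.json.
"""

import json
from pathlib import Path

from ctgds import build_table, reference_table, relative_risk
from ctgds.io import read_cohort, births_frame

ROOT = Path(__file__).resolve().parents[1]


def risk_block(table) -> dict:
    out = {
        "counts": {g: [int(x) for x in table.loc[g]] for g in table.index},
        "nulliparous_pct": {
            g: round(float(100 * table.loc[g, "nulliparous"] / table.loc[g].sum()), 1)
            for g in table.index
        },
    }
    for outcome, label in (("hie", "hie"), ("acidosis_criterion", "acidosis_criterion")):
        r = relative_risk(table, outcome=outcome)
        out[label] = {
            "rr": round(r.rr, 3),
            "ci95": [round(r.ci_low, 3), round(r.ci_high, 3)],
            "chi2": round(r.chi2, 2),
            "p": float(r.p),
        }
    return out


def main() -> None:
    blocks = {"reference_cohort": risk_block(reference_table())}

    cohort_dir = ROOT / "scratch" / "cohort"
    if cohort_dir.exists():
        births = births_frame(read_cohort(cohort_dir))
        blocks["synthetic_cohort"] = risk_block(build_table(births))
    else:
        print("note: scratch/cohort missing; run 01_simulate_cohort.py for the synthetic block")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "cohort_statistics.json").write_text(json.dumps(blocks, indent=2))

    ref = blocks["reference_cohort"]
    print("reference cohort:")
    print(f"  nulliparous shares: {ref['nulliparous_pct']}")
    print(
        f"  RR(HIE | nulliparous) = {ref['hie']['rr']} "
        f"CI {ref['hie']['ci95']} (p = {ref['hie']['p']:.2e})"
    )
    print(
        f"  RR(acidosis criterion) = {ref['acidosis_criterion']['rr']} "
        f"CI {ref['acidosis_criterion']['ci95']} (p = {ref['acidosis_criterion']['p']:.2e})"
    )
    if "synthetic_cohort" in blocks:
        syn = blocks["synthetic_cohort"]
        print("synthetic cohort (2,000 births):")
        print(f"  nulliparous shares: {syn['nulliparous_pct']}")
        print("  (small-sample RRs are noisy; the generator matches proportions in expectation)")


if __name__ == "__main__":
    main()
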