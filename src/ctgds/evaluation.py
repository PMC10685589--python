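"""Cohort statistics and the replicated system comparison.

Statistics of the reference contingency table (outcome group x parity):
relative risks of nulliparity with Katz log-method 95% confidence
intervals, chi-square tests of independence, plus the replication
machinery — notch-formula median confidence intervals (median +/-
1.57*IQR/sqrt(n)) and Wilcoxon rank-sum comparisons — used to compare the
decision-support systems over independent train/test resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GROUPS
from .decision import (
    DSConfig,
    calibrate_threshold,
    evaluate_births,
    recommendation_rates,
    time_course,
)
from .forest import (
    ForestConfig,
    oob_posterior,
    predict,
    split_train_test,
    train_forest,
)

#: Reference-cohort counts (nulliparous, multiparous) per outcome group,
#: from a large retrospective intrapartum cohort; used as the packaged
#: contingency-table input for the risk statistics.
REFERENCE_PARITY_COUNTS = {
    "healthy": (21691, 15855),
    "acidosis": (1971, 1085),
    "hie": (250, 124),
}


def reference_table() -> pd.DataFrame:
    """The packaged reference contingency table as a 3x2 DataFrame."""
    return pd.DataFrame(
        REFERENCE_PARITY_COUNTS, index=["nulliparous", "multiparous"]
    ).T.loc[list(GROUPS)]


@dataclass
class RiskResult:
    rr: float
    ci_low: float
    ci_high: float
    p: float
    chi2: float
    table_2x2: np.ndarray  # rows: (nulliparous, multiparous); cols: (case, non-case)


def build_table(births: pd.DataFrame) -> pd.DataFrame:
    """Group x parity contingency table of a cohort frame."""
    table = pd.DataFrame(0, index=list(GROUPS), columns=["nulliparous", "multiparous"])
    counts = births.groupby(["group", "parity"]).size()
    for (g, p), n in counts.items():
        table.loc[g, p] = n
    return table


def chi_square_independence(table_2x2: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square of independence, 1 d.f., no continuity correction."""
    table_2x2 = np.asarray(table_2x2, dtype=float)
    if table_2x2.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table_2x2.sum(axis=0) == 0) or np.any(table_2x2.sum(axis=1) == 0):
        raise ValueError("degenerate margins")
    chi2, p, _, _ = stats.chi2_contingency(table_2x2, correction=False)
    return float(chi2), float(p)


def relative_risk(table: pd.DataFrame, outcome: str = "hie") -> RiskResult:
    """Relative risk of the outcome for nulliparous vs multiparous births.

    ``outcome='hie'`` uses HIE cases; ``outcome='acidosis_criterion'`` uses
    the acidosis criterion (acidosis or HIE, since HIE requires acidosis).
    Denominators are all births of each parity.  The 95% CI is the Katz
    log method: exp(ln RR +/- 1.96*sqrt(1/a - 1/N1 + 1/c - 1/N0)); the
    p-value is the 2x2 chi-square of independence (case vs non-case).
    """
    if outcome == "hie":
        case_groups = ["hie"]
    elif outcome == "acidosis_criterion":
        case_groups = ["acidosis", "hie"]
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    a = float(table.loc[case_groups, "nulliparous"].sum())  # exposed cases
    c = float(table.loc[case_groups, "multiparous"].sum())  # unexposed cases
    n1 = float(table["nulliparous"].sum())
    n0 = float(table["multiparous"].sum())
    if a == 0 or c == 0:
        raise ValueError("zero case cell: CI undefined")
    rr = (a / n1) / (c / n0)
    se = np.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    lo, hi = np.exp(np.log(rr) - 1.96 * se), np.exp(np.log(rr) + 1.96 * se)
    t22 = np.array([[a, n1 - a], [c, n0 - c]])
    chi2, p = chi_square_independence(t22)
    return RiskResult(float(rr), float(lo), float(hi), p, chi2, t22)


def median_ci(x: np.ndarray) -> tuple[float, float, float]:
    """Notch-formula CI of the median: median +/- 1.57*IQR/sqrt(n).

    Quartiles use the linear-interpolation convention.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("median_ci requires n >= 2")
    med = float(np.median(x))
    iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
    half = 1.57 * iqr / np.sqrt(n)
    return med, med - half, med + half


@lru_cache(maxsize=8)
def _combination_matrix(n: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    n1, n = len(x), len(pooled)
    obs = ranks[:n1].sum()
    sums = ranks[_combination_matrix(n, n1)].sum(axis=1)
    m = len(sums)
    eps = 1e-9
    p_low = np.sum(sums <= obs + eps) / m
    p_high = np.sum(sums >= obs - eps) / m
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_limit: int = 200_000) -> float:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney p-value.

    Exact enumeration of all C(n1+n2, n1) group assignments (ties handled
    via midranks) when both samples have fewer than 20 values and the
    enumeration is affordable; otherwise the tie-corrected normal
    approximation.  Completely tied data give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(x) < 20 and len(y) < 20 and comb(len(x) + len(y), len(x)) <= exact_limit:
        return _exact_rank_sum_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


# ---------------------------------------------------------------------------
# replicated experiment
# ---------------------------------------------------------------------------

SYSTEMS = ("ds_all", "ds_all_np", "ds_two_path")


@dataclass
class SystemRun:
    """One decision-support system evaluated on one resample."""

    system: str
    t_pat: float
    target_fp_rate: float
    achieved_oob_fp_rate: float
    rates: pd.DataFrame  # scope x group rates on the test set
    recommendations: pd.DataFrame


@dataclass
class RunResult:
    """Aggregate of a replicated system comparison."""

    rates: pd.DataFrame  # run, system, scope, group, rate, n
    summary: pd.DataFrame  # system, scope, group, median, ci_low, ci_high, n_runs
    pairwise_p: pd.DataFrame  # scope, group, system_a, system_b, p
    calibration: pd.DataFrame  # run, system, t_pat, target, achieved
    n_runs_requested: int
    failed_runs: list[int] = field(default_factory=list)
    time_courses: pd.DataFrame | None = None


def _healthy_caesarean_rate(births: pd.DataFrame, ids: np.ndarray, parity: str | None) -> float:
    sub = births[births["id"].isin(ids) & (births["group"] == "healthy")]
    if parity is not None:
        sub = sub[sub["parity"] == parity]
    if len(sub) == 0:
        raise ValueError("no healthy training births in calibration subpopulation")
    return float(sub["caesarean"].mean())


def run_once(
    features: pd.DataFrame,
    births: pd.DataFrame,
    seed: int,
    systems: tuple[str, ...] = SYSTEMS,
    forest_config: ForestConfig = ForestConfig(),
    ds_config: DSConfig = DSConfig(),
    collect_time_course: bool = False,
) -> dict[str, SystemRun]:
    """One 90/10 resample: train, calibrate and evaluate the chosen systems.

    Systems: ``ds_all`` (parity-blind one-path), ``ds_all_np`` (one-path
    with the nulliparity feature), ``ds_two_path`` (C_np / C_mp routed by
    parity, each path calibrated to its own parity-specific healthy
    Caesarean rate).
    """
    from dataclasses import replace

    train_ids, test_ids = split_train_test(births, seed=seed)
    assert len(np.intersect1d(train_ids, test_ids)) == 0
    train_feat = features[features["birth_id"].isin(train_ids)]
    test_feat = features[features["birth_id"].isin(test_ids)]
    ss = np.random.SeedSequence([seed, 1])
    forest_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    out: dict[str, SystemRun] = {}

    def _finish(system: str, model_preds: pd.DataFrame, calib, rec_cfg) -> SystemRun:
        recs = evaluate_births(model_preds, test_ids, rec_cfg)
        rates = recommendation_rates(recs, births)
        return SystemRun(system, calib.t_pat, calib.target_fp_rate,
                         calib.achieved_fp_rate, rates, recs)

    healthy_train = births[
        births["id"].isin(train_ids) & (births["group"] == "healthy")
    ]["id"].to_numpy()

    if "ds_all" in systems or "ds_all_np" in systems:
        for system, include_parity, fseed in (
            ("ds_all", False, forest_seeds[0]),
            ("ds_all_np", True, forest_seeds[1]),
        ):
            if system not in systems:
                continue
            cfg = replace(forest_config, seed=fseed)
            model = train_forest(
                train_feat, cfg, include_parity=include_parity,
                tag="C_all+np" if include_parity else "C_all",
            )
            # only healthy-birth OOB posteriors enter threshold calibration
            oob = oob_posterior(model, train_feat[train_feat["group"] == "healthy"])
            target = _healthy_caesarean_rate(births, train_ids, None)
            calib = calibrate_threshold(oob, healthy_train, target, ds_config)
            rec_cfg = replace(ds_config, t_pat=calib.t_pat)
            preds = predict(model, test_feat)
            out[system] = _finish(system, preds, calib, rec_cfg)

    if "ds_two_path" in systems:
        path_recs = []
        t_pats, targets, achieved = {}, {}, {}
        for parity, tag, fseed in (
            ("nulliparous", "C_np", forest_seeds[2]),
            ("multiparous", "C_mp", forest_seeds[3]),
        ):
            sub_train_ids = births[
                births["id"].isin(train_ids) & (births["parity"] == parity)
            ]["id"].to_numpy()
            cfg = replace(forest_config, seed=fseed)
            model = train_forest(train_feat, cfg, subset_ids=sub_train_ids, tag=tag)
            oob = oob_posterior(
                model,
                train_feat[(train_feat["parity"] == parity)
                           & (train_feat["group"] == "healthy")],
            )
            healthy_sub = births[
                births["id"].isin(sub_train_ids) & (births["group"] == "healthy")
            ]["id"].to_numpy()
            target = _healthy_caesarean_rate(births, train_ids, parity)
            calib = calibrate_threshold(oob, healthy_sub, target, ds_config)
            rec_cfg = replace(ds_config, t_pat=calib.t_pat)
            sub_test_ids = births[
                births["id"].isin(test_ids) & (births["parity"] == parity)
            ]["id"].to_numpy()
            preds = predict(model, test_feat[test_feat["parity"] == parity])
            path_recs.append(evaluate_births(preds, sub_test_ids, rec_cfg))
            t_pats[parity], targets[parity], achieved[parity] = (
                calib.t_pat, calib.target_fp_rate, calib.achieved_fp_rate,
            )
        recs = pd.concat(path_recs, ignore_index=True)
        rates = recommendation_rates(recs, births)
        # report the union system; thresholds are per path (nulliparous one
        # first), summarised by their mean for the scalar slots
        out["ds_two_path"] = SystemRun(
            "ds_two_path",
            t_pat=float(np.mean(list(t_pats.values()))),
            target_fp_rate=float(np.mean(list(targets.values()))),
            achieved_oob_fp_rate=float(np.mean(list(achieved.values()))),
            rates=rates,
            recommendations=recs,
        )
    return out


def run_replicated_experiment(
    features: pd.DataFrame,
    births: pd.DataFrame,
    n_runs: int = 100,
    base_seed: int = 0,
    systems: tuple[str, ...] = SYSTEMS,
    forest_config: ForestConfig = ForestConfig(),
    ds_config: DSConfig = DSConfig(),
    collect_time_course: bool = False,
) -> RunResult:
    """Replicate the train/calibrate/test protocol over independent resamples.

    Aggregates per-system, per-scope, per-group recommendation rates into
    medians with notch CIs and pairwise rank-sum p-values.  A failing run
    is recorded and excluded rather than aborting the replication.
    """
    ss = np.random.SeedSequence(base_seed)
    run_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_runs)]
    rate_rows, calib_rows, tc_rows = [], [], []
    failed: list[int] = []
    for r in range(n_runs):
        try:
            runs = run_once(
                features, births, run_seeds[r], systems, forest_config, ds_config
            )
        except Exception:
            failed.append(r)
            continue
        for system, sr in runs.items():
            for _, row in sr.rates.iterrows():
                rate_rows.append(
                    {"run": r, "system": system, "scope": row["scope"],
                     "group": row["group"], "rate": row["rate"], "n": row["n"]}
                )
            calib_rows.append(
                {"run": r, "system": system, "t_pat": sr.t_pat,
                 "target": sr.target_fp_rate, "achieved": sr.achieved_oob_fp_rate}
            )
            if collect_time_course:
                tc = time_course(sr.recommendations, births)
                tc["run"], tc["system"] = r, system
                tc_rows.append(tc)

    rates = pd.DataFrame(rate_rows)
    summary_rows, pair_rows = [], []
    if len(rates):
        for (system, scope, group), sub in rates.groupby(["system", "scope", "group"]):
            vals = sub["rate"].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) >= 2:
                med, lo, hi = median_ci(vals)
            elif len(vals) == 1:
                med, lo, hi = float(vals[0]), np.nan, np.nan
            else:
                med, lo, hi = np.nan, np.nan, np.nan
            summary_rows.append(
                {"system": system, "scope": scope, "group": group,
                 "median": med, "ci_low": lo, "ci_high": hi, "n_runs": len(vals)}
            )
        for scope in rates["scope"].unique():
            for group in GROUPS:
                for sys_a, sys_b in combinations(sorted(rates["system"].unique()), 2):
                    xa = rates[
                        (rates["system"] == sys_a) & (rates["scope"] == scope)
                        & (rates["group"] == group)
                    ]["rate"].dropna().to_numpy()
                    xb = rates[
                        (rates["system"] == sys_b) & (rates["scope"] == scope)
                        & (rates["group"] == group)
                    ]["rate"].dropna().to_numpy()
                    if len(xa) and len(xb):
                        p = rank_sum_test(xa, xb)
                        pair_rows.append(
                            {"scope": scope, "group": group, "system_a": sys_a,
                             "system_b": sys_b, "p": p}
                        )
    return RunResult(
        rates=rates,
        summary=pd.DataFrame(summary_rows),
        pairwise_p=pd.DataFrame(pair_rows),
        calibration=pd.DataFrame(calib_rows),
        n_runs_requested=n_runs,
        failed_runs=failed,
        time_courses=pd.concat(tc_rows, ignore_index=True) if tc_rows else None,
    )
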