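"""Sliding-window aggregation, threshold calibration and rate summaries."""

import numpy as np
import pandas as pd
import pytest

from ctgds import DSConfig, calibrate_threshold, evaluate_birth, evaluate_births
from ctgds.decision import fp_rate_at, recommendation_rates, time_course


CFG = DSConfig(t_pat=0.5)


class TestEvaluateBirth:
    def test_five_alerting_epochs_recommended_at_first_in_time_window(self):
        rec = evaluate_birth({k: 0.9 for k in range(5)}, CFG)
        assert rec.recommended
        # earliest in-time window with >=3 present epochs has its edge at
        # index 2 (epochs 2..6, three present)
        assert rec.first_recommendation_min_before_delivery == 40.0

    def test_earliest_window_wins_for_long_labor(self):
        rec = evaluate_birth({k: 0.9 for k in range(36)}, CFG)
        assert rec.first_recommendation_min_before_delivery == 31 * 20.0

    def test_window_with_two_valid_epochs_skipped(self):
        # only two epochs exist; every window has <3 valid epochs
        rec = evaluate_birth({2: 0.9, 3: 0.95}, CFG)
        assert not rec.recommended
        assert rec.windows_evaluated == 0

    def test_alerts_only_in_final_40_minutes_not_recommended(self):
        # epochs 0..2 alert but no in-time window (edge >= 2) has 3 valid
        # epochs from them... indices 0,1,2 give window edge 0 only
        p = {0: 0.9, 1: 0.9, 2: 0.1, 3: 0.1, 4: 0.1}
        rec = evaluate_birth(p, CFG)
        assert not rec.recommended

    def test_one_cold_epoch_blocks_window(self):
        p = {2: 0.9, 3: 0.9, 4: 0.2, 5: 0.9, 6: 0.9}
        # window edge 2 covers epochs 2..6, all five present, min=0.2<=t
        rec = evaluate_birth(p, CFG)
        assert not rec.recommended

    def test_missing_marker_counts_as_missing(self):
        p = {2: 0.9, 3: 0.9, 4: np.nan, 5: 0.9, 6: 0.9}
        rec = evaluate_birth(p, CFG)
        assert rec.recommended  # 4 valid epochs, all alerting

    def test_no_epochs(self):
        rec = evaluate_birth({}, CFG)
        assert not rec.recommended and rec.windows_evaluated == 0


def test_evaluate_births_matches_single_birth_reference():
    rng = np.random.default_rng(0)
    rows = []
    expected = {}
    for i in range(40):
        bid = f"b{i:03d}"
        idx = np.sort(rng.choice(36, size=rng.integers(0, 20), replace=False))
        p_by = {int(k): float(rng.random()) for k in idx}
        for k, v in p_by.items():
            rows.append({"birth_id": bid, "epoch_index": k, "p_pat": v})
        ref = evaluate_birth(p_by, CFG)
        expected[bid] = ref
    preds = pd.DataFrame(rows, columns=["birth_id", "epoch_index", "p_pat"])
    out = evaluate_births(preds, np.array(sorted(expected)), CFG)
    for _, row in out.iterrows():
        ref = expected[row["birth_id"]]
        assert row["recommended"] == ref.recommended
        assert row["windows_evaluated"] == ref.windows_evaluated
        if ref.recommended:
            assert row["first_time_min"] == ref.first_recommendation_min_before_delivery
        else:
            assert np.isnan(row["first_time_min"])


def _oob_frame(rng, n_births=60, label="h"):
    rows = []
    for i in range(n_births):
        for k in range(rng.integers(5, 15)):
            rows.append(
                {"birth_id": f"{label}{i:03d}", "epoch_index": k, "p_pat": rng.random()}
            )
    return pd.DataFrame(rows)


class TestCalibration:
    def test_threshold_monotonicity_exhaustive_grid(self):
        rng = np.random.default_rng(1)
        preds = _oob_frame(rng)
        ids = preds["birth_id"].unique()
        from ctgds.decision import _alert_scores, _posterior_matrix

        scores = _alert_scores(_posterior_matrix(preds, ids), CFG)
        grid = np.unique(preds["p_pat"])
        fps = [fp_rate_at(scores, t) for t in grid]
        assert all(a >= b for a, b in zip(fps, fps[1:]))

    def test_target_one_gives_smallest_candidate(self):
        rng = np.random.default_rng(2)
        preds = _oob_frame(rng)
        ids = preds["birth_id"].unique()
        res = calibrate_threshold(preds, ids, 1.0, CFG)
        assert res.t_pat == np.min(preds["p_pat"].to_numpy())
        assert res.achieved_fp_rate <= 1.0

    def test_target_zero_gives_zero_fp(self):
        rng = np.random.default_rng(3)
        preds = _oob_frame(rng)
        ids = preds["birth_id"].unique()
        res = calibrate_threshold(preds, ids, 0.0, CFG)
        assert res.achieved_fp_rate == 0.0

    def test_achieved_within_one_grid_step_below_target(self):
        rng = np.random.default_rng(4)
        preds = _oob_frame(rng, n_births=120)
        ids = preds["birth_id"].unique()
        for target in (0.1, 0.25, 0.4, 0.6):
            res = calibrate_threshold(preds, ids, target, CFG)
            assert res.achieved_fp_rate <= target
            if res.fp_at_previous_candidate is not None:
                assert res.fp_at_previous_candidate > target

    def test_no_valid_windows_raises(self):
        preds = pd.DataFrame(
            [{"birth_id": "b0", "epoch_index": 0, "p_pat": 0.4}],
            columns=["birth_id", "epoch_index", "p_pat"],
        )
        with pytest.raises(ValueError):
            calibrate_threshold(preds, np.array(["b0"]), 0.5, CFG)


def _births_labels():
    rows = []
    for i, (g, p) in enumerate(
        [("healthy", "nulliparous"), ("healthy", "multiparous"),
         ("acidosis", "nulliparous"), ("hie", "multiparous")] * 5
    ):
        rows.append({"id": f"b{i:02d}", "group": g, "parity": p})
    return pd.DataFrame(rows)


class TestRates:
    def test_rates_equal_hand_count(self):
        births = _births_labels()
        recs = pd.DataFrame(
            {
                "birth_id": births["id"],
                "recommended": [i % 2 == 0 for i in range(len(births))],
                "first_time_min": [40.0 if i % 2 == 0 else np.nan for i in range(len(births))],
            }
        )
        rates = recommendation_rates(recs, births)
        allh = rates[(rates["scope"] == "all") & (rates["group"] == "healthy")]
        # healthy ids are indices 0,1 mod 4 -> recommended iff index even
        healthy_ids = births[births["group"] == "healthy"]["id"]
        manual = np.mean([int(b[1:]) % 2 == 0 for b in healthy_ids])
        assert allh["rate"].iloc[0] == pytest.approx(manual)

    def test_all_recommended_rate_one(self):
        births = _births_labels()
        recs = pd.DataFrame(
            {"birth_id": births["id"], "recommended": True, "first_time_min": 60.0}
        )
        rates = recommendation_rates(recs, births)
        assert (rates.dropna()["rate"] == 1.0).all()

    def test_union_rate_is_parity_weighted_average(self):
        births = _births_labels()
        rng = np.random.default_rng(0)
        recs = pd.DataFrame(
            {
                "birth_id": births["id"],
                "recommended": rng.random(len(births)) < 0.5,
                "first_time_min": 40.0,
            }
        )
        rates = recommendation_rates(recs, births)
        for group in ("healthy",):
            sub = rates[rates["group"] == group].set_index("scope")
            w_np, w_mp = sub.loc["nulliparous", "n"], sub.loc["multiparous", "n"]
            expect = (
                sub.loc["nulliparous", "rate"] * w_np + sub.loc["multiparous", "rate"] * w_mp
            ) / (w_np + w_mp)
            assert sub.loc["all", "rate"] == pytest.approx(expect)


class TestTimeCourse:
    def test_matches_cumulative_hand_count_and_cutoff_rate(self):
        births = _births_labels()
        first = [40.0, 120.0, np.nan, 200.0] * 5
        recs = pd.DataFrame(
            {"birth_id": births["id"], "recommended": [np.isfinite(t) for t in first],
             "first_time_min": first}
        )
        tc = time_course(recs, births)
        h = tc[tc["group"] == "healthy"].set_index("time_min")["rate"]
        # healthy births alternate first times 40 and 120
        assert h.loc[40] == pytest.approx(1.0)
        assert h.loc[60] == pytest.approx(0.5)
        assert h.loc[140] == 0.0
        # non-increasing step function
        assert (np.diff(h.to_numpy()) <= 1e-12).all()
        # value at the cutoff equals the overall recommendation rate
        rates = recommendation_rates(recs, births)
        overall = rates[(rates["scope"] == "all") & (rates["group"] == "healthy")]["rate"].iloc[0]
        assert h.loc[40] == pytest.approx(overall)

    def test_no_recommendations_identically_zero(self):
        births = _births_labels()
        recs = pd.DataFrame(
            {"birth_id": births["id"], "recommended": False, "first_time_min": np.nan}
        )
        tc = time_course(recs, births)
        assert (tc["rate"] == 0.0).all()
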