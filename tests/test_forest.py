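"""Split stratification, per-tree 2:1:1 undersampling, OOB posteriors and
two-path routing."""

import numpy as np
import pandas as pd
import pytest

from ctgds import (
    ForestConfig,
    draw_tree_sample,
    oob_posterior,
    predict,
    predict_two_path,
    split_train_test,
    train_forest,
)
from ctgds.forest import oob_balanced_accuracy, select_hyperparameters


def _births(u=5):
    """Imbalanced label frame: per parity stratum 4u healthy, 2u acidosis,
    u HIE individuals (so the 2:1:1 draw always has room)."""
    per_group = {"healthy": 4 * u, "acidosis": 2 * u, "hie": u}
    rows = []
    i = 0
    for g, n in per_group.items():
        for p in ("nulliparous", "multiparous"):
            for _ in range(n):
                rows.append({"id": f"b{i:04d}", "group": g, "parity": p})
                i += 1
    return pd.DataFrame(rows)


def _separable_features(births, epochs_per_birth=4, noise=0.1, seed=0, shift=3.0):
    """Synthetic feature frame: one informative column separates healthy
    from pathological; remaining columns are noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, b in births.iterrows():
        mu = 0.0 if b["group"] == "healthy" else shift
        for k in range(epochs_per_birth):
            rows.append(
                {
                    "birth_id": b["id"], "group": b["group"], "parity": b["parity"],
                    "epoch_index": k, "valid_fraction": 1.0,
                    "f_signal": mu + rng.normal(0, noise),
                    "f_noise1": rng.normal(), "f_noise2": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestSplit:
    def test_exact_90_10_per_stratum(self):
        births = _births(5)  # strata of 20 / 10 / 5 per parity
        train, test = split_train_test(births, seed=1)
        m = births.set_index("id")
        sizes = {"healthy": (18, 2), "acidosis": (9, 1), "hie": (4, 1)}
        for (g, _), sub in m.loc[train].groupby(["group", "parity"]):
            assert len(sub) == sizes[g][0]
        for (g, _), sub in m.loc[test].groupby(["group", "parity"]):
            assert len(sub) == sizes[g][1]

    def test_deterministic_and_disjoint(self):
        births = _births(10)
        a = split_train_test(births, seed=7)
        b = split_train_test(births, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert set(a[0]).isdisjoint(a[1])

    def test_tiny_stratum_rejected(self):
        births = _births(10)
        births = births[~((births["group"] == "hie") & (births["parity"] == "multiparous"))]
        one = pd.DataFrame([{"id": "x", "group": "hie", "parity": "multiparous"}])
        with pytest.raises(ValueError):
            split_train_test(pd.concat([births, one]), seed=0)


class TestDrawTreeSample:
    def test_2_1_1_sizes_anchored_at_hie_pool(self):
        pools = {
            "healthy": np.array([f"h{i}" for i in range(100)]),
            "acidosis": np.array([f"a{i}" for i in range(50)]),
            "hie": np.array([f"p{i}" for i in range(10)]),
        }
        rng = np.random.default_rng(0)
        sample = draw_tree_sample(pools, rng)
        groups = [s[0] for s in sample]
        assert groups.count("h") == 20 and groups.count("a") == 10 and groups.count("p") == 10
        # binary relabeling: pathological units equal healthy units
        assert groups.count("a") + groups.count("p") == groups.count("h")
        # without replacement
        assert len(set(sample)) == len(sample)

    def test_pool_too_small_rejected(self):
        pools = {
            "healthy": np.array(["h0", "h1"]),
            "acidosis": np.array(["a0", "a1"]),
            "hie": np.array(["p0", "p1"]),
        }
        with pytest.raises(ValueError):
            draw_tree_sample(pools, np.random.default_rng(0))

    def test_healthy_inclusion_frequency_binomial(self):
        pools = {
            "healthy": np.array([f"h{i}" for i in range(100)]),
            "acidosis": np.array([f"a{i}" for i in range(50)]),
            "hie": np.array([f"p{i}" for i in range(10)]),
        }
        rng = np.random.default_rng(5)
        hits = sum("h0" in set(draw_tree_sample(pools, rng)) for _ in range(1000))
        se = np.sqrt(0.2 * 0.8 / 1000)
        assert abs(hits / 1000 - 0.2) < 2 * se


class TestForest:
    def test_separable_fixture_high_oob_accuracy(self):
        births = _births(12)
        feat = _separable_features(births)
        model = train_forest(feat, ForestConfig(n_trees=100, seed=0))
        acc = oob_balanced_accuracy(oob_posterior(model, feat), feat)
        assert acc > 0.95

    def test_shuffled_labels_chance_level(self):
        births = _births(12)
        feat = _separable_features(births)
        rng = np.random.default_rng(3)
        # permute group labels at the individual level
        perm = dict(zip(births["id"], rng.permutation(births["group"].to_numpy())))
        shuffled = feat.copy()
        shuffled["group"] = shuffled["birth_id"].map(perm)
        model = train_forest(shuffled, ForestConfig(n_trees=100, seed=0))
        acc = oob_balanced_accuracy(oob_posterior(model, shuffled), shuffled)
        assert 0.35 < acc < 0.65

    def test_seed_reproducibility(self):
        births = _births(10)
        feat = _separable_features(births)
        p1 = oob_posterior(train_forest(feat, ForestConfig(n_trees=50, seed=9)), feat)
        p2 = oob_posterior(train_forest(feat, ForestConfig(n_trees=50, seed=9)), feat)
        np.testing.assert_array_equal(p1["p_pat"].to_numpy(), p2["p_pat"].to_numpy())

    def test_class_balance_every_tree(self):
        births = _births(10)
        feat = _separable_features(births)
        model = train_forest(feat, ForestConfig(n_trees=30, seed=2))
        groups = (
            feat[["birth_id", "group"]].drop_duplicates().sort_values("birth_id")["group"].to_numpy()
        )
        path = groups != "healthy"
        for t in range(30):
            inbag = model.inbag[t]
            assert inbag[path].sum() == inbag[~path].sum()

    def test_oob_vote_count_oracle(self):
        """OOB p_PAT equals a brute-force per-tree vote recount."""
        births = _births(8)
        feat = _separable_features(births, epochs_per_birth=2, noise=1.5)
        model = train_forest(feat, ForestConfig(n_trees=12, seed=4))
        oob = oob_posterior(model, feat)
        cols = [c for c in feat.columns
                if c not in ("birth_id", "group", "parity", "epoch_index", "valid_fraction")]
        X = feat[cols].to_numpy(dtype=np.float32)
        id_pos = {b: i for i, b in enumerate(model.individual_ids)}
        for row_i in range(len(feat)):
            votes, n_oob = 0, 0
            for t, clf in enumerate(model.trees):
                if not model.inbag[t, id_pos[feat["birth_id"].iat[row_i]]]:
                    n_oob += 1
                    votes += int(clf.predict(X[row_i : row_i + 1])[0])
            expect = votes / n_oob if n_oob else np.nan
            got = oob["p_pat"].iat[row_i]
            assert (np.isnan(expect) and np.isnan(got)) or got == pytest.approx(expect)

    def test_fully_inbag_individuals_get_missing_marker(self):
        births = _births(8)
        feat = _separable_features(births, epochs_per_birth=2)
        model = train_forest(feat, ForestConfig(n_trees=20, seed=1))
        oob = oob_posterior(model, feat)
        merged = oob.merge(feat[["birth_id", "group"]].drop_duplicates(), on="birth_id")
        # whole-pool HIE sampling -> every HIE epoch lacks OOB trees
        assert merged.loc[merged["group"] == "hie", "p_pat"].isna().all()
        assert merged.loc[merged["group"] == "healthy", "p_pat"].notna().all()


class TestPredict:
    def test_unanimous_pathological_vote_gives_one(self):
        births = _births(10)
        feat = _separable_features(births, noise=0.05)
        model = train_forest(feat, ForestConfig(n_trees=50, seed=0))
        probe = feat[feat["group"] == "hie"].head(4)
        assert (predict(model, probe)["p_pat"] == 1.0).all()

    def test_two_path_routing_uses_parity_model(self):
        births = _births(10)
        feat = _separable_features(births)
        np_ids = births[births["parity"] == "nulliparous"]["id"].to_numpy()
        mp_ids = births[births["parity"] == "multiparous"]["id"].to_numpy()
        m_np = train_forest(feat, ForestConfig(n_trees=30, seed=1), subset_ids=np_ids, tag="C_np")
        m_mp = train_forest(feat, ForestConfig(n_trees=30, seed=2), subset_ids=mp_ids, tag="C_mp")
        combined = predict_two_path(m_np, m_mp, feat).set_index(["birth_id", "epoch_index"])
        direct_np = predict(m_np, feat[feat["parity"] == "nulliparous"])
        for _, row in direct_np.iterrows():
            assert combined.loc[(row["birth_id"], row["epoch_index"]), "p_pat"] == row["p_pat"]

    def test_identical_paths_give_identical_posteriors(self):
        births = _births(10)
        feat = _separable_features(births)
        m1 = train_forest(feat, ForestConfig(n_trees=30, seed=5), tag="C_np")
        m2 = train_forest(feat, ForestConfig(n_trees=30, seed=5), tag="C_mp")
        np.testing.assert_array_equal(
            predict_two_path(m1, m2, feat).sort_values(["birth_id", "epoch_index"])["p_pat"].to_numpy(),
            predict(m1, feat).sort_values(["birth_id", "epoch_index"])["p_pat"].to_numpy(),
        )

    def test_unknown_parity_rejected(self):
        births = _births(10)
        feat = _separable_features(births)
        m = train_forest(feat, ForestConfig(n_trees=10, seed=0))
        bad = feat.copy()
        bad.loc[bad.index[:2], "parity"] = "unknown"
        with pytest.raises(ValueError):
            predict_two_path(m, m, bad)


def test_hyperparameter_grid_scored_by_oob():
    births = _births(10)
    feat = _separable_features(births)
    best, scores = select_hyperparameters(
        feat, ForestConfig(n_trees=30, seed=0), depths=(2, 8), max_features_grid=("sqrt",)
    )
    assert len(scores) == 2
    assert best.max_depth in (2, 8)
    assert scores["oob_balanced_accuracy"].max() > 0.9
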