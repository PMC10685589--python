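"""Parity-aware random-forest epoch classification.

The task is binary: healthy vs a pathological class pooling the acidosis
and HIE groups.  Four classifier configurations are supported:

* ``C_all``    — all training births, CTG features only;
* ``C_all+np`` — all training births, plus the nulliparity flag feature;
* ``C_np``     — nulliparous training births only;
* ``C_mp``     — multiparous training births only.

Every tree is grown on an undersampled *individual-level* draw at the fixed
2:1:1 healthy : acidosis : HIE ratio — the whole HIE pool, an equal number
of acidosis individuals and twice that number of healthy individuals, all
sampled without replacement — so each tree's individuals are exactly
class-balanced (2 healthy vs 1+1 pathological units).  All epochs of a
sampled individual enter the tree.  An individual left out of a tree's draw
is out-of-bag (OOB) for that tree, and the OOB posterior p_PAT of its
epochs is the pathological vote fraction over those trees only.  Because
the HIE pool is used whole, HIE individuals have no OOB trees and get a
missing marker (NaN).

Base learners are scikit-learn decision trees; the sampling, OOB
bookkeeping and two-path parity routing are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .cohort import GROUPS

META_COLUMNS = ("birth_id", "group", "parity", "epoch_index", "valid_fraction")

CONFIG_TAGS = ("C_all", "C_all+np", "C_np", "C_mp")


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    The reference analysis uses 2,500 trees; the scaled default here is 200.
    """

    n_trees: int = 200
    max_depth: int | None = 12
    max_features: str | int | float = "sqrt"
    ratio: tuple[int, int, int] = (2, 1, 1)  # healthy : acidosis : HIE
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if any(r <= 0 for r in self.ratio):
            raise ValueError("ratio components must be positive")


@dataclass
class TrainedModel:
    """A fitted forest with its per-tree in-bag individual sets."""

    tag: str
    config: ForestConfig
    include_parity: bool
    trees: list[DecisionTreeClassifier]
    individual_ids: np.ndarray  # ids of training individuals, sorted
    inbag: np.ndarray  # bool (n_trees, n_individuals)
    feature_columns: list[str]


def split_train_test(
    births: pd.DataFrame, train_frac: float = 0.9, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Individual-level split, stratified by group x parity.

    All epochs of a birth land on one side.  Every stratum must hold at
    least 2 births so both sides are populated.
    """
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for (_, _), sub in births.groupby(["group", "parity"], sort=True):
        ids = np.sort(sub["id"].to_numpy())
        if len(ids) < 2:
            raise ValueError(
                f"stratum {sub['group'].iat[0]}/{sub['parity'].iat[0]} too small to stratify"
            )
        perm = rng.permutation(len(ids))
        n_train = max(1, min(len(ids) - 1, int(np.floor(train_frac * len(ids)))))
        train.append(ids[perm[:n_train]])
        test.append(ids[perm[n_train:]])
    train_ids = np.sort(np.concatenate(train))
    test_ids = np.sort(np.concatenate(test))
    assert len(np.intersect1d(train_ids, test_ids)) == 0, "train/test leakage"
    return train_ids, test_ids


def draw_tree_sample(
    ids_by_group: dict[str, np.ndarray],
    rng: np.random.Generator,
    ratio: tuple[int, int, int] = (2, 1, 1),
) -> np.ndarray:
    """One tree's individual draw at the healthy:acidosis:HIE ratio.

    Anchored at the full HIE pool (the rarest group), taken whole without
    replacement; the other groups are subsampled without replacement.
    """
    pools = [np.asarray(ids_by_group[g]) for g in GROUPS]
    k = len(pools[2]) // ratio[2]
    if k == 0:
        raise ValueError("empty HIE pool")
    sizes = [ratio[0] * k, ratio[1] * k, ratio[2] * k]
    out = []
    for pool, size in zip(pools, sizes):
        if len(pool) < size:
            raise ValueError(f"pool of {len(pool)} too small for draw of {size}")
        if size == len(pool):
            out.append(pool)
        else:
            out.append(rng.choice(pool, size=size, replace=False))
    return np.concatenate(out)


def _design_matrix(
    features: pd.DataFrame, include_parity: bool
) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in features.columns if c not in META_COLUMNS]
    X = features[cols].to_numpy(dtype=np.float32)
    if include_parity:
        flag = (features["parity"].to_numpy() == "nulliparous").astype(np.float32)
        X = np.column_stack([X, flag])
        cols = cols + ["nulliparous"]
    return np.ascontiguousarray(X), cols


def _row_index_by_individual(
    birth_ids: np.ndarray, individual_ids: np.ndarray
) -> list[np.ndarray]:
    order = np.argsort(birth_ids, kind="stable")
    sorted_ids = birth_ids[order]
    bounds = np.searchsorted(sorted_ids, individual_ids)
    bounds_hi = np.searchsorted(sorted_ids, individual_ids, side="right")
    return [order[lo:hi] for lo, hi in zip(bounds, bounds_hi)]


def train_forest(
    features: pd.DataFrame,
    config: ForestConfig = ForestConfig(),
    include_parity: bool = False,
    subset_ids: np.ndarray | None = None,
    tag: str = "C_all",
) -> TrainedModel:
    """Fit one forest configuration on a training feature table.

    ``subset_ids`` restricts training to those births (used for C_np/C_mp
    and for the train side of a split).  Reproducible given ``config.seed``.
    """
    config.validate()
    if subset_ids is not None:
        features = features[features["birth_id"].isin(np.asarray(subset_ids))]
    if len(features) == 0:
        raise ValueError("empty training set")

    X, cols = _design_matrix(features, include_parity)
    y = (features["group"].to_numpy() != "healthy").astype(np.int8)
    birth_ids = features["birth_id"].to_numpy()

    indiv = features[["birth_id", "group"]].drop_duplicates().sort_values("birth_id")
    individual_ids = indiv["birth_id"].to_numpy()
    ids_by_group = {
        g: indiv.loc[indiv["group"] == g, "birth_id"].to_numpy() for g in GROUPS
    }
    if any(len(ids_by_group[g]) == 0 for g in GROUPS):
        raise ValueError("all three groups must be present in the training set")
    rows_by_indiv = _row_index_by_individual(birth_ids, individual_ids)
    pos = {bid: i for i, bid in enumerate(individual_ids)}

    ss = np.random.SeedSequence(config.seed)
    tree_seeds = ss.spawn(config.n_trees)
    trees: list[DecisionTreeClassifier] = []
    inbag = np.zeros((config.n_trees, len(individual_ids)), dtype=bool)
    for t in range(config.n_trees):
        rng = np.random.default_rng(tree_seeds[t])
        sample = draw_tree_sample(ids_by_group, rng, config.ratio)
        idx = [pos[b] for b in sample]
        inbag[t, idx] = True
        rows = np.concatenate([rows_by_indiv[i] for i in idx])
        clf = DecisionTreeClassifier(
            max_depth=config.max_depth,
            max_features=config.max_features,
            random_state=int(rng.integers(2**31)),
        )
        clf.fit(X[rows], y[rows])
        trees.append(clf)
    return TrainedModel(tag, config, include_parity, trees, individual_ids, inbag, cols)


def _votes(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """(n_trees, n_rows) pathological votes.

    Uses the fitted Cython tree directly (input is already the validated
    float32 design matrix), which avoids per-tree estimator overhead.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    out = np.empty((len(model.trees), len(X)), dtype=np.int8)
    for t, clf in enumerate(model.trees):
        leaf_counts = clf.tree_.predict(X).reshape(len(X), -1)  # (n_rows, n_classes)
        if leaf_counts.shape[1] == 1:  # degenerate single-class tree
            out[t] = int(clf.classes_[0])
        else:
            out[t] = leaf_counts[:, 1] > leaf_counts[:, 0]
    return out


def _check_columns(model: TrainedModel, cols: list[str]) -> None:
    if cols != model.feature_columns:
        raise ValueError("feature schema mismatch with trained model")


def oob_posterior(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Out-of-bag p_PAT per training epoch.

    p_PAT is the pathological vote fraction over the trees whose in-bag
    draw excluded the epoch's individual; epochs of individuals in-bag for
    every tree (the whole-pool HIE individuals) get NaN.
    """
    features = features[features["birth_id"].isin(model.individual_ids)]
    X, cols = _design_matrix(features, model.include_parity)
    _check_columns(model, cols)
    votes = _votes(model, X)
    ind_idx = np.searchsorted(model.individual_ids, features["birth_id"].to_numpy())
    oob_mask = ~model.inbag[:, ind_idx]  # (n_trees, n_rows)
    n_oob = oob_mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_oob > 0, (votes * oob_mask).sum(axis=0) / np.maximum(n_oob, 1), np.nan)
    return pd.DataFrame(
        {
            "birth_id": features["birth_id"].to_numpy(),
            "epoch_index": features["epoch_index"].to_numpy(),
            "p_pat": p,
            "n_oob_trees": n_oob,
        }
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Full-forest p_PAT (vote fraction over all trees) per epoch."""
    X, cols = _design_matrix(features, model.include_parity)
    _check_columns(model, cols)
    p = _votes(model, X).mean(axis=0)
    return pd.DataFrame(
        {
            "birth_id": features["birth_id"].to_numpy(),
            "epoch_index": features["epoch_index"].to_numpy(),
            "p_pat": p,
        }
    )


def predict_two_path(
    model_np: TrainedModel, model_mp: TrainedModel, features: pd.DataFrame
) -> pd.DataFrame:
    """Route each birth to C_np or C_mp by its parity label, then predict."""
    parity = features["parity"].to_numpy()
    known = np.isin(parity, ["nulliparous", "multiparous"])
    if not known.all():
        bad = features.loc[~known, "birth_id"].unique()
        raise ValueError(f"unknown parity for births {list(bad)[:5]}: two-path routing has no fallback")
    parts = []
    for model, label in ((model_np, "nulliparous"), (model_mp, "multiparous")):
        sub = features[features["parity"] == label]
        if len(sub):
            parts.append(predict(model, sub))
    return pd.concat(parts, ignore_index=True)


def oob_balanced_accuracy(oob: pd.DataFrame, features: pd.DataFrame) -> float:
    """Epoch-level OOB balanced accuracy at the 0.5 vote threshold.

    Restricted to epochs with at least one OOB tree (HIE epochs have none
    under whole-pool sampling, so the pathological side is acidosis-driven).
    """
    merged = oob.merge(
        features[["birth_id", "epoch_index", "group"]], on=["birth_id", "epoch_index"]
    )
    merged = merged[merged["n_oob_trees"] > 0]
    y = (merged["group"] != "healthy").to_numpy()
    yhat = (merged["p_pat"] > 0.5).to_numpy()
    tpr = yhat[y].mean() if y.any() else np.nan
    tnr = (~yhat[~y]).mean() if (~y).any() else np.nan
    return float(0.5 * (tpr + tnr))


def select_hyperparameters(
    features: pd.DataFrame,
    config: ForestConfig = ForestConfig(),
    depths: tuple[int | None, ...] = (8, 12, None),
    max_features_grid: tuple = ("sqrt", 0.25),
    include_parity: bool = False,
) -> tuple[ForestConfig, pd.DataFrame]:
    """Small OOB-scored grid over depth and features-per-split."""
    rows = []
    best, best_score = None, -np.inf
    for depth, mf in product(depths, max_features_grid):
        cfg = replace(config, max_depth=depth, max_features=mf)
        model = train_forest(features, cfg, include_parity=include_parity)
        score = oob_balanced_accuracy(oob_posterior(model, features), features)
        rows.append({"max_depth": depth, "max_features": mf, "oob_balanced_accuracy": score})
        if score > best_score:
            best, best_score = cfg, score
    return best, pd.DataFrame(rows)
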