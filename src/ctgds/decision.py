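"""Sliding-window decision support over epoch alerts.

Per-epoch posteriors p_PAT are aggregated into a per-birth intervention
recommendation by a 100-minute (5-epoch) window sliding from the earliest
epoch toward delivery in 20-minute steps:

* a window with fewer than 3 valid epochs (more than 2 missing out of 5)
  is skipped and the scan continues;
* a window recommends intervention iff *every* valid epoch inside it has
  issued an alert, i.e. p_PAT strictly above the threshold t_PAT;
* only windows whose delivery-proximal edge lies at least 40 minutes before
  delivery count — later decisions are too late for effective intervention;
* the birth's recommendation time is the earliest (farthest from delivery)
  recommending window's edge.

t_PAT is calibrated on the out-of-bag posteriors of the healthy training
births: the candidate grid is the sorted distinct OOB p_PAT values, and the
selected threshold is the smallest whose false-positive recommendation rate
does not exceed the healthy-group Caesarean delivery rate of the same
training subpopulation (the conservative reading of rate matching on a
finite grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import MAX_EPOCHS


@dataclass(frozen=True)
class DSConfig:
    """Sliding-window aggregation parameters."""

    window_min: int = 100
    epoch_min: int = 20
    max_missing_epochs: int = 2
    cutoff_min_before_delivery: int = 40
    t_pat: float = 0.5

    def validate(self) -> None:
        if self.window_min % self.epoch_min != 0:
            raise ValueError("window must be divisible by epoch length")
        if self.cutoff_min_before_delivery < 0:
            raise ValueError("cutoff must be >= 0")
        if not 0.0 <= self.t_pat <= 1.0:
            raise ValueError("t_pat must be in [0, 1]")

    @property
    def window_epochs(self) -> int:
        return self.window_min // self.epoch_min

    @property
    def min_valid_epochs(self) -> int:
        return self.window_epochs - self.max_missing_epochs

    @property
    def cutoff_index(self) -> int:
        """Smallest delivery-edge epoch index whose decision is in time."""
        return -(-self.cutoff_min_before_delivery // self.epoch_min)


@dataclass
class Recommendation:
    birth_id: str
    recommended: bool
    first_recommendation_min_before_delivery: float | None
    windows_evaluated: int


@dataclass
class CalibrationResult:
    t_pat: float
    achieved_fp_rate: float
    target_fp_rate: float
    n_candidates: int
    #: FP rate at the next-lower candidate threshold (None if t_pat is the
    #: smallest candidate); > target unless the grid is degenerate, which
    #: is what "within one grid step below the target" means.
    fp_at_previous_candidate: float | None = None


def _window_scores(p_by_index: dict[int, float], cfg: DSConfig) -> list[tuple[int, float]]:
    """(edge index j, min p_PAT over present epochs) for each valid window.

    Window j covers epoch slots j..j+4 (edge at 20·j minutes before
    delivery); missing slots are epochs excluded by the validity rule or
    beyond the recorded labor.  NaN posteriors count as missing.
    """
    finite = {k: v for k, v in p_by_index.items() if v is not None and np.isfinite(v)}
    if not finite:
        return []
    w = cfg.window_epochs
    scores = []
    for j in range(0, MAX_EPOCHS - w + 1):
        present = [finite[k] for k in range(j, j + w) if k in finite]
        if len(present) >= cfg.min_valid_epochs:
            scores.append((j, min(present)))
    return scores


def birth_alert_score(p_by_index: dict[int, float], cfg: DSConfig) -> float:
    """Threshold-free recommendation score of one birth.

    The birth is recommended at threshold t iff this score is > t: it is
    the max over in-time valid windows of the window's min p_PAT, or -inf
    when no such window exists.
    """
    eligible = [s for j, s in _window_scores(p_by_index, cfg) if j >= cfg.cutoff_index]
    return max(eligible) if eligible else -np.inf


def evaluate_birth(p_by_index: dict[int, float], cfg: DSConfig) -> "Recommendation":
    """Apply the sliding-window rule to one birth's epoch posteriors."""
    cfg.validate()
    scores = _window_scores(p_by_index, cfg)
    in_time = [(j, s) for j, s in scores if j >= cfg.cutoff_index]
    rec_windows = [j for j, s in in_time if s > cfg.t_pat]
    recommended = len(rec_windows) > 0
    first = float(max(rec_windows) * cfg.epoch_min) if recommended else None
    return Recommendation(
        birth_id="", recommended=recommended,
        first_recommendation_min_before_delivery=first,
        windows_evaluated=len(in_time),
    )


def _posterior_matrix(
    predictions: pd.DataFrame, birth_ids: np.ndarray
) -> np.ndarray:
    """(n_births, 36) p_PAT matrix aligned to ``birth_ids``; NaN = missing."""
    birth_ids = np.asarray(birth_ids)
    M = np.full((len(birth_ids), MAX_EPOCHS), np.nan)
    sub = predictions[predictions["birth_id"].isin(birth_ids)]
    order = np.argsort(birth_ids, kind="stable")
    pos_sorted = np.searchsorted(birth_ids[order], sub["birth_id"].to_numpy())
    rows = order[pos_sorted]
    cols = sub["epoch_index"].to_numpy(dtype=int)
    keep = (cols >= 0) & (cols < MAX_EPOCHS)
    M[rows[keep], cols[keep]] = sub["p_pat"].to_numpy()[keep]
    return M


def _window_stats(M: np.ndarray, cfg: DSConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-birth window minima and validity over the in-time window edges.

    Returns (wmin, valid) of shape (n_births, n_edges) where edge index j
    runs over cfg.cutoff_index .. MAX_EPOCHS - window; wmin is the min
    p_PAT over present epochs (+inf where none), valid marks windows with
    at least ``min_valid_epochs`` present epochs.
    """
    w = cfg.window_epochs
    edges = range(cfg.cutoff_index, MAX_EPOCHS - w + 1)
    wmin = np.empty((len(M), len(edges)))
    valid = np.empty((len(M), len(edges)), dtype=bool)
    for col, j in enumerate(edges):
        W = M[:, j : j + w]
        present = ~np.isnan(W)
        valid[:, col] = present.sum(axis=1) >= cfg.min_valid_epochs
        wmin[:, col] = np.nanmin(np.where(present, W, np.inf), axis=1)
    return wmin, valid


def _alert_scores(M: np.ndarray, cfg: DSConfig) -> np.ndarray:
    """Vectorized :func:`birth_alert_score` over a posterior matrix."""
    wmin, valid = _window_stats(M, cfg)
    scores = np.where(valid, wmin, -np.inf)
    return scores.max(axis=1, initial=-np.inf)


def evaluate_births(
    predictions: pd.DataFrame, birth_ids: np.ndarray, cfg: DSConfig
) -> pd.DataFrame:
    """Recommendations for every listed birth (births with no epochs are
    never recommended)."""
    cfg.validate()
    birth_ids = np.asarray(birth_ids)
    M = _posterior_matrix(predictions, birth_ids)
    wmin, valid = _window_stats(M, cfg)
    alert = valid & (wmin > cfg.t_pat)
    recommended = alert.any(axis=1)
    # earliest recommending window = largest edge index
    edge0 = cfg.cutoff_index
    last_col = alert.shape[1] - 1 - np.argmax(alert[:, ::-1], axis=1)
    first_time = np.where(
        recommended, (edge0 + last_col) * float(cfg.epoch_min), np.nan
    )
    return pd.DataFrame(
        {
            "birth_id": birth_ids,
            "recommended": recommended,
            "first_time_min": first_time,
            "windows_evaluated": valid.sum(axis=1),
        }
    )


def fp_rate_at(scores: np.ndarray, t: float) -> float:
    """Recommendation (false-positive) rate of healthy scores at threshold t."""
    return float(np.mean(scores > t))


def calibrate_threshold(
    oob_predictions: pd.DataFrame,
    healthy_ids: np.ndarray,
    target_fp_rate: float,
    cfg: DSConfig,
) -> CalibrationResult:
    """Choose t_PAT so the healthy-group OOB recommendation rate matches the
    Caesarean target.

    Candidates are the sorted distinct finite OOB p_PAT values; the smallest
    candidate whose false-positive rate does not exceed the target is
    selected.  By monotonicity the achieved rate is within one grid step
    below the target.
    """
    healthy_ids = np.asarray(healthy_ids)
    sub = oob_predictions[oob_predictions["birth_id"].isin(healthy_ids)]
    # births with no valid window (or no OOB predictions at all) score -inf
    # and are never recommended at any threshold
    all_scores = _alert_scores(_posterior_matrix(sub, healthy_ids), cfg)
    if not np.isfinite(all_scores).any():
        raise ValueError("no healthy births with valid windows — cannot calibrate")

    candidates = np.unique(sub["p_pat"].to_numpy())
    candidates = candidates[np.isfinite(candidates)]
    finite_scores = np.sort(all_scores)
    n = len(all_scores)
    # fp(t) = (# scores > t) / n, non-increasing in t
    counts_above = n - np.searchsorted(finite_scores, candidates, side="right")
    ok = counts_above / n <= target_fp_rate
    if not ok.any():
        # only possible if target < 0 on a finite grid; max candidate always
        # satisfies fp = P(score > max p) = 0 for min-of-p scores
        chosen = len(candidates) - 1
    else:
        chosen = int(np.argmax(ok))
    t = float(candidates[chosen])
    achieved = fp_rate_at(all_scores, t)
    prev_fp = (
        float(counts_above[chosen - 1] / n) if chosen > 0 else None
    )
    return CalibrationResult(
        t_pat=t, achieved_fp_rate=achieved,
        target_fp_rate=float(target_fp_rate), n_candidates=len(candidates),
        fp_at_previous_candidate=prev_fp,
    )


def recommendation_rates(
    recommendations: pd.DataFrame, births: pd.DataFrame
) -> pd.DataFrame:
    """Per group (and per parity scope) recommendation rates.

    Scopes: 'all', 'nulliparous', 'multiparous'.  Empty cells get NaN rate
    and n=0.
    """
    merged = recommendations.merge(
        births[["id", "group", "parity"]], left_on="birth_id", right_on="id"
    )
    rows = []
    for scope in ("all", "nulliparous", "multiparous"):
        sub = merged if scope == "all" else merged[merged["parity"] == scope]
        for group in ("healthy", "acidosis", "hie"):
            g = sub[sub["group"] == group]
            rate = float(g["recommended"].mean()) if len(g) else np.nan
            rows.append({"scope": scope, "group": group, "rate": rate, "n": len(g)})
    return pd.DataFrame(rows)


def time_course(
    recommendations: pd.DataFrame,
    births: pd.DataFrame,
    max_time_min: int = 720,
    step_min: int = 20,
) -> pd.DataFrame:
    """Recommendation rate as a function of time before delivery.

    At each time t, the fraction of each group whose first recommendation
    occurred at >= t minutes before delivery — a non-increasing step
    function of t that equals the overall rate at the 40-minute cutoff.
    """
    merged = recommendations.merge(
        births[["id", "group"]], left_on="birth_id", right_on="id"
    )
    times = np.arange(0, max_time_min + step_min, step_min)
    rows = []
    for group, sub in merged.groupby("group", sort=True):
        first = sub["first_time_min"].to_numpy(dtype=float)  # NaN if never
        for t in times:
            rows.append(
                {"group": group, "time_min": int(t),
                 "rate": float(np.mean(first >= t)), "n": len(sub)}
            )
    return pd.DataFrame(rows)
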