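"""Transition-count and dwell-time featurization of epochs.

Each 20-minute epoch is summarized over the joint (FHR x UP) state set
S = {baseline, acceleration, deceleration, invalid} x {contraction, rest,
invalid} (|S| = 12, FHR-major order) by:

* the S x S transition-count matrix (zero diagonal) over adjacent runs,
  counted within contiguous valid segments only — excised invalid samples
  never create a transition;
* per-state dwell totals (seconds), mean dwells and visit counts;
* per-state occupancy fractions (dwell total / valid time).

The flattened feature order is fixed and exposed by :func:`feature_names`.
An optional nulliparity flag is appended when the classifier is configured
to use the clinical parity variable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import FHR_STATES, UP_STATES, TICKS_PER_S, BirthRecord
from .preprocessing import Epoch, N_JOINT_STATES, joint_intervals, segment_epochs

#: joint state labels, FHR-major: "baseline|contraction", ...
JOINT_STATE_LABELS = tuple(f"{f}|{u}" for f in FHR_STATES for u in UP_STATES)

_SHORT = tuple(f"{f[0].upper()}{u[0].lower()}" for f in FHR_STATES for u in UP_STATES)


def feature_names(include_parity: bool = False) -> list[str]:
    """Fixed, documented feature column order."""
    names = [
        f"trans_{_SHORT[i]}_{_SHORT[j]}"
        for i in range(N_JOINT_STATES)
        for j in range(N_JOINT_STATES)
    ]
    names += [f"dwell_total_{s}" for s in _SHORT]
    names += [f"dwell_mean_{s}" for s in _SHORT]
    names += [f"occ_{s}" for s in _SHORT]
    if include_parity:
        names.append("nulliparous")
    return names


def joint_runs(
    fhr_runs: "object", up_runs: "object", window_ticks: tuple[int, int] | None = None
) -> list[tuple[int, int]]:
    """Joint run sequence of two fully valid channels over a window.

    Accepts :class:`~ctgds.cohort.EventStream` objects; the window defaults
    to the full common extent.  Returns (joint_code, dwell_ticks) runs whose
    dwells sum to the window length; consecutive joint states are distinct.
    """
    t0, t1 = window_ticks if window_ticks is not None else (0, fhr_runs.total_ticks)
    dw, fs, us = joint_intervals(fhr_runs, up_runs, t0, t1)
    codes = fs.astype(np.int64) * 3 + us
    out: list[tuple[int, int]] = []
    for c, d in zip(codes, dw):
        if out and out[-1][0] == c:
            out[-1] = (int(c), out[-1][1] + int(d))
        else:
            out.append((int(c), int(d)))
    return out


def transition_counts(segments: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """S x S adjacent-run transition counts, within segments only."""
    mat = np.zeros((N_JOINT_STATES, N_JOINT_STATES), dtype=np.int64)
    for codes, _ in segments:
        if len(codes) > 1:
            np.add.at(mat, (codes[:-1].astype(int), codes[1:].astype(int)), 1)
    return mat


def dwell_stats(
    segments: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-state (visit count, total dwell seconds, mean dwell seconds).

    States never visited get (0, 0, 0).
    """
    if segments:
        all_codes = np.concatenate([c for c, _ in segments]).astype(np.intp)
        all_dwells = np.concatenate([d for _, d in segments])
        counts = np.bincount(all_codes, minlength=N_JOINT_STATES)
        total_ticks = np.bincount(
            all_codes, weights=all_dwells, minlength=N_JOINT_STATES
        ).astype(np.int64)
    else:
        counts = np.zeros(N_JOINT_STATES, dtype=np.int64)
        total_ticks = np.zeros(N_JOINT_STATES, dtype=np.int64)
    total_s = total_ticks / TICKS_PER_S
    with np.errstate(invalid="ignore"):
        mean_s = np.where(counts > 0, total_s / np.maximum(counts, 1), 0.0)
    return counts, total_s, mean_s


def featurize(epoch: Epoch, include_parity: bool = False, nulliparous: int | None = None) -> np.ndarray:
    """Flatten one epoch into the fixed feature order.

    ``nulliparous`` (0/1) is required iff ``include_parity``.
    """
    mat = transition_counts(epoch.segments)
    counts, total_s, mean_s = dwell_stats(epoch.segments)
    total_valid = total_s.sum()
    occ = total_s / total_valid if total_valid > 0 else total_s
    parts = [mat.ravel().astype(float), total_s, mean_s, occ]
    if include_parity:
        if nulliparous is None:
            raise ValueError("nulliparous flag required when include_parity=True")
        parts.append(np.array([float(nulliparous)]))
    return np.concatenate(parts)


def features_table(records: list[BirthRecord], **segment_kwargs) -> pd.DataFrame:
    """Epoch feature table for a cohort.

    One row per retained epoch: metadata columns (birth_id, group, parity,
    epoch_index, valid_fraction) followed by the base feature columns
    (without the parity flag — classifiers append it from the ``parity``
    column when configured to).
    """
    base_names = feature_names(include_parity=False)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    for rec in records:
        for ep in segment_epochs(rec, **segment_kwargs):
            rows.append(featurize(ep))
            meta.append(
                (rec.id, rec.group, rec.parity, ep.index_from_delivery, ep.valid_fraction)
            )
    meta_df = pd.DataFrame(
        meta, columns=["birth_id", "group", "parity", "epoch_index", "valid_fraction"]
    )
    feat_df = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(base_names))),
        columns=base_names,
    )
    return pd.concat([meta_df, feat_df], axis=1)
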