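"""Signal conditioning and epoching.

Two families of operations live here:

* numeric-signal conditioning on :class:`SampledSignal` — linear
  interpolation of short (< 15 s) FHR gaps and up-sampling of the 1 Hz
  uterine-pressure channel to 4 Hz;
* event-stream epoching on :class:`~ctgds.cohort.BirthRecord` — tiling
  20-minute epochs backward from delivery over at most the last 12 hours,
  healing short dropouts with the same < 15 s rule, excluding epochs with
  less than 80% valid samples on either channel, and run-length encoding
  the joint (FHR state, UP state) sequence of each retained epoch.

Epoch indices are delivery-anchored: epoch k spans [-20(k+1), -20k] minutes,
so index 0 is the epoch ending at delivery and at most 36 epochs exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    TICKS_PER_S,
    BirthRecord,
    EventStream,
    FHR_INVALID,
    UP_INVALID,
    _merge_same_state,
)

EPOCH_MIN = 20
EPOCH_TICKS = EPOCH_MIN * 60 * TICKS_PER_S  # 4800 samples at 4 Hz
MAX_EPOCHS = 36  # 12 h horizon / 20 min

#: number of joint (FHR x UP) states: 4 FHR x 3 UP
N_JOINT_STATES = 12


def joint_code(fhr_code: int, up_code: int) -> int:
    """Joint state code, FHR-major: fhr*3 + up, in 0..11."""
    return fhr_code * 3 + up_code


@dataclass
class SampledSignal:
    """Uniformly sampled signal with a validity mask, ending at delivery."""

    values: np.ndarray
    valid: np.ndarray
    rate_hz: int
    t_end_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have equal length")
        if self.rate_hz not in (1, 4):
            raise ValueError("rate_hz must be 1 or 4")


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal invalid runs as (start, stop) index pairs."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def interpolate_short_gaps(signal: SampledSignal, max_gap_s: float = 15.0) -> SampledSignal:
    """Linearly interpolate invalid FHR runs strictly shorter than 15 s.

    Runs of ``max_gap_s`` or longer, and leading/trailing gaps (which lack a
    flanking valid sample), are left untouched.  An all-invalid signal is
    returned unchanged.  Idempotent.
    """
    if signal.rate_hz != 4:
        raise ValueError("gap interpolation is defined on the 4 Hz channel")
    values = signal.values.copy()
    valid = signal.valid.copy()
    n = len(values)
    max_len = int(round(max_gap_s * signal.rate_hz))
    for start, stop in _invalid_runs(signal.valid):
        if stop - start >= max_len or start == 0 or stop == n:
            continue
        left, right = values[start - 1], values[stop]
        k = stop - start
        frac = np.arange(1, k + 1) / (k + 1)
        values[start:stop] = left + frac * (right - left)
        valid[start:stop] = True
    return SampledSignal(values, valid, signal.rate_hz, signal.t_end_s)


def upsample_uterine(signal: SampledSignal) -> SampledSignal:
    """Up-sample the 1 Hz uterine-pressure signal to 4 Hz.

    Values at the original instants are reproduced exactly; in-between
    samples are linearly interpolated when both flanking source samples are
    valid, otherwise held at the earlier value.  Each source sample's block
    of four output samples inherits its validity.
    """
    if signal.rate_hz != 1:
        raise ValueError("upsample_uterine expects a 1 Hz signal")
    v = signal.values
    n = len(v)
    out = np.repeat(v, 4)
    valid = np.repeat(signal.valid, 4)
    if n > 1:
        both_valid = signal.valid[:-1] & signal.valid[1:]
        for off, frac in ((1, 0.25), (2, 0.5), (3, 0.75)):
            idx = np.arange(n - 1) * 4 + off
            interp = v[:-1] + frac * (v[1:] - v[:-1])
            out[idx] = np.where(both_valid, interp, v[:-1])
    return SampledSignal(out, valid, 4, signal.t_end_s)


@dataclass
class Epoch:
    """One retained 20-minute epoch of a birth, delivery-anchored.

    ``segments`` is the run-length-encoded joint state sequence, split into
    maximal contiguous valid stretches: invalid samples are excised and no
    transition is counted across an excision.
    """

    birth_id: str
    index_from_delivery: int
    start_min_before_delivery: float
    end_min_before_delivery: float
    segments: list[tuple[np.ndarray, np.ndarray]]  # (joint codes, dwell ticks)
    valid_fraction: float
    valid_fraction_fhr: float
    valid_fraction_up: float


def heal_short_dropouts(stream: EventStream, max_gap_s: float = 15.0) -> EventStream:
    """Apply the < 15 s gap rule at the event level.

    An invalid run strictly shorter than ``max_gap_s`` with valid neighbours
    on both sides is absorbed into them, split at its midpoint (ties give
    the extra tick to the earlier run).  This is the event-stream analogue
    of :func:`interpolate_short_gaps`.
    """
    inv = stream.invalid_code()
    states = stream.states.copy()
    dwells = stream.dwells.copy()
    max_ticks = int(round(max_gap_s * TICKS_PER_S))
    n = len(states)
    if n < 3:
        return EventStream(stream.channel, states, dwells)
    heal = np.zeros(n, dtype=bool)
    interior = np.arange(1, n - 1)
    heal[interior] = (
        (states[interior] == inv)
        & (dwells[interior] < max_ticks)
        & (states[interior - 1] != inv)
        & (states[interior + 1] != inv)
    )
    if not heal.any():
        return EventStream(stream.channel, states, dwells)
    idx = np.flatnonzero(heal)
    left_share = (dwells[idx] + 1) // 2
    # healed runs sit between two valid runs, so targets are never healed
    np.add.at(dwells, idx - 1, left_share)
    np.add.at(dwells, idx + 1, dwells[idx] - left_share)
    keep = ~heal
    s, d = _merge_same_state(states[keep], dwells[keep])
    return EventStream(stream.channel, s, d)


def _run_bounds(stream: EventStream) -> np.ndarray:
    return np.concatenate(([0], np.cumsum(stream.dwells)))


def _clip_cuts(
    bounds: np.ndarray, states: np.ndarray, t0: int, t1: int
) -> tuple[np.ndarray, np.ndarray]:
    """Run boundaries and states clipped to ticks [t0, t1)."""
    i0 = int(np.searchsorted(bounds, t0, side="right")) - 1
    i1 = int(np.searchsorted(bounds, t1, side="left"))
    b = bounds[i0 : i1 + 1].copy()
    b[0], b[-1] = t0, t1
    return b, states[i0:i1]


def joint_intervals(
    fhr: EventStream, up: EventStream, t0: int, t1: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge the two channels over ticks [t0, t1).

    Returns (dwell_ticks, fhr_states, up_states) for the interleaved
    interval partition: a new interval starts whenever either channel
    changes state.
    """
    return _joint_intervals_from_bounds(
        _run_bounds(fhr), fhr.states, _run_bounds(up), up.states, t0, t1
    )


def _joint_intervals_from_bounds(
    fhr_bounds: np.ndarray,
    fhr_states: np.ndarray,
    up_bounds: np.ndarray,
    up_states: np.ndarray,
    t0: int,
    t1: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fb, fs = _clip_cuts(fhr_bounds, fhr_states, t0, t1)
    ub, us = _clip_cuts(up_bounds, up_states, t0, t1)
    cuts = np.union1d(fb, ub)
    mids = cuts[:-1]
    fi = np.searchsorted(fb, mids, side="right") - 1
    ui = np.searchsorted(ub, mids, side="right") - 1
    return np.diff(cuts), fs[fi], us[ui]


def _encode_epoch_segments(
    dwells: np.ndarray, fhr_states: np.ndarray, up_states: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Excise invalid intervals and RLE the joint codes of each valid segment."""
    valid = (fhr_states != FHR_INVALID) & (up_states != UP_INVALID)
    codes = fhr_states.astype(np.int64) * 3 + up_states
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    n = len(dwells)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        s, d = _merge_same_state(codes[i:j].astype(np.int8), dwells[i:j].astype(np.int64))
        if len(s):
            segments.append((s, d))
        i = j
    return segments


def segment_epochs(
    record: BirthRecord,
    horizon_h: float = 12.0,
    epoch_min: float = EPOCH_MIN,
    min_valid: float = 0.8,
    heal_gaps: bool = True,
) -> list[Epoch]:
    """Tile valid 20-minute epochs backward from delivery.

    An epoch is retained only if the valid-sample fraction is at least
    ``min_valid`` (boundary inclusive) on *both* channels.  Labors shorter
    than one epoch yield an empty list.
    """
    if record.fhr_stream is None or record.up_stream is None:
        raise ValueError(f"birth {record.id} has no event streams")
    fhr, up = record.fhr_stream, record.up_stream
    if fhr.total_ticks != up.total_ticks:
        raise ValueError("channel durations differ")
    if heal_gaps:
        fhr = heal_short_dropouts(fhr)
        up = heal_short_dropouts(up)

    total = fhr.total_ticks
    epoch_ticks = int(round(epoch_min * 60 * TICKS_PER_S))
    max_epochs = int(round(horizon_h * 60 / epoch_min))
    n_epochs = min(max_epochs, total // epoch_ticks)
    fhr_bounds, up_bounds = _run_bounds(fhr), _run_bounds(up)

    epochs: list[Epoch] = []
    for k in range(n_epochs):
        t1 = total - k * epoch_ticks
        t0 = t1 - epoch_ticks
        dw, fs, us = _joint_intervals_from_bounds(
            fhr_bounds, fhr.states, up_bounds, up.states, t0, t1
        )
        vf_fhr = 1.0 - float(dw[fs == FHR_INVALID].sum()) / epoch_ticks
        vf_up = 1.0 - float(dw[us == UP_INVALID].sum()) / epoch_ticks
        vf = min(vf_fhr, vf_up)
        if vf_fhr < min_valid or vf_up < min_valid:
            continue
        segments = _encode_epoch_segments(dw, fs, us)
        epochs.append(
            Epoch(
                birth_id=record.id,
                index_from_delivery=k,
                start_min_before_delivery=(k + 1) * epoch_min,
                end_min_before_delivery=k * epoch_min,
                segments=segments,
                valid_fraction=vf,
                valid_fraction_fhr=vf_fhr,
                valid_fraction_up=vf_up,
            )
        )
    return epochs
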