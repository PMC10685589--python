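"""Shared fixtures: small synthetic cohorts and sample-level oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ctgds import CohortConfig, features_table, sample_cohort
from ctgds.cohort import EventStream, FHR_INVALID, UP_INVALID
from ctgds.io import births_frame
from ctgds.preprocessing import heal_short_dropouts

#: balanced tiny-cohort config for unit tests (unrealistic prevalences, kept
#: small so forests and splits have every stratum populated)
TINY = CohortConfig(
    n_births=100,
    group_probs=(0.6, 0.3, 0.1),
    duration_mean_multiparous_min=120.0,
    seed=424242,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    return sample_cohort(TINY)


@pytest.fixture(scope="session")
def tiny_births(tiny_cohort):
    return births_frame(tiny_cohort)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return features_table(tiny_cohort)


# ---------------------------------------------------------------------------
# sample-level (4 Hz tick walk) oracle for the run-length feature path
# ---------------------------------------------------------------------------

def expand_ticks(stream: EventStream) -> np.ndarray:
    """Per-tick state codes of a stream."""
    return np.repeat(stream.states, stream.dwells)


def oracle_epoch_features(fhr: EventStream, up: EventStream, t0: int, t1: int):
    """Walk the joint 4 Hz label sequence of window [t0, t1) sample by sample.

    Returns (transition_counts 12x12, visit counts, total dwell seconds)
    with invalid ticks excised and no transition counted across an excision
    or between non-adjacent ticks.
    """
    f = expand_ticks(fhr)[t0:t1]
    u = expand_ticks(up)[t0:t1]
    valid = (f != FHR_INVALID) & (u != UP_INVALID)
    codes = f.astype(int) * 3 + u.astype(int)
    trans = np.zeros((12, 12), dtype=int)
    visits = np.zeros(12, dtype=int)
    totals = np.zeros(12, dtype=float)
    prev_code = None  # None across excisions / at segment starts
    for i in range(len(codes)):
        if not valid[i]:
            prev_code = None
            continue
        c = codes[i]
        totals[c] += 0.25
        if prev_code is None or prev_code != c:
            visits[c] += 1
            if prev_code is not None:
                trans[prev_code, c] += 1
        prev_code = c
    return trans, visits, totals


def oracle_features_for_record(record, epoch):
    """Oracle features for one retained epoch of a record (healed streams)."""
    fhr = heal_short_dropouts(record.fhr_stream)
    up = heal_short_dropouts(record.up_stream)
    total = fhr.total_ticks
    t1 = total - epoch.index_from_delivery * 4800
    return oracle_epoch_features(fhr, up, t1 - 4800, t1)
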