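"""Synthetic labor cohort generator.

Emulates the structure of a large intrapartum cardiotocography (CTG) cohort:
three outcome groups (healthy, acidosis, HIE), a nulliparity label whose
prevalence rises with outcome severity, longer labors in nulliparous mothers,
group-dependent deceleration/contraction dynamics, signal dropouts, and
group-by-parity Caesarean delivery rates.

Event streams are generated as semi-Markov chains over labeled CTG event
states — fetal heart rate (FHR): baseline / acceleration / deceleration;
uterine pressure (UP): contraction / rest — with an elevated
deceleration-entry hazard during and shortly after contractions
(contraction-stress coupling). Dropouts are inserted as "invalid" runs.
All run boundaries live on a 0.25 s grid (the 4 Hz sample grid); UP run
boundaries are additionally rounded to whole seconds (its native 1 Hz grid).

The ``parity_dynamics_effect`` knob controls whether parity alters the
conditional law of the streams given labor duration.  At 0 (the default,
the physiological null) parity affects only prevalence, labor duration and
Caesarean rates; the state sequences are then bit-identical across parity
for a matched seed and duration.  At e > 0 the dynamics of nulliparous
births are shifted along the severity axis that separates the outcome
groups (deceleration-entry odds x(1+e), with matched shifts of baseline
dwell, contraction coupling and contraction frequency), injecting a
parity x dynamics interaction that a parity-blind classifier must
confound with outcome severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GROUPS = ("healthy", "acidosis", "hie")
PARITIES = ("nulliparous", "multiparous")

# FHR state codes
FHR_BASELINE, FHR_ACCEL, FHR_DECEL, FHR_INVALID = 0, 1, 2, 3
FHR_STATES = ("baseline", "acceleration", "deceleration", "invalid")
# UP state codes
UP_CONTRACTION, UP_REST, UP_INVALID = 0, 1, 2
UP_STATES = ("contraction", "rest", "invalid")

TICKS_PER_S = 4  # 4 Hz tick grid


class ConfigError(ValueError):
    """Raised for invalid cohort configuration."""


@dataclass(frozen=True)
class GroupDynamics:
    """Semi-Markov parameters of one outcome group.

    Dwells are gamma-distributed (shape 4) around the given means; the FHR
    transition matrix is over (baseline, acceleration, deceleration) with a
    zero diagonal; UP alternates contraction <-> rest.  ``coupling_odds``
    multiplies the deceleration-entry weight during a contraction and for
    ``coupling_lag_s`` afterwards.

    The numeric defaults per group (see :func:`default_dynamics`) are
    stand-ins: no quantitative per-group event dynamics are published for
    the cohort this generator emulates, only the event taxonomy.
    """

    fhr_mean_dwell_s: tuple[float, float, float]  # baseline, accel, decel
    fhr_transition: tuple[tuple[float, float, float], ...]
    up_mean_dwell_s: tuple[float, float]  # contraction, rest
    coupling_odds: float = 2.0
    coupling_lag_s: float = 60.0

    def validate(self) -> None:
        mat = np.asarray(self.fhr_transition, dtype=float)
        if mat.shape != (3, 3):
            raise ConfigError("fhr_transition must be 3x3")
        if np.any(np.diag(mat) != 0):
            raise ConfigError("self-transitions must have probability 0")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigError("fhr_transition rows must sum to 1")
        if np.any(mat < 0):
            raise ConfigError("negative transition probability")
        if min(self.fhr_mean_dwell_s) <= 0 or min(self.up_mean_dwell_s) <= 0:
            raise ConfigError("mean dwells must be positive")
        if self.coupling_odds < 1:
            raise ConfigError("coupling_odds must be >= 1")


def default_dynamics() -> dict[str, GroupDynamics]:
    """Stand-in per-group dynamics.

    Pathological groups enter decelerations more readily (shorter baselines,
    larger deceleration branch weight, stronger contraction coupling) and
    contract slightly more frequently.  Differences are concentrated on the
    deceleration side so that deceleration behaviour, not contraction timing,
    carries most of the outcome signal.
    """
    return {
        "healthy": GroupDynamics(
            fhr_mean_dwell_s=(150.0, 30.0, 50.0),
            fhr_transition=((0.0, 0.75, 0.25), (0.9, 0.0, 0.1), (1.0, 0.0, 0.0)),
            up_mean_dwell_s=(60.0, 120.0),
            coupling_odds=2.0,
        ),
        "acidosis": GroupDynamics(
            fhr_mean_dwell_s=(120.0, 30.0, 55.0),
            fhr_transition=((0.0, 0.55, 0.45), (0.9, 0.0, 0.1), (1.0, 0.0, 0.0)),
            up_mean_dwell_s=(60.0, 110.0),
            coupling_odds=3.0,
        ),
        "hie": GroupDynamics(
            fhr_mean_dwell_s=(100.0, 30.0, 60.0),
            fhr_transition=((0.0, 0.40, 0.60), (0.85, 0.0, 0.15), (1.0, 0.0, 0.0)),
            up_mean_dwell_s=(60.0, 105.0),
            coupling_odds=4.0,
        ),
    }


# Reference-cohort group sizes (healthy, acidosis, HIE) used for the default
# prevalences, and per-group nulliparity proportions from the same cohort.
_REF_GROUP_COUNTS = (37546, 3056, 374)
_REF_NULLIPARITY = (0.578, 0.645, 0.668)
# Caesarean delivery rates by group (rows) and parity (nulliparous,
# multiparous), from the reference cohort.
_REF_CAESAREAN = ((0.416, 0.354), (0.345, 0.430), (0.516, 0.636))


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic cohort draw."""

    n_births: int = 1000
    group_probs: tuple[float, float, float] = tuple(
        c / sum(_REF_GROUP_COUNTS) for c in _REF_GROUP_COUNTS
    )
    nulliparity_prob_by_group: tuple[float, float, float] = _REF_NULLIPARITY
    duration_mean_multiparous_min: float = 360.0
    nulliparous_duration_multiplier: float = 1.4
    duration_sigma_log: float = 0.35
    duration_min_floor: float = 30.0
    duration_min_ceil: float = 900.0
    dynamics: dict[str, GroupDynamics] = field(default_factory=default_dynamics)
    parity_dynamics_effect: float = 0.0
    caesarean_rate_by_group_parity: tuple[tuple[float, float], ...] = _REF_CAESAREAN
    dropout_rate: float = 0.06
    dropout_mean_len_s: float = 45.0
    #: sd (log scale) of the per-birth random effects on the
    #: group-distinguishing dynamics parameters, emulating within-group
    #: physiological variability; 0 = homogeneous groups (which would make
    #: the outcome groups near-perfectly separable, unlike real CTG)
    birth_heterogeneity_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_births <= 0:
            raise ConfigError("n_births must be positive")
        gp = np.asarray(self.group_probs, dtype=float)
        if gp.shape != (3,) or np.any(gp < 0) or abs(gp.sum() - 1.0) > 1e-12:
            raise ConfigError("group_probs must be 3 non-negative values summing to 1")
        npg = np.asarray(self.nulliparity_prob_by_group, dtype=float)
        if npg.shape != (3,) or np.any((npg < 0) | (npg > 1)):
            raise ConfigError("nulliparity_prob_by_group must be 3 probabilities")
        if self.nulliparous_duration_multiplier < 1:
            raise ConfigError("nulliparous_duration_multiplier must be >= 1")
        if self.parity_dynamics_effect < 0:
            raise ConfigError("parity_dynamics_effect must be >= 0")
        cs = np.asarray(self.caesarean_rate_by_group_parity, dtype=float)
        if cs.shape != (3, 2) or np.any((cs < 0) | (cs > 1)):
            raise ConfigError("caesarean_rate_by_group_parity must be 3x2 probabilities")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.birth_heterogeneity_sigma < 0:
            raise ConfigError("birth_heterogeneity_sigma must be >= 0")
        for g in GROUPS:
            if g not in self.dynamics:
                raise ConfigError(f"missing dynamics for group {g!r}")
            self.dynamics[g].validate()


@dataclass
class EventStream:
    """Run-length-encoded labeled event stream on the 4 Hz tick grid.

    ``states`` are channel state codes, ``dwells`` tick counts.  Runs are
    contiguous, cover [0, duration], consecutive states are distinct and all
    dwells are positive.
    """

    channel: str  # "fhr" or "up"
    states: np.ndarray  # int8 codes
    dwells: np.ndarray  # int64 ticks

    @property
    def total_ticks(self) -> int:
        return int(self.dwells.sum())

    @property
    def duration_s(self) -> float:
        return self.total_ticks / TICKS_PER_S

    def runs(self) -> list[tuple[str, float, float]]:
        """Runs as (state_label, start_s, dwell_s)."""
        labels = FHR_STATES if self.channel == "fhr" else UP_STATES
        starts = np.concatenate(([0], np.cumsum(self.dwells)[:-1]))
        return [
            (labels[s], st / TICKS_PER_S, d / TICKS_PER_S)
            for s, st, d in zip(self.states, starts, self.dwells)
        ]

    def invalid_code(self) -> int:
        return FHR_INVALID if self.channel == "fhr" else UP_INVALID

    def validate(self) -> None:
        if len(self.states) != len(self.dwells):
            raise ValueError("states/dwells length mismatch")
        if np.any(self.dwells <= 0):
            raise ValueError("non-positive dwell")
        if np.any(self.states[1:] == self.states[:-1]):
            raise ValueError("consecutive runs share a state")


@dataclass
class BirthRecord:
    """One delivery: labels plus the two event streams (delivery at t=end)."""

    id: str
    group: str
    parity: str
    caesarean: bool
    duration_min: float
    fhr_stream: EventStream | None = None
    up_stream: EventStream | None = None


def _merge_same_state(states: np.ndarray, dwells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent runs with identical state; drop zero dwells."""
    keep = dwells > 0
    states, dwells = states[keep], dwells[keep]
    if len(states) == 0:
        return states, dwells
    new = np.concatenate(([True], states[1:] != states[:-1]))
    idx = np.cumsum(new) - 1
    out_states = states[new]
    out_dwells = np.zeros(len(out_states), dtype=np.int64)
    np.add.at(out_dwells, idx, dwells)
    return out_states, out_dwells


def _gamma_dwell_ticks(rng: np.random.Generator, mean_s: float, grid_ticks: int) -> int:
    """Gamma(shape 4) dwell rounded to the channel grid, at least one cell."""
    d = rng.gamma(4.0, mean_s / 4.0) * TICKS_PER_S
    return max(grid_ticks, int(round(d / grid_ticks)) * grid_ticks)


def _simulate_up(rng: np.random.Generator, dyn: GroupDynamics, total_ticks: int) -> EventStream:
    states: list[int] = []
    dwells: list[int] = []
    # random initial phase, start in rest or contraction proportional to dwell
    p_rest = dyn.up_mean_dwell_s[1] / sum(dyn.up_mean_dwell_s)
    state = UP_REST if rng.random() < p_rest else UP_CONTRACTION
    t = 0
    while t < total_ticks:
        mean = dyn.up_mean_dwell_s[0] if state == UP_CONTRACTION else dyn.up_mean_dwell_s[1]
        d = _gamma_dwell_ticks(rng, mean, TICKS_PER_S)  # 1 s grid
        d = min(d, total_ticks - t)
        states.append(state)
        dwells.append(d)
        t += d
        state = UP_REST if state == UP_CONTRACTION else UP_CONTRACTION
    s, d = _merge_same_state(np.array(states, dtype=np.int8), np.array(dwells, dtype=np.int64))
    return EventStream("up", s, d)


def _coupled_windows(up: EventStream, lag_ticks: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open tick intervals [start, end) during/after contractions."""
    starts = np.concatenate(([0], np.cumsum(up.dwells)[:-1]))
    mask = up.states == UP_CONTRACTION
    ws = starts[mask]
    we = np.minimum(starts[mask] + up.dwells[mask] + lag_ticks, up.total_ticks)
    return ws, we


def _simulate_fhr(
    rng: np.random.Generator,
    dyn: GroupDynamics,
    total_ticks: int,
    up: EventStream,
    decel_odds_multiplier: float,
) -> EventStream:
    ws, we = _coupled_windows(up, int(round(dyn.coupling_lag_s * TICKS_PER_S)))
    trans = np.asarray(dyn.fhr_transition, dtype=float)

    states: list[int] = []
    dwells: list[int] = []
    state = FHR_BASELINE
    t = 0
    while t < total_ticks:
        mean = dyn.fhr_mean_dwell_s[state]
        d = _gamma_dwell_ticks(rng, mean, 1)  # 0.25 s grid
        d = min(d, total_ticks - t)
        states.append(state)
        dwells.append(d)
        t += d
        if t >= total_ticks:
            break
        # next state: tilt the deceleration weight by parity effect and,
        # inside a contraction window, by the coupling odds
        w = trans[state].copy()
        mult = decel_odds_multiplier
        i = np.searchsorted(ws, t, side="right") - 1
        if i >= 0 and t < we[i]:
            mult *= dyn.coupling_odds
        w[FHR_DECEL] *= mult
        u = rng.random() * w.sum()
        state = 0 if u < w[0] else (1 if u < w[0] + w[1] else 2)
    s, d = _merge_same_state(np.array(states, dtype=np.int8), np.array(dwells, dtype=np.int64))
    return EventStream("fhr", s, d)


def _insert_dropouts(
    stream: EventStream, rng: np.random.Generator, rate: float, mean_len_s: float
) -> EventStream:
    """Overlay i.i.d. exponential-length invalid runs at the configured rate."""
    if rate <= 0:
        return stream
    total = stream.total_ticks
    mean_len_ticks = mean_len_s * TICKS_PER_S
    n = rng.poisson(rate * total / mean_len_ticks)
    if n == 0:
        return stream
    starts = np.sort(rng.integers(0, total, size=n))
    lens = np.maximum(1, np.round(rng.exponential(mean_len_ticks, size=n))).astype(np.int64)
    ends = np.minimum(starts + lens, total)
    # merge overlapping dropout intervals
    merged_s, merged_e = [int(starts[0])], [int(ends[0])]
    for s0, e0 in zip(starts[1:], ends[1:]):
        if s0 <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], int(e0))
        else:
            merged_s.append(int(s0))
            merged_e.append(int(e0))
    starts = np.array(merged_s, dtype=np.int64)
    ends = np.array(merged_e, dtype=np.int64)
    n = len(starts)

    inv = stream.invalid_code()
    bounds = np.concatenate(([0], np.cumsum(stream.dwells)))
    cuts = np.unique(np.concatenate((bounds, starts, ends)))
    seg_starts = cuts[:-1]
    seg_dwells = np.diff(cuts)
    base_idx = np.searchsorted(bounds, seg_starts, side="right") - 1
    seg_states = stream.states[base_idx].copy()
    # mark segments inside any dropout interval as invalid
    j = np.searchsorted(starts, seg_starts, side="right") - 1
    hit = (j >= 0) & (seg_starts < ends[np.clip(j, 0, n - 1)])
    seg_states[hit] = inv
    s, d = _merge_same_state(seg_states.astype(np.int8), seg_dwells)
    return EventStream(stream.channel, s, d)


# Exponents mapping the parity-interaction strength onto each dynamics
# parameter, so the injected effect moves nulliparous births along the same
# severity axis that separates the outcome groups (at (1+e) = 4 the healthy
# dynamics land on the HIE defaults: baseline 150 -> ~100 s, coupling 2 -> 4,
# rest 120 -> ~105 s, deceleration-entry odds x4).  A deceleration-only
# effect would leave parity-independent side channels (baseline dwell,
# coupling) by which a parity-blind classifier could still separate the
# groups, and would not constitute a parity x dynamics confound.
_PARITY_BASE_DWELL_EXP = -0.3
_PARITY_COUPLING_EXP = 0.5
_PARITY_REST_EXP = -0.1


def _apply_parity_effect(dyn: GroupDynamics, parity: str, effect: float) -> tuple[GroupDynamics, float]:
    """Severity-axis shift of nulliparous dynamics; returns (dynamics,
    deceleration odds multiplier)."""
    if parity != "nulliparous" or effect <= 0:
        return dyn, 1.0
    m = 1.0 + effect
    b, a, d = dyn.fhr_mean_dwell_s
    c, r = dyn.up_mean_dwell_s
    shifted = replace(
        dyn,
        fhr_mean_dwell_s=(b * m**_PARITY_BASE_DWELL_EXP, a, d),
        up_mean_dwell_s=(c, r * m**_PARITY_REST_EXP),
        coupling_odds=dyn.coupling_odds * m**_PARITY_COUPLING_EXP,
    )
    return shifted, m


def simulate_labor(
    group: str,
    parity: str,
    duration_min: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[EventStream, EventStream]:
    """Simulate the (FHR, UP) event streams of one labor of known duration.

    With ``parity_dynamics_effect == 0`` the draw is identical across parity
    for a matched generator state and duration.
    """
    if group not in GROUPS:
        raise ConfigError(f"unknown group {group!r}")
    if parity not in PARITIES:
        raise ConfigError(f"unknown parity {parity!r}")
    dyn = config.dynamics[group]
    total_ticks = int(round(duration_min * 60)) * TICKS_PER_S
    # Per-birth random effects on every group-distinguishing dynamics
    # parameter (within-group physiological variability; without it the
    # groups would be near-perfectly separable).  Drawn before parity
    # enters, so the e=0 matched-seed parity invariance is preserved.
    sigma = config.birth_heterogeneity_sigma
    hetero_decel = 1.0
    if sigma > 0:
        hetero_decel = float(rng.lognormal(-sigma**2 / 2.0, sigma))
        coupling_pow = float(np.exp(rng.normal(0.0, 0.5 * sigma)))
        rest_mult = float(rng.lognormal(0.0, 0.3 * sigma))
        base_mult = float(rng.lognormal(0.0, 0.3 * sigma))
        b, a, d = dyn.fhr_mean_dwell_s
        c, r = dyn.up_mean_dwell_s
        dyn = replace(
            dyn,
            fhr_mean_dwell_s=(b * base_mult, a, d),
            up_mean_dwell_s=(c, r * rest_mult),
            coupling_odds=dyn.coupling_odds**coupling_pow,
        )
    dyn, parity_decel_mult = _apply_parity_effect(
        dyn, parity, config.parity_dynamics_effect
    )
    up = _simulate_up(rng, dyn, total_ticks)
    fhr = _simulate_fhr(rng, dyn, total_ticks, up, hetero_decel * parity_decel_mult)
    fhr = _insert_dropouts(fhr, rng, config.dropout_rate, config.dropout_mean_len_s)
    up = _insert_dropouts(up, rng, config.dropout_rate, config.dropout_mean_len_s)
    return fhr, up


def assign_caesarean(record: BirthRecord, config: CohortConfig, rng: np.random.Generator) -> bool:
    """Bernoulli Caesarean-delivery draw at the configured group x parity rate."""
    g = GROUPS.index(record.group)
    p = PARITIES.index(record.parity)
    rate = config.caesarean_rate_by_group_parity[g][p]
    return bool(rng.random() < rate)


def _draw_duration(parity: str, config: CohortConfig, rng: np.random.Generator) -> float:
    mean = config.duration_mean_multiparous_min
    if parity == "nulliparous":
        mean *= config.nulliparous_duration_multiplier
    sigma = config.duration_sigma_log
    mu = np.log(mean) - sigma**2 / 2.0
    d = float(rng.lognormal(mu, sigma))
    d = min(max(d, config.duration_min_floor), config.duration_min_ceil)
    return round(d * 60) / 60.0  # whole seconds


def sample_cohort(config: CohortConfig, with_streams: bool = True) -> list[BirthRecord]:
    """Draw a full labeled cohort; identical config => bit-identical cohort.

    ``with_streams=False`` skips event-stream simulation (labels and
    durations only), for label-level statistics at large n.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_births
    groups = label_rng.choice(3, size=n, p=np.asarray(config.group_probs, dtype=float))
    np_probs = np.asarray(config.nulliparity_prob_by_group, dtype=float)[groups]
    nulli = label_rng.random(n) < np_probs
    birth_seeds = ss.spawn(n)

    records: list[BirthRecord] = []
    width = max(6, len(str(n)))
    for i in range(n):
        rng = np.random.default_rng(birth_seeds[i])
        group = GROUPS[groups[i]]
        parity = "nulliparous" if nulli[i] else "multiparous"
        duration = _draw_duration(parity, config, rng)
        rec = BirthRecord(
            id=f"b{i:0{width}d}", group=group, parity=parity,
            caesarean=False, duration_min=duration,
        )
        rec.caesarean = assign_caesarean(rec, config, rng)
        if with_streams:
            rec.fhr_stream, rec.up_stream = simulate_labor(group, parity, duration, config, rng)
        records.append(rec)
    return records


def with_positive_parity_effect(config: CohortConfig, effect: float = 3.0) -> CohortConfig:
    """Config variant injecting a parity x dynamics interaction.

    The default effect size shifts nulliparous-healthy dynamics onto the
    multiparous-HIE defaults along every group-distinguishing parameter,
    so that a parity-blind classifier must confuse the two strata while a
    parity-routed classifier separates each cleanly.
    """
    return replace(config, parity_dynamics_effect=effect)
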