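"""Synthetic MATB-II-like cohorts with known gaze-transition structure.

The generator emulates the statistical skeleton the entropy analysis
assumes: a 2 (communication frequency, between) x 2 (tracking difficulty,
within) design, two 20-minute trials per participant, gaze over three task
AOIs (1 = tracking, 2 = system monitoring, 3 = communication) following a
first-order Markov chain whose transition matrix differs by design cell,
log-normal dwell durations, occasional off-AOI fixations, monitoring-aid
alert schedules (28 Hits + 12 false alarms, i.e. a 70%-reliable aid) and
auditory communication events (16 vs 4 per trial) that pull gaze to the
communication panel.

Default cell matrices are zero-diagonal (one fixation per AOI visit, so the
chain is its own collapsed sequence) and were solved so their analytic
normalized GTE is 0.245 / 0.215 / 0.200 / 0.170 for the Easy-High /
Easy-Low / Difficult-High / Difficult-Low cells: harder tracking and fewer
interruptions both make scanning more stereotyped, and the Easy > Difficult,
High > Low orderings hold for SGE as well. For a zero-diagonal 3-state chain
the stationary mass of any single AOI cannot exceed 1/2, which bounds
normalized SGE below by ~0.63; the defaults sit on the feasible boundary
(analytic normalized SGE 0.756-0.720 across cells).

All randomness flows from a single cohort seed through
``numpy.random.SeedSequence`` substreams (one per participant, then per
trial), so any trial is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ScheduleError, ValidationError
from .io import AOIRegion, Fixation, TrialRecord

DIFFICULTY_LEVELS = ("Easy", "Difficult")
COMM_LEVELS = ("High", "Low")
CELLS = tuple((d, c) for d in DIFFICULTY_LEVELS for c in COMM_LEVELS)

#: three-AOI layout mimicking the MATB-II panel arrangement on a 1920x1080
#: canvas: tracking top-center, system monitoring left, communication
#: lower-left
DEFAULT_LAYOUT: tuple[AOIRegion, ...] = (
    AOIRegion(1, "tracking", 640.0, 60.0, 1280.0, 560.0),
    AOIRegion(2, "system_monitoring", 60.0, 60.0, 560.0, 560.0),
    AOIRegion(3, "communication", 60.0, 620.0, 560.0, 1000.0),
)


def _cell_matrix(a: float, b: float) -> np.ndarray:
    return np.array(
        [
            [0.0, 1.0 - a, a],
            [1.0 - b, 0.0, b],
            [1.0 - a, a, 0.0],
        ]
    )


#: per-cell transition matrices; (a, b) solved so analytic normalized GTE is
#: 0.245 / 0.215 / 0.200 / 0.170 (see module docstring)
DEFAULT_CELL_MATRICES: dict[tuple[str, str], np.ndarray] = {
    ("Easy", "High"): _cell_matrix(0.044898, 0.035918),
    ("Easy", "Low"): _cell_matrix(0.037852, 0.030282),
    ("Difficult", "High"): _cell_matrix(0.034470, 0.027576),
    ("Difficult", "Low"): _cell_matrix(0.027991, 0.022393),
}


@dataclass(frozen=True)
class CohortDesign:
    """The 2x2 mixed design and per-trial event composition."""

    n_participants: int = 40
    trial_length_s: float = 1200.0
    n_comm_messages: Mapping[str, int] = field(
        default_factory=lambda: {"High": 16, "Low": 4}
    )
    n_hit_events: int = 28
    n_fa_events: int = 12
    tracking_forcing_hz: Mapping[str, float] = field(
        default_factory=lambda: {"Easy": 0.06, "Difficult": 0.12}
    )
    alert_min_separation_s: float = 5.0
    comm_min_separation_s: float = 30.0
    seed: int = 0

    @property
    def aid_reliability(self) -> float:
        """Fraction of aid alerts that are Hits (the aid's reliability)."""
        return self.n_hit_events / (self.n_hit_events + self.n_fa_events)

    def group_sizes(self) -> dict[str, int]:
        """Participants per between-level, split as evenly as possible."""
        high = (self.n_participants + 1) // 2
        return {"High": high, "Low": self.n_participants - high}


@dataclass
class GenerativeParams:
    """Generative knobs for scanpath simulation.

    ``cell_matrices`` maps (difficulty, comm_frequency) to a zero-diagonal
    row-stochastic 3x3 matrix. Dwell durations are log-normal
    (median ``dwell_median_ms``, log-sd ``dwell_sigma_log``); off-AOI
    fixations are *inserted* between AOI visits at rate ``offaoi_rate`` so
    the drop-then-collapse pipeline recovers the underlying visit chain
    exactly. ``participant_logit_sd`` is the sd of per-participant
    logit-normal offsets on transition probabilities (a random intercept
    shared by both of a participant's trials).
    """

    cell_matrices: dict[tuple[str, str], np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_CELL_MATRICES.items()}
    )
    dwell_median_ms: float = 400.0
    dwell_sigma_log: float = 0.5
    saccade_gap_ms: float = 30.0
    offaoi_rate: float = 0.02
    offaoi_dwell_median_ms: float = 150.0
    error_rate_mean: float = 0.12
    error_rate_sd: float = 0.08
    participant_logit_sd: float = 0.30
    canvas_px: tuple[int, int] = (1920, 1080)
    comm_pull_window_s: float = 2.0

    def __post_init__(self) -> None:
        if self.dwell_median_ms <= 0 or self.dwell_sigma_log <= 0:
            raise ValidationError("dwell parameters must be positive")
        if not 0 <= self.offaoi_rate < 1:
            raise ValidationError("offaoi_rate must be in [0, 1)")
        for cell, P in self.cell_matrices.items():
            validate_transition_matrix(np.asarray(P, dtype=float), cell)


def validate_transition_matrix(P: np.ndarray, cell=None) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    tag = f" for cell {cell}" if cell else ""
    if P.shape != (3, 3):
        raise ValidationError(f"transition matrix{tag} must be 3x3")
    if np.any(np.diag(P) != 0):
        raise ValidationError(f"transition matrix{tag} must have a zero diagonal")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError(f"rows of transition matrix{tag} must sum to 1")
    return P


@dataclass(frozen=True, slots=True)
class TrialSchedule:
    """Event timeline of one trial (times in seconds from trial start)."""

    alert_events: tuple[tuple[float, str], ...]
    comm_events: tuple[float, ...]
    trial_length_s: float


def _spaced_times(
    rng: np.random.Generator, n: int, length_s: float, min_sep_s: float
) -> np.ndarray:
    """n sorted uniform-random times in [0, length_s) with pairwise gaps
    >= min_sep_s (uniform over the set of valid configurations)."""
    if n == 0:
        return np.empty(0)
    slack = length_s - (n - 1) * min_sep_s
    if slack <= 0:
        raise ScheduleError(
            f"cannot place {n} events {min_sep_s} s apart in {length_s} s; "
            "reduce the count or the separation"
        )
    base = np.sort(rng.uniform(0.0, slack, size=n))
    return base + min_sep_s * np.arange(n)


def generate_schedule(
    design: CohortDesign, cell: tuple[str, str], seed: int | np.random.SeedSequence
) -> TrialSchedule:
    """Alert and communication event times for one trial of a design cell."""
    difficulty, comm = cell
    if comm not in design.n_comm_messages:
        raise ValidationError(f"unknown communication level {comm!r}")
    rng = np.random.default_rng(seed)
    n_alerts = design.n_hit_events + design.n_fa_events
    alert_times = _spaced_times(
        rng, n_alerts, design.trial_length_s, design.alert_min_separation_s
    )
    kinds = np.array(["Hit"] * design.n_hit_events + ["FA"] * design.n_fa_events)
    rng.shuffle(kinds)
    comm_times = _spaced_times(
        rng,
        design.n_comm_messages[comm],
        design.trial_length_s,
        design.comm_min_separation_s,
    )
    return TrialSchedule(
        alert_events=tuple(zip(alert_times.tolist(), kinds.tolist())),
        comm_events=tuple(comm_times.tolist()),
        trial_length_s=design.trial_length_s,
    )


def simulate_markov_states(
    P: np.ndarray, n_steps: int, rng: np.random.Generator, init: int | None = None
) -> np.ndarray:
    """Sample a state path (1-based AOI ids) of length n_steps from chain P."""
    from .entropy import stationary_distribution

    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    pi = stationary_distribution(P)
    s = int(rng.choice(k, p=pi)) if init is None else int(init) - 1
    # presample, per step, the would-be successor from every source state;
    # the sequential pass then only chains the lookups
    u = rng.random(n_steps - 1)
    cum = np.cumsum(P, axis=1)
    next_if = np.stack([np.searchsorted(cum[i], u, side="right") for i in range(k)])
    np.clip(next_if, 0, k - 1, out=next_if)
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = s
    for t in range(n_steps - 1):
        s = next_if[s, t]
        states[t + 1] = s
    return states + 1


def _offaoi_point(rng: np.random.Generator, layout, canvas) -> tuple[float, float]:
    w, h = canvas
    for _ in range(1000):
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        if not any(r.contains(x, y) for r in layout):
            return x, y
    raise ValidationError("AOI layout covers the canvas; cannot place off-AOI point")


def simulate_scanpath(
    params: GenerativeParams,
    cell: tuple[str, str],
    schedule: TrialSchedule,
    seed: int | np.random.SeedSequence,
    P: np.ndarray | None = None,
    layout: Sequence[AOIRegion] = DEFAULT_LAYOUT,
    participant_id: str = "P000",
    trial_id: str = "T1",
) -> TrialRecord:
    """One trial's fixation stream from the cell's (or supplied) chain.

    AOI visits follow the Markov chain; each visit is one fixation uniform
    inside its AOI rectangle with a log-normal dwell. Each communication
    event pulls the first fixation starting within ``comm_pull_window_s``
    onto the communication AOI (id 3). Off-AOI fixations are inserted at
    ``offaoi_rate``.
    """
    difficulty, comm = cell
    P = validate_transition_matrix(
        params.cell_matrices[(difficulty, comm)] if P is None else P, cell
    )
    rng = np.random.default_rng(seed)
    T_ms = schedule.trial_length_s * 1000.0
    mean_dwell = params.dwell_median_ms * np.exp(params.dwell_sigma_log**2 / 2)
    per_visit = (mean_dwell + params.saccade_gap_ms) * (1 + params.offaoi_rate)
    n_est = int(T_ms / per_visit * 1.25) + 20

    states = simulate_markov_states(P, n_est, rng)
    durations = rng.lognormal(np.log(params.dwell_median_ms), params.dwell_sigma_log, n_est)

    # insert off-AOI fixations between visits
    if params.offaoi_rate > 0:
        ins = rng.random(n_est) < params.offaoi_rate
        idx = np.flatnonzero(ins)
        off_dur = rng.lognormal(
            np.log(params.offaoi_dwell_median_ms), params.dwell_sigma_log, len(idx)
        )
        states = np.insert(states, idx + 1, 0)
        durations = np.insert(durations, idx + 1, off_dur)

    onsets = np.concatenate(
        [[0.0], np.cumsum(durations + params.saccade_gap_ms)[:-1]]
    )
    keep = onsets + durations <= T_ms
    states, durations, onsets = states[keep], durations[keep], onsets[keep]

    # communication events pull gaze to the communication panel
    for t_ev in schedule.comm_events:
        t0, t1 = t_ev * 1000.0, (t_ev + params.comm_pull_window_s) * 1000.0
        cand = np.flatnonzero((onsets >= t0) & (onsets < t1) & (states > 0))
        if len(cand):
            states[cand[0]] = 3

    regions = {r.aoi_id: r for r in layout}
    xs = np.empty(len(states))
    ys = np.empty(len(states))
    for aoi_id, r in regions.items():
        sel = states == aoi_id
        m = int(sel.sum())
        xs[sel] = rng.uniform(r.x_min, r.x_max, m)
        ys[sel] = rng.uniform(r.y_min, r.y_max, m)
    off = np.flatnonzero(states == 0)
    for k in off:
        xs[k], ys[k] = _offaoi_point(rng, layout, params.canvas_px)

    fixations = [
        Fixation(onset_ms=float(o), duration_ms=float(d), x_px=float(x), y_px=float(y))
        for o, d, x, y in zip(onsets, durations, xs, ys)
    ]
    return TrialRecord(
        participant_id=participant_id,
        trial_id=trial_id,
        difficulty=difficulty,
        comm_frequency=comm,
        fixations=fixations,
        trial_length_s=schedule.trial_length_s,
    )


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _jitter_matrix(P: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Apply per-row logit offsets to the first off-diagonal entry of each
    row (the complement adjusts), keeping rows stochastic and the diagonal 0."""
    P = np.asarray(P, dtype=float).copy()
    n = P.shape[0]
    for i in range(n):
        cols = [j for j in range(n) if j != i]
        p = P[i, cols[0]]
        if p <= 0 or p >= 1:  # degenerate rows stay fixed
            continue
        p_new = 1.0 / (1.0 + np.exp(-(_logit(np.array(p)) + offsets[i])))
        P[i, cols[0]] = p_new
        P[i, cols[1]] = 1.0 - p_new
    return P


def _beta_error_rate(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Moment-matched Beta draw, clipped away from impossible variances."""
    var = min(sd**2, mean * (1 - mean) * 0.95)
    nu = mean * (1 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def generate_cohort(
    design: CohortDesign,
    params: GenerativeParams | None = None,
    force_exclusion: bool = True,
    layout: Sequence[AOIRegion] = DEFAULT_LAYOUT,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Generate a full cohort: two trials per participant plus a participant
    table with monitoring error rates.

    With ``force_exclusion`` one random participant's monitoring error rate
    is drawn above 0.5, exercising the screening rule (so a default 40-person
    cohort analyzes as 39). Identical design+params+seed give bit-identical
    cohorts.
    """
    params = params or GenerativeParams()
    root = np.random.SeedSequence(design.seed)
    assign_ss, exclude_ss, *participant_ss = root.spawn(2 + design.n_participants)

    sizes = design.group_sizes()
    groups = np.array(["High"] * sizes["High"] + ["Low"] * sizes["Low"])
    np.random.default_rng(assign_ss).shuffle(groups)
    forced = (
        int(np.random.default_rng(exclude_ss).integers(design.n_participants))
        if force_exclusion
        else -1
    )

    trials: list[TrialRecord] = []
    rows = []
    for i, (comm, ss) in enumerate(zip(groups, participant_ss)):
        pid = f"P{i + 1:03d}"
        meta_ss, *trial_ss = ss.spawn(3)
        meta_rng = np.random.default_rng(meta_ss)
        offsets = meta_rng.normal(0.0, params.participant_logit_sd, size=3)
        order = list(DIFFICULTY_LEVELS)
        if meta_rng.random() < 0.5:
            order.reverse()
        if i == forced:
            err = float(meta_rng.uniform(0.55, 0.85))
        else:
            err = _beta_error_rate(meta_rng, params.error_rate_mean, params.error_rate_sd)
        rows.append(
            {
                "participant_id": pid,
                "comm_frequency": comm,
                "monitoring_error_rate": err,
            }
        )
        for t, (difficulty, t_ss) in enumerate(zip(order, trial_ss), start=1):
            sched_ss, path_ss = t_ss.spawn(2)
            cell = (difficulty, comm)
            schedule = generate_schedule(design, cell, sched_ss)
            P_part = _jitter_matrix(params.cell_matrices[cell], offsets)
            trials.append(
                simulate_scanpath(
                    params,
                    cell,
                    schedule,
                    path_ss,
                    P=P_part,
                    layout=layout,
                    participant_id=pid,
                    trial_id=f"T{t}",
                )
            )
    return trials, pd.DataFrame(rows)
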