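"""From fixation streams to AOI symbol sequences.

The analysis alphabet is the set of AOI ids; fixations landing outside every
AOI map to the sentinel :data:`OFF_AOI`. Two post-processing choices matter
downstream and are explicit here:

* ``offaoi_policy`` — ``"drop"`` removes off-AOI fixations (they are counted,
  not silently lost) so the alphabet stays the task AOIs, as in a three-state
  transition matrix; ``"keep_as_aoi"`` retains them as an extra state.
* ``collapse`` — merges runs of consecutive same-AOI fixations into single
  dwells, which removes self-transitions from the chain. Dropping happens
  before collapsing by default, so an off-AOI interruption inside one task
  region does not manufacture a self-transition.

An optional dispersion-threshold (I-DT) detector is provided for raw gaze
samples; fixation-level input never passes through it implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import EmptySequenceError, ValidationError
from .io import AOIRegion, Fixation, TrialRecord

#: sentinel symbol for fixations outside every AOI (never a chain state
#: under the default "drop" policy)
OFF_AOI: int = 0

#: I-DT defaults; stated defaults only, applied only when the caller invokes
#: the detector explicitly
IDT_DISPERSION_PX: float = 50.0
IDT_MIN_DURATION_MS: float = 100.0


@dataclass(frozen=True, slots=True)
class RawGazeSample:
    """One raw gaze sample (upstream of fixation detection)."""

    t_ms: float
    x_px: float
    y_px: float
    valid: bool = True


@dataclass(slots=True)
class AOISequence:
    """The AOI symbol sequence of one trial, with per-symbol dwell times."""

    participant_id: str
    trial_id: str
    symbols: np.ndarray  # int array of aoi_ids
    dwell_durations_ms: np.ndarray  # float array, same length
    n_dropped_offaoi: int = 0

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        self.dwell_durations_ms = np.asarray(self.dwell_durations_ms, dtype=float)
        if self.symbols.shape != self.dwell_durations_ms.shape:
            raise ValidationError("symbols and dwell_durations_ms must have equal length")

    def __len__(self) -> int:
        return len(self.symbols)


def assign_aoi(fixation: Fixation, layout: Sequence[AOIRegion]) -> int:
    """Return the id of the unique AOI containing the fixation, else OFF_AOI."""
    for r in layout:
        if r.contains(fixation.x_px, fixation.y_px):
            return r.aoi_id
    return OFF_AOI


def assign_aoi_array(
    x: np.ndarray, y: np.ndarray, layout: Sequence[AOIRegion]
) -> np.ndarray:
    """Vectorized AOI assignment for arrays of coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(x.shape, OFF_AOI, dtype=np.int64)
    for r in layout:
        inside = (r.x_min <= x) & (x < r.x_max) & (r.y_min <= y) & (y < r.y_max)
        out[inside] = r.aoi_id
    return out


def collapse_runs(
    symbols: np.ndarray, durations: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge runs of identical consecutive symbols, summing their durations."""
    symbols = np.asarray(symbols)
    durations = np.asarray(durations, dtype=float)
    if len(symbols) == 0:
        return symbols, durations
    starts = np.flatnonzero(np.r_[True, symbols[1:] != symbols[:-1]])
    sums = np.add.reduceat(durations, starts)
    return symbols[starts], sums


def build_sequence(
    trial: TrialRecord,
    layout: Sequence[AOIRegion],
    offaoi_policy: str = "drop",
    collapse: bool = True,
    drop_before_collapse: bool = True,
) -> AOISequence:
    """Map a trial's fixations to an AOI symbol sequence.

    With ``offaoi_policy="drop"`` off-AOI fixations are removed (and counted
    in ``n_dropped_offaoi``); ``"keep_as_aoi"`` keeps them as symbol
    ``OFF_AOI``. ``drop_before_collapse=False`` reverses the default order
    for sensitivity analyses.
    """
    if offaoi_policy not in ("drop", "keep_as_aoi"):
        raise ValidationError(f"unknown offaoi_policy {offaoi_policy!r}")
    if not trial.fixations:
        raise EmptySequenceError(
            f"trial {trial.participant_id}/{trial.trial_id} has no fixations"
        )
    x = np.array([f.x_px for f in trial.fixations])
    y = np.array([f.y_px for f in trial.fixations])
    durations = np.array([f.duration_ms for f in trial.fixations])
    symbols = assign_aoi_array(x, y, layout)

    n_dropped = 0

    def drop(sym: np.ndarray, dur: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nonlocal n_dropped
        keep = sym != OFF_AOI
        n_dropped += int((~keep).sum())
        return sym[keep], dur[keep]

    if offaoi_policy == "drop" and drop_before_collapse:
        symbols, durations = drop(symbols, durations)
    if collapse:
        symbols, durations = collapse_runs(symbols, durations)
    if offaoi_policy == "drop" and not drop_before_collapse:
        symbols, durations = drop(symbols, durations)
        if collapse:  # dropping may have created new adjacent duplicates
            symbols, durations = collapse_runs(symbols, durations)

    if len(symbols) == 0:
        raise EmptySequenceError(
            f"trial {trial.participant_id}/{trial.trial_id}: all fixations off-AOI"
        )
    return AOISequence(
        participant_id=trial.participant_id,
        trial_id=trial.trial_id,
        symbols=symbols,
        dwell_durations_ms=durations,
        n_dropped_offaoi=n_dropped,
    )


def detect_fixations_idt(
    samples: Sequence[RawGazeSample],
    dispersion_px: float = IDT_DISPERSION_PX,
    min_duration_ms: float = IDT_MIN_DURATION_MS,
) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    Grows a window while its bounding-box dispersion (width + height) stays
    within ``dispersion_px``; windows spanning at least ``min_duration_ms``
    become fixations at the window centroid. Invalid samples break windows.
    """
    if dispersion_px <= 0 or min_duration_ms <= 0:
        raise ValidationError("dispersion_px and min_duration_ms must be positive")
    ts = [s.t_ms for s in samples]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValidationError("samples must be sorted by t_ms")

    fixations: list[Fixation] = []
    run: list[RawGazeSample] = []
    for s in samples:
        if s.valid:
            run.append(s)
        else:
            fixations.extend(_idt_run(run, dispersion_px, min_duration_ms))
            run = []
    fixations.extend(_idt_run(run, dispersion_px, min_duration_ms))
    return fixations


def _dispersion(run: Sequence[RawGazeSample], i: int, j: int) -> float:
    xs = [run[k].x_px for k in range(i, j + 1)]
    ys = [run[k].y_px for k in range(i, j + 1)]
    return (max(xs) - min(xs)) + (max(ys) - min(ys))


def _idt_run(
    run: Sequence[RawGazeSample], dispersion_px: float, min_duration_ms: float
) -> list[Fixation]:
    out: list[Fixation] = []
    n = len(run)
    i = 0
    while i < n:
        # smallest window starting at i that spans min_duration_ms
        j = i
        while j < n and run[j].t_ms - run[i].t_ms < min_duration_ms:
            j += 1
        if j >= n:
            break
        if _dispersion(run, i, j) <= dispersion_px:
            while j + 1 < n and _dispersion(run, i, j + 1) <= dispersion_px:
                j += 1
            window = run[i : j + 1]
            out.append(
                Fixation(
                    onset_ms=window[0].t_ms,
                    duration_ms=window[-1].t_ms - window[0].t_ms,
                    x_px=float(np.mean([s.x_px for s in window])),
                    y_px=float(np.mean([s.y_px for s in window])),
                )
            )
            i = j + 1
        else:
            i += 1
    return out
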