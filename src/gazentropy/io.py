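"""Reading and writing fixation records, AOI layouts and entropy tables.

File conventions
----------------
* Fixation files are delimited text (comma by default) with one row per
  fixation. The default header is
  ``participant_id, trial_id, difficulty, comm_frequency, onset_ms,
  duration_ms, x_px, y_px``; a :class:`ColumnDialect` remaps nonstandard
  headers. Unknown extra columns are ignored with a logged warning.
* AOI layouts are YAML: a list of mappings with keys
  ``aoi_id, label, x_min, y_min, x_max, y_max`` (screen pixels, origin
  top-left, y downward). Rectangles are half-open
  ``[x_min, x_max) x [y_min, y_max)`` so every point belongs to at most one
  region without tie-breaking.
* Entropy results are written as a tab-delimited long-format table, one row
  per participant x trial, and round-trip losslessly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .exceptions import FormatError, LayoutError, ValidationError

logger = logging.getLogger(__name__)

DIFFICULTY_LEVELS = ("Easy", "Difficult")
COMM_LEVELS = ("High", "Low")

#: canonical column order for fixation files
FIXATION_COLUMNS = (
    "participant_id",
    "trial_id",
    "difficulty",
    "comm_frequency",
    "onset_ms",
    "duration_ms",
    "x_px",
    "y_px",
)


@dataclass(frozen=True, slots=True)
class Fixation:
    """One fixation event within a trial.

    Times are milliseconds from trial start; coordinates are screen pixels
    with the origin at the top-left corner and y increasing downward.
    """

    onset_ms: float
    duration_ms: float
    x_px: float
    y_px: float

    def __post_init__(self) -> None:
        if not self.duration_ms > 0:
            raise ValidationError(f"duration_ms must be > 0, got {self.duration_ms}")
        if self.onset_ms < 0:
            raise ValidationError(f"onset_ms must be >= 0, got {self.onset_ms}")


@dataclass(slots=True)
class TrialRecord:
    """All fixations of one participant in one experimental trial.

    ``difficulty`` (within-subject) and ``comm_frequency`` (between-subject)
    place the trial in one cell of the 2x2 mixed design.
    """

    participant_id: str
    trial_id: str
    difficulty: str
    comm_frequency: str
    fixations: list[Fixation]
    trial_length_s: float = 1200.0

    def __post_init__(self) -> None:
        if self.difficulty not in DIFFICULTY_LEVELS:
            raise ValidationError(
                f"difficulty must be one of {DIFFICULTY_LEVELS}, got {self.difficulty!r}"
            )
        if self.comm_frequency not in COMM_LEVELS:
            raise ValidationError(
                f"comm_frequency must be one of {COMM_LEVELS}, got {self.comm_frequency!r}"
            )
        self.fixations = sorted(self.fixations, key=lambda f: f.onset_ms)
        limit = self.trial_length_s * 1000.0
        for f in self.fixations:
            if not (0 <= f.onset_ms < limit):
                raise ValidationError(
                    f"fixation onset {f.onset_ms} ms outside [0, {limit}) in trial "
                    f"{self.participant_id}/{self.trial_id}"
                )


@dataclass(frozen=True, slots=True)
class AOIRegion:
    """A named rectangular area of interest, half-open in both axes."""

    aoi_id: int
    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.aoi_id <= 0:
            raise LayoutError(f"aoi_id must be a positive integer, got {self.aoi_id}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise LayoutError(
                f"degenerate rectangle for AOI {self.aoi_id}: "
                f"[{self.x_min},{self.x_max}) x [{self.y_min},{self.y_max})"
            )

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass(frozen=True)
class ColumnDialect:
    """Maps canonical fixation-file column names to the file's headers."""

    participant_id: str = "participant_id"
    trial_id: str = "trial_id"
    difficulty: str = "difficulty"
    comm_frequency: str = "comm_frequency"
    onset_ms: str = "onset_ms"
    duration_ms: str = "duration_ms"
    x_px: str = "x_px"
    y_px: str = "y_px"
    sep: str = ","

    def mapping(self) -> dict[str, str]:
        """file column -> canonical name"""
        return {
            getattr(self, f.name): f.name
            for f in fields(self)
            if f.name != "sep"
        }


DEFAULT_DIALECT = ColumnDialect()


def read_fixations(
    path: str | Path,
    dialect: ColumnDialect | None = None,
    trial_length_s: float = 1200.0,
) -> list[TrialRecord]:
    """Read a delimited fixation file into trial records.

    Rows are grouped by participant x trial and re-sorted by onset, so the
    result does not depend on input row order. Malformed rows raise
    :class:`ValidationError` naming the 1-based data line.
    """
    dialect = dialect or DEFAULT_DIALECT
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=dialect.sep)
    colmap = dialect.mapping()
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in colmap]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path, extra)
    df = df[list(colmap)].rename(columns=colmap)
    return trials_from_dataframe(df, trial_length_s=trial_length_s, source=str(path))


def trials_from_dataframe(
    df: pd.DataFrame, trial_length_s: float = 1200.0, source: str = "<dataframe>"
) -> list[TrialRecord]:
    """Build validated :class:`TrialRecord` objects from a canonical frame."""
    bad = df.index[~(pd.to_numeric(df["duration_ms"], errors="coerce") > 0)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise ValidationError(
            f"{source}: non-positive or non-numeric duration_ms at line(s) {rows}"
        )
    bad = df.index[pd.to_numeric(df["onset_ms"], errors="coerce") < 0]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])
        raise ValidationError(f"{source}: negative onset_ms at line(s) {rows}")

    records: list[TrialRecord] = []
    for (pid, tid), grp in df.groupby(["participant_id", "trial_id"], sort=True):
        diff = grp["difficulty"].unique()
        comm = grp["comm_frequency"].unique()
        if len(diff) != 1 or len(comm) != 1:
            raise ValidationError(
                f"{source}: inconsistent condition labels within trial {pid}/{tid}"
            )
        fx = [
            Fixation(
                onset_ms=float(r.onset_ms),
                duration_ms=float(r.duration_ms),
                x_px=float(r.x_px),
                y_px=float(r.y_px),
            )
            for r in grp.itertuples()
        ]
        records.append(
            TrialRecord(
                participant_id=str(pid),
                trial_id=str(tid),
                difficulty=str(diff[0]),
                comm_frequency=str(comm[0]),
                fixations=fx,
                trial_length_s=trial_length_s,
            )
        )
    return records


def trials_to_dataframe(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        (
            t.participant_id,
            t.trial_id,
            t.difficulty,
            t.comm_frequency,
            f.onset_ms,
            f.duration_ms,
            f.x_px,
            f.y_px,
        )
        for t in trials
        for f in t.fixations
    ]
    return pd.DataFrame(rows, columns=list(FIXATION_COLUMNS))


def write_fixations(
    trials: Iterable[TrialRecord], path: str | Path, dialect: ColumnDialect | None = None
) -> None:
    dialect = dialect or DEFAULT_DIALECT
    df = trials_to_dataframe(trials)
    inv = {v: k for k, v in dialect.mapping().items()}
    df.rename(columns=inv).to_csv(path, sep=dialect.sep, index=False)


def _rects_overlap(a: AOIRegion, b: AOIRegion) -> bool:
    # half-open rectangles intersect iff the open interval tests pass;
    # regions sharing only an edge do not overlap
    return a.x_min < b.x_max and b.x_min < a.x_max and a.y_min < b.y_max and b.y_min < a.y_max


def validate_layout(regions: Sequence[AOIRegion]) -> list[AOIRegion]:
    ids = [r.aoi_id for r in regions]
    if len(set(ids)) != len(ids):
        raise LayoutError(f"duplicate aoi_id in layout: {sorted(ids)}")
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            if _rects_overlap(a, b):
                raise LayoutError(
                    f"AOIs {a.aoi_id} ({a.label!r}) and {b.aoi_id} ({b.label!r}) overlap"
                )
    return list(regions)


def read_aoi_layout(path: str | Path) -> list[AOIRegion]:
    """Read an AOI layout from a YAML file and validate disjointness."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if isinstance(raw, Mapping) and "aois" in raw:
        raw = raw["aois"]
    if not isinstance(raw, list) or not raw:
        raise FormatError(f"{path}: expected a non-empty list of AOI entries")
    regions = []
    for entry in raw:
        try:
            regions.append(
                AOIRegion(
                    aoi_id=int(entry["aoi_id"]),
                    label=str(entry.get("label", f"AOI{entry['aoi_id']}")),
                    x_min=float(entry["x_min"]),
                    y_min=float(entry["y_min"]),
                    x_max=float(entry["x_max"]),
                    y_max=float(entry["y_max"]),
                )
            )
        except KeyError as e:
            raise FormatError(f"{path}: AOI entry missing key {e}") from e
    return validate_layout(regions)


def write_aoi_layout(regions: Sequence[AOIRegion], path: str | Path) -> None:
    entries = [
        {
            "aoi_id": r.aoi_id,
            "label": r.label,
            "x_min": float(r.x_min),
            "y_min": float(r.y_min),
            "x_max": float(r.x_max),
            "y_max": float(r.y_max),
        }
        for r in regions
    ]
    Path(path).write_text(yaml.safe_dump({"aois": entries}, sort_keys=False))


# ---------------------------------------------------------------------------
# entropy result tables


RESULT_COLUMNS = (
    "participant_id",
    "trial_id",
    "difficulty",
    "comm_frequency",
    "sge_bits",
    "gte_bits",
    "sge_norm",
    "gte_norm",
    "n_aois",
    "n_transitions",
    "n_dropped_offaoi",
    "collapse",
    "offaoi_policy",
    "p_i_estimator",
)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write the per-trial entropy table as tab-delimited text.

    Floats are written with ``repr`` precision so the table round-trips to
    better than 1e-12.
    """
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty results table")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"results table missing column(s) {missing}")
    results[list(RESULT_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: results table missing column(s) {missing}")
    return df
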