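"""Stationary gaze entropy (SGE) and gaze transition entropy (GTE).

Given an AOI symbol sequence, the first-order transition structure is
summarised by the pair (p_i, p_ij): p_i is the simple probability of viewing
AOI i and p_ij the conditional probability of moving from AOI i to AOI j
between successive dwells. The two entropies are

    H_s = -sum_i p_i log2 p_i                      (SGE, bits)
    H_t = -sum_i p_i sum_j p_ij log2 p_ij          (GTE, bits)

with 0*log 0 = 0 by continuity. High SGE means gaze mass is spread evenly
over the AOIs; high GTE means the next AOI is hard to predict from the
current one. When consecutive same-AOI fixations have been collapsed, the
diagonal of p_ij is structurally zero and the natural GTE ceiling drops from
log2(n) to log2(n-1); both raw bits and normalized values are reported
because published magnitudes cannot always be attributed to one convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InsufficientDataError, ValidationError
from .scanpath import AOISequence

P_I_ESTIMATORS = ("visit_frequency", "dwell_weighted", "left_eigenvector")

_NORM_TOL = 1e-9


@dataclass(slots=True)
class TransitionModel:
    """First-order transition structure of one AOI sequence.

    ``counts[i, j]`` is the number of observed moves from AOI ``i+1`` to AOI
    ``j+1`` (0-based storage of 1-based AOI ids); ``p_ij`` row-normalizes the
    counts (all-zero rows stay all-zero); ``p_i`` is the simple viewing
    probability under the chosen estimator.
    """

    n_aois: int
    counts: np.ndarray
    p_i: np.ndarray
    p_ij: np.ndarray
    n_transitions: int
    p_i_estimator: str = "visit_frequency"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.p_i = np.asarray(self.p_i, dtype=float)
        self.p_ij = np.asarray(self.p_ij, dtype=float)
        n = self.n_aois
        if self.counts.shape != (n, n) or self.p_ij.shape != (n, n):
            raise ValidationError("counts and p_ij must be n_aois x n_aois")
        if self.p_i.shape != (n,):
            raise ValidationError("p_i must have length n_aois")
        if self.n_transitions >= 1 and abs(self.p_i.sum() - 1.0) > 1e-12 * max(1, n):
            raise ValidationError("p_i must sum to 1")
        rowsums = self.p_ij.sum(axis=1)
        support = self.counts.sum(axis=1) > 0
        if np.any(np.abs(rowsums[support] - 1.0) > 1e-12):
            raise ValidationError("supported rows of p_ij must sum to 1")
        if np.any(self.p_ij[~support] != 0):
            raise ValidationError("rows without outgoing counts must be all-zero")


@dataclass(slots=True)
class EntropyResult:
    """Per-trial SGE and GTE, raw bits and normalized, plus conventions."""

    sge_bits: float
    gte_bits: float
    sge_norm: float
    gte_norm: float
    n_aois: int
    n_transitions: int
    conventions: dict = field(default_factory=dict)
    participant_id: str = ""
    trial_id: str = ""


def _check_prob_vector(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("probability vector must be 1-D")
    if np.any(p < -_NORM_TOL):
        raise ValidationError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValidationError(f"probability vector sums to {p.sum()}, not 1")
    return np.clip(p, 0.0, None)


def _plogp(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def compute_sge(p_i: np.ndarray) -> float:
    """Shannon entropy of the AOI viewing distribution, in bits."""
    p = _check_prob_vector(p_i)
    return float(-_plogp(p).sum())


def compute_gte(p_i: np.ndarray, p_ij: np.ndarray) -> float:
    """Stationary-weighted conditional entropy of the transition matrix, bits.

    Rows of ``p_ij`` with zero support (all-zero rows) contribute nothing.
    """
    p = _check_prob_vector(p_i)
    P = np.asarray(p_ij, dtype=float)
    if P.shape != (len(p), len(p)):
        raise ValidationError(
            f"p_ij shape {P.shape} does not match p_i length {len(p)}"
        )
    rowsums = P.sum(axis=1)
    supported = rowsums > 0
    if np.any(np.abs(rowsums[supported] - 1.0) > _NORM_TOL):
        raise ValidationError("each supported row of p_ij must sum to 1")
    row_h = -_plogp(P).sum(axis=1)
    return float((p * row_h).sum())


def normalize_entropy(h_bits: float, n_aois: int, exclude_self: bool = False) -> float:
    """Scale an entropy in bits to [0, 1] by its combinatorial ceiling.

    The ceiling is log2(n_aois), or log2(n_aois - 1) for transition entropy
    of a chain whose self-transitions are structurally excluded.
    """
    if n_aois < 2:
        raise ValidationError("normalization requires n_aois >= 2")
    if h_bits < -1e-12:
        raise ValidationError("entropy must be non-negative")
    denom = np.log2(n_aois - 1) if exclude_self else np.log2(n_aois)
    if denom == 0:  # n_aois == 2 with self-exclusion: only one destination
        return 0.0
    v = h_bits / denom
    if v > 1.0 + 1e-12 or v < -1e-12:
        raise ValidationError(f"normalized entropy {v} outside [0, 1]")
    return float(np.clip(v, 0.0, 1.0))


def transition_counts(symbols: np.ndarray, n_aois: int) -> np.ndarray:
    """n x n matrix of adjacent-pair counts (AOI ids are 1-based)."""
    s = np.asarray(symbols, dtype=np.int64)
    if np.any(s < 1) or np.any(s > n_aois):
        raise ValidationError(
            f"symbols must be AOI ids in 1..{n_aois}; got range "
            f"[{s.min() if len(s) else '-'}, {s.max() if len(s) else '-'}]"
        )
    src = s[:-1] - 1
    dst = s[1:] - 1
    flat = np.bincount(src * n_aois + dst, minlength=n_aois * n_aois)
    return flat.reshape(n_aois, n_aois)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector).

    For reducible matrices the eigenvector associated with the eigenvalue
    closest to 1 is returned; states with no support get zero mass.
    """
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.clip(pi if pi.sum() >= 0 else -pi, 0.0, None)
    total = pi.sum()
    if total <= 0:
        raise ValidationError("could not extract a stationary distribution")
    return pi / total


def estimate_model(
    seq: AOISequence, n_aois: int, p_i_estimator: str = "visit_frequency"
) -> TransitionModel:
    """Estimate (p_i, p_ij) from one AOI sequence.

    ``visit_frequency`` (default) takes p_i as the relative frequency of each
    symbol; ``dwell_weighted`` weights symbols by dwell duration;
    ``left_eigenvector`` solves pi @ p_ij = pi for the chain's stationary
    distribution.
    """
    if p_i_estimator not in P_I_ESTIMATORS:
        raise ValidationError(f"unknown p_i estimator {p_i_estimator!r}")
    if len(seq) < 2:
        raise InsufficientDataError(
            f"trial {seq.participant_id}/{seq.trial_id}: need >= 2 symbols "
            f"(>= 1 transition), got {len(seq)}"
        )
    counts = transition_counts(seq.symbols, n_aois)
    n_transitions = int(counts.sum())
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ij = np.where(rowsum > 0, counts / np.where(rowsum == 0, 1, rowsum), 0.0)

    if p_i_estimator == "visit_frequency":
        p_i = np.bincount(seq.symbols - 1, minlength=n_aois).astype(float)
        p_i /= p_i.sum()
    elif p_i_estimator == "dwell_weighted":
        p_i = np.bincount(
            seq.symbols - 1, weights=seq.dwell_durations_ms, minlength=n_aois
        )
        p_i /= p_i.sum()
    else:  # left_eigenvector
        p_i = stationary_distribution(p_ij)

    return TransitionModel(
        n_aois=n_aois,
        counts=counts,
        p_i=p_i,
        p_ij=p_ij,
        n_transitions=n_transitions,
        p_i_estimator=p_i_estimator,
    )


def entropy_from_model(
    model: TransitionModel,
    exclude_self: bool = True,
    participant_id: str = "",
    trial_id: str = "",
    conventions: dict | None = None,
) -> EntropyResult:
    """SGE/GTE (raw and normalized) for one estimated transition model."""
    sge = compute_sge(model.p_i)
    gte = compute_gte(model.p_i, model.p_ij)
    return EntropyResult(
        sge_bits=sge,
        gte_bits=gte,
        sge_norm=normalize_entropy(sge, model.n_aois, exclude_self=False),
        gte_norm=normalize_entropy(gte, model.n_aois, exclude_self=exclude_self),
        n_aois=model.n_aois,
        n_transitions=model.n_transitions,
        conventions=dict(conventions or {}, p_i_estimator=model.p_i_estimator),
        participant_id=participant_id,
        trial_id=trial_id,
    )


def analytic_entropies(P: np.ndarray, pi: np.ndarray | None = None) -> tuple[float, float]:
    """Exact (SGE, GTE) in bits for a known chain (pi defaults to stationary)."""
    P = np.asarray(P, dtype=float)
    if pi is None:
        pi = stationary_distribution(P)
    return compute_sge(pi), compute_gte(pi, P)


def aggregate_condition_matrix(models: Sequence[TransitionModel]) -> np.ndarray:
    """Cell-wise unweighted mean of per-trial p_ij matrices.

    Every model counts equally regardless of its transition count, so the
    aggregate's rows need not sum to 1.
    """
    if not models:
        raise ValidationError("cannot aggregate an empty list of models")
    n = models[0].n_aois
    if any(m.n_aois != n for m in models):
        raise ValidationError("all models must share n_aois")
    return np.mean([m.p_ij for m in models], axis=0)


def write_matrix(matrix: np.ndarray, path, labels: Iterable[str] | None = None) -> None:
    """Write an aggregated matrix as a labeled tab-delimited table."""
    import pandas as pd

    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    labels = list(labels) if labels is not None else [str(i + 1) for i in range(n)]
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.index.name = "source_aoi"
    df.to_csv(path, sep="\t", float_format="%.17g")
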