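"""Mixed-design inference for condition effects on gaze measures.

The experimental design is 2 x 2 mixed: communication frequency
(High/Low) varies between participants and tracking difficulty
(Easy/Difficult) within participants. For each dependent measure a
split-plot ANOVA gives F(1, N-2) for the between main effect, the within
main effect and their interaction, with generalized eta-squared
(eta2_G = SS_effect / (SS_effect + SS_error_between + SS_error_within)) as
the effect size appropriate to mixed designs.

Evidence is additionally summarised by a Bayes factor approximated from the
BIC identity BF10 = exp((BIC_null - BIC_alt) / 2). This is a unit-information
approximation, not a default-prior (JZS) Bayes factor, and is labeled on the
standard Jeffreys bands (3.16, 10, 31.6, 100 and their reciprocals).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import DesignError, ValidationError

logger = logging.getLogger(__name__)

EFFECTS = ("between_main", "within_main", "interaction")

#: half-decade Jeffreys band edges on BF10 > 1
_JEFFREYS_EDGES = (10 ** 0.5, 10.0, 10 ** 1.5, 100.0)
_JEFFREYS_NAMES = ("anecdotal", "substantial", "strong", "very strong", "decisive")


@dataclass(slots=True)
class MixedAnovaResult:
    """One effect line of the 2x2 mixed ANOVA."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta2_G: float
    bf10: float
    evidence_label: str


@dataclass(slots=True)
class ConditionSummary:
    """Marginal mean with a t-based 95% confidence interval."""

    condition: str
    mean: float
    ci95_low: float
    ci95_high: float
    n: int


def exclude_participants(
    participants: pd.DataFrame,
    threshold: float = 0.50,
    error_col: str = "monitoring_error_rate",
) -> tuple[pd.DataFrame, list[str]]:
    """Drop participants whose monitoring error rate is strictly above threshold.

    Mirrors the screening rule of the study design: an error rate *above*
    50% in the system monitoring task excludes the participant; exactly 50%
    is retained.
    """
    if error_col not in participants.columns:
        raise ValidationError(f"participant table lacks column {error_col!r}")
    rates = participants[error_col].astype(float)
    if ((rates < 0) | (rates > 1)).any():
        raise ValidationError("monitoring error rates must lie in [0, 1]")
    excluded_mask = rates > threshold
    excluded = participants.loc[excluded_mask, "participant_id"].astype(str).tolist()
    retained = participants.loc[~excluded_mask].copy()
    if retained.empty:
        raise ValidationError("exclusion rule removed every participant")
    for pid in excluded:
        logger.warning("excluding participant %s (monitoring error rate > %.2f)", pid, threshold)
    return retained, excluded


def _check_complete(
    data: pd.DataFrame, dv: str, within: str, between: str, subject: str
) -> pd.DataFrame:
    for col in (dv, within, between, subject):
        if col not in data.columns:
            raise ValidationError(f"data lacks column {col!r}")
    counts = data.groupby(subject, observed=True)[within].nunique()
    bad = counts.index[counts != 2].tolist()
    if bad:
        raise DesignError(f"participants missing a within-level observation: {bad}")
    ngroups = data.groupby(subject, observed=True)[between].nunique()
    bad = ngroups.index[ngroups != 1].tolist()
    if bad:
        raise DesignError(f"participants with more than one between-level: {bad}")
    return data


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "difficulty",
    between: str = "comm_frequency",
    subject: str = "participant_id",
) -> list[MixedAnovaResult]:
    """Split-plot ANOVA of a 2 (between) x 2 (within) design.

    Expects long-format data with one row per participant x within-level.
    Returns the between main effect, within main effect and interaction,
    each with F(1, N-2), generalized eta-squared, the BIC Bayes factor and
    its Jeffreys label.
    """
    import pingouin as pg

    data = _check_complete(data, dv, within, between, subject)
    n_subjects = data[subject].nunique()
    if data[between].nunique() != 2 or data[within].nunique() != 2:
        raise DesignError("mixed_anova_2x2 requires exactly 2 levels per factor")

    constant = np.isclose(data[dv].astype(float).var(ddof=0), 0.0)
    if constant:
        # zero variance: every SS is 0, define F = 0 (no evidence of effect)
        df2 = n_subjects - 2
        return [
            _result(eff, 0.0, 1, df2, 1.0, 0.0, n_subjects) for eff in EFFECTS
        ]

    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject,
        effsize="ng2", correction=False,
    )
    aov = aov.set_index("Source")
    order = {"between_main": aov.index[0], "within_main": aov.index[1],
             "interaction": "Interaction"}
    out = []
    for effect in EFFECTS:
        row = aov.loc[order[effect]]
        F = float(row["F"])
        eta = float(row["ng2"])
        if not math.isfinite(F):
            F, eta = 0.0, 0.0
        out.append(
            _result(effect, F, int(row["DF1"]), int(row["DF2"]),
                    float(row["p_unc"]) if math.isfinite(F) else 1.0,
                    eta, n_subjects)
        )
    return out


def _result(effect: str, F: float, df1: int, df2: int, p: float, eta: float,
            n: int) -> MixedAnovaResult:
    bf = bf10_bic(F, df1, df2, n)
    return MixedAnovaResult(
        effect=effect, F=F, df1=df1, df2=df2, p=p, eta2_G=eta,
        bf10=bf, evidence_label=jeffreys_label(bf),
    )


def bf10_bic(f: float, df1: int, df2: int, n: int) -> float:
    """Bayes factor BF10 from an F statistic via the BIC identity.

    Uses BF10 = exp((BIC_null - BIC_alt)/2) with
    BIC_null - BIC_alt = n*ln(1 + df1*F/df2) - df1*ln(n), taking ``n`` as the
    number of independent observations (participants). A unit-information
    approximation; values are comparable in order of magnitude, not
    numerically identical, to default-prior Bayes factors.
    """
    if not math.isfinite(f) or f < 0:
        raise ValidationError(f"F must be finite and non-negative, got {f}")
    if min(df1, df2, n) <= 0:
        raise ValidationError("df1, df2 and n must be positive")
    log_bf = 0.5 * (n * math.log1p(df1 * f / df2) - df1 * math.log(n))
    try:
        return math.exp(log_bf)
    except OverflowError:
        return math.inf


def jeffreys_label(bf10: float) -> str:
    """Jeffreys evidence category for a Bayes factor BF10.

    Bands at half decades: 1-3.16 anecdotal, 3.16-10 substantial, 10-31.6
    strong, 31.6-100 very strong, >100 decisive; reciprocal bands describe
    evidence for the null. BF10 = 1 is 'no evidence'.
    """
    if not bf10 > 0:
        raise ValidationError(f"bf10 must be positive, got {bf10}")
    if bf10 == 1.0:
        return "no evidence"
    favors_null = bf10 < 1.0
    b = 1.0 / bf10 if favors_null else bf10
    idx = sum(b >= edge for edge in _JEFFREYS_EDGES)
    name = _JEFFREYS_NAMES[idx]
    return f"{name} (for null)" if favors_null else name


def condition_summaries(
    data: pd.DataFrame,
    measure: str = "value",
    factors: tuple[str, ...] = ("difficulty", "comm_frequency"),
    subject: str = "participant_id",
    conf: float = 0.95,
) -> list[ConditionSummary]:
    """Marginal means with t-based confidence intervals per factor level.

    Each participant contributes one value per margin (their mean over rows
    at that level), so within-factor CIs are computed on participant-level
    values.
    """
    out: list[ConditionSummary] = []
    for factor in factors:
        if factor not in data.columns:
            raise ValidationError(f"data lacks factor column {factor!r}")
        for level, grp in data.groupby(factor, observed=True, sort=True):
            vals = grp.groupby(subject, observed=True)[measure].mean().to_numpy()
            n = len(vals)
            if n < 2:
                raise ValidationError(
                    f"margin {factor}={level} has n={n} < 2 participants"
                )
            m = float(np.mean(vals))
            sem = float(np.std(vals, ddof=1) / np.sqrt(n))
            tcrit = float(scipy.stats.t.ppf(0.5 + conf / 2, n - 1))
            half = tcrit * sem
            out.append(
                ConditionSummary(
                    condition=f"{factor}={level}", mean=m,
                    ci95_low=m - half, ci95_high=m + half, n=n,
                )
            )
    return out


def anova_table(results: list[MixedAnovaResult]) -> pd.DataFrame:
    """Effects as a tidy frame (one row per effect)."""
    return pd.DataFrame(
        [
            {
                "effect": r.effect, "F": r.F, "df1": r.df1, "df2": r.df2,
                "p": r.p, "eta2_G": r.eta2_G, "bf10": r.bf10,
                "evidence": r.evidence_label,
            }
            for r in results
        ]
    )
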