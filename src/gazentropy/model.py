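"""Model/Results interface tying the pipeline together.

``GazeEntropyModel`` holds the data (trial records + AOI layout) and the
analysis conventions; ``fit()`` returns a ``GazeEntropyResults`` carrying
per-trial entropies, per-condition transition matrices, the mixed-design
ANOVA tables and a ``summary()``. Typical use::

    from gazentropy import GazeEntropyModel, CohortDesign

    model = GazeEntropyModel.from_simulation(CohortDesign(seed=7))
    res = model.fit()
    print(res.summary())
    res.per_trial.head()
    res.condition_matrix("difficulty", "Easy")
    res.anova("gte_norm")
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import entropy as ent
from . import inference as inf
from . import io as gio
from . import scanpath as sp
from .exceptions import ValidationError
from .simulate import (
    DEFAULT_LAYOUT,
    CohortDesign,
    GenerativeParams,
    generate_cohort,
)

logger = logging.getLogger(__name__)

MEASURES = ("sge_bits", "gte_bits", "sge_norm", "gte_norm")


class GazeEntropyModel:
    """Gaze-entropy analysis of a cohort of trials over a fixed AOI layout.

    Parameters
    ----------
    trials
        Trial records (fixation streams with design-cell labels).
    layout
        Disjoint AOI rectangles; their ids are the chain alphabet.
    participants
        Optional table with ``participant_id`` and ``monitoring_error_rate``;
        when present, participants with error rate > ``error_threshold`` are
        excluded before estimation.
    collapse, offaoi_policy, p_i_estimator
        Analysis conventions (see :mod:`gazentropy.scanpath` and
        :mod:`gazentropy.entropy`).
    """

    def __init__(
        self,
        trials: Sequence[gio.TrialRecord],
        layout: Sequence[gio.AOIRegion] = DEFAULT_LAYOUT,
        participants: pd.DataFrame | None = None,
        collapse: bool = True,
        offaoi_policy: str = "drop",
        p_i_estimator: str = "visit_frequency",
        error_threshold: float = 0.50,
    ) -> None:
        if not trials:
            raise ValidationError("no trials supplied")
        self.trials = list(trials)
        self.layout = gio.validate_layout(list(layout))
        self.participants = participants
        self.collapse = collapse
        self.offaoi_policy = offaoi_policy
        self.p_i_estimator = p_i_estimator
        self.error_threshold = error_threshold

    # ------------------------------------------------------------- builders
    @classmethod
    def from_files(
        cls,
        fixation_path: str | Path,
        layout_path: str | Path,
        participants_path: str | Path | None = None,
        dialect: gio.ColumnDialect | None = None,
        **kwargs,
    ) -> "GazeEntropyModel":
        trials = gio.read_fixations(fixation_path, dialect=dialect)
        layout = gio.read_aoi_layout(layout_path)
        participants = (
            pd.read_csv(participants_path) if participants_path is not None else None
        )
        return cls(trials, layout, participants=participants, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        layout: Sequence[gio.AOIRegion] = DEFAULT_LAYOUT,
        **kwargs,
    ) -> "GazeEntropyModel":
        return cls(gio.trials_from_dataframe(df), layout, **kwargs)

    @classmethod
    def from_simulation(
        cls,
        design: CohortDesign | None = None,
        params: GenerativeParams | None = None,
        force_exclusion: bool = True,
        **kwargs,
    ) -> "GazeEntropyModel":
        design = design or CohortDesign()
        trials, participants = generate_cohort(
            design, params, force_exclusion=force_exclusion
        )
        model = cls(trials, DEFAULT_LAYOUT, participants=participants, **kwargs)
        model.design = design
        return model

    # ------------------------------------------------------------------ fit
    def fit(self) -> "GazeEntropyResults":
        """Run exclusion, sequence building, estimation and entropies."""
        trials = self.trials
        excluded: list[str] = []
        if self.participants is not None and "monitoring_error_rate" in self.participants:
            retained, excluded = inf.exclude_participants(
                self.participants, threshold=self.error_threshold
            )
            keep = set(retained["participant_id"].astype(str))
            trials = [t for t in trials if t.participant_id in keep]
            if not trials:
                raise ValidationError("exclusion removed every trial")

        n_aois = len(self.layout)
        conventions = {
            "collapse": self.collapse,
            "offaoi_policy": self.offaoi_policy,
            "p_i_estimator": self.p_i_estimator,
            "normalization_base_gte": (
                n_aois - 1 if self.collapse else n_aois
            ),
        }
        rows = []
        models: dict[tuple[str, str], ent.TransitionModel] = {}
        for t in trials:
            seq = sp.build_sequence(
                t, self.layout, offaoi_policy=self.offaoi_policy, collapse=self.collapse
            )
            m = ent.estimate_model(seq, n_aois, p_i_estimator=self.p_i_estimator)
            r = ent.entropy_from_model(
                m,
                exclude_self=self.collapse,
                participant_id=t.participant_id,
                trial_id=t.trial_id,
                conventions=conventions,
            )
            models[(t.participant_id, t.trial_id)] = m
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "trial_id": t.trial_id,
                    "difficulty": t.difficulty,
                    "comm_frequency": t.comm_frequency,
                    "sge_bits": r.sge_bits,
                    "gte_bits": r.gte_bits,
                    "sge_norm": r.sge_norm,
                    "gte_norm": r.gte_norm,
                    "n_aois": n_aois,
                    "n_transitions": m.n_transitions,
                    "n_dropped_offaoi": seq.n_dropped_offaoi,
                    "collapse": self.collapse,
                    "offaoi_policy": self.offaoi_policy,
                    "p_i_estimator": self.p_i_estimator,
                }
            )
        per_trial = pd.DataFrame(rows)
        n_dropped = int(per_trial["n_dropped_offaoi"].sum())
        if n_dropped:
            logger.warning(
                "dropped %d off-AOI fixation(s) across %d trial(s)",
                n_dropped, int((per_trial["n_dropped_offaoi"] > 0).sum()),
            )
        return GazeEntropyResults(
            model=self,
            per_trial=per_trial,
            transition_models=models,
            excluded_ids=excluded,
            conventions=conventions,
        )


@dataclass
class GazeEntropyResults:
    """Fitted per-trial entropies plus condition-level aggregation/inference."""

    model: GazeEntropyModel
    per_trial: pd.DataFrame
    transition_models: Mapping[tuple[str, str], ent.TransitionModel]
    excluded_ids: list[str]
    conventions: dict

    # ---------------------------------------------------------- aggregation
    def condition_matrix(self, factor: str, level: str) -> np.ndarray:
        """Unweighted mean transition matrix over trials at a factor level."""
        sel = self.per_trial[self.per_trial[factor] == level]
        if sel.empty:
            raise ValidationError(f"no trials with {factor} == {level!r}")
        models = [
            self.transition_models[(r.participant_id, r.trial_id)]
            for r in sel.itertuples()
        ]
        return ent.aggregate_condition_matrix(models)

    def condition_matrices(self) -> dict[str, np.ndarray]:
        out = {}
        for factor, levels in (
            ("difficulty", gio.DIFFICULTY_LEVELS),
            ("comm_frequency", gio.COMM_LEVELS),
        ):
            for level in levels:
                out[f"{factor}={level}"] = self.condition_matrix(factor, level)
        return out

    # ------------------------------------------------------------ inference
    def anova(self, measure: str = "gte_norm") -> list[inf.MixedAnovaResult]:
        if measure not in self.per_trial.columns:
            raise ValidationError(f"unknown measure {measure!r}")
        return inf.mixed_anova_2x2(self.per_trial, dv=measure)

    def anova_tables(self, measures: Sequence[str] = ("gte_norm", "sge_norm")) -> pd.DataFrame:
        frames = []
        for m in measures:
            tab = inf.anova_table(self.anova(m))
            tab.insert(0, "measure", m)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)

    def cell_anova_tables(self) -> pd.DataFrame:
        """ANOVAs of each off-diagonal transition-matrix cell probability."""
        rows = []
        for r in self.per_trial.itertuples():
            m = self.transition_models[(r.participant_id, r.trial_id)]
            for i in range(m.n_aois):
                for j in range(m.n_aois):
                    if i == j and self.conventions["collapse"]:
                        continue
                    rows.append(
                        {
                            "participant_id": r.participant_id,
                            "trial_id": r.trial_id,
                            "difficulty": r.difficulty,
                            "comm_frequency": r.comm_frequency,
                            "cell": f"p{i + 1}{j + 1}",
                            "value": m.p_ij[i, j],
                        }
                    )
        long = pd.DataFrame(rows)
        frames = []
        for cell, grp in long.groupby("cell"):
            tab = inf.anova_table(inf.mixed_anova_2x2(grp, dv="value"))
            tab.insert(0, "measure", cell)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)

    def condition_summaries(self, measure: str = "gte_norm") -> pd.DataFrame:
        summaries = inf.condition_summaries(self.per_trial, measure=measure)
        return pd.DataFrame(
            [
                {
                    "measure": measure,
                    "condition": s.condition,
                    "mean": s.mean,
                    "ci95_low": s.ci95_low,
                    "ci95_high": s.ci95_high,
                    "n": s.n,
                }
                for s in summaries
            ]
        )

    # -------------------------------------------------------------- display
    def summary(self) -> str:
        lines = []
        n_part = self.per_trial["participant_id"].nunique()
        lines.append("Gaze entropy analysis")
        lines.append("=" * 64)
        lines.append(
            f"participants analyzed: {n_part}"
            + (f" (excluded: {', '.join(self.excluded_ids)})" if self.excluded_ids else "")
        )
        lines.append(f"trials: {len(self.per_trial)}   AOIs: {self.per_trial['n_aois'].iloc[0]}")
        lines.append(
            "conventions: collapse={collapse}, offaoi_policy={offaoi_policy}, "
            "p_i={p_i_estimator}".format(**self.conventions)
        )
        lines.append("")
        for measure in ("gte_norm", "sge_norm"):
            lines.append(f"-- {measure} --")
            summ = self.condition_summaries(measure)
            for r in summ.itertuples():
                lines.append(
                    f"  {r.condition:<24} mean {r.mean:.4f}  "
                    f"95% CI [{r.ci95_low:.4f}, {r.ci95_high:.4f}]  n={r.n}"
                )
            for a in self.anova(measure):
                lines.append(
                    f"  {a.effect:<13} F({a.df1},{a.df2}) = {a.F:8.2f}  "
                    f"eta2_G = {a.eta2_G:.3f}  BF10 = {a.bf10:.3g} ({a.evidence_label})"
                )
            lines.append("")
        return "\n".join(lines)

    # ------------------------------------------------------------- plotting
    def plot_condition_matrices(self, axes=None):
        """Heatmaps of the four condition-mean transition matrices."""
        import matplotlib.pyplot as plt

        mats = self.condition_matrices()
        if axes is None:
            _, axes = plt.subplots(2, 2, figsize=(8, 7))
        for ax, (name, mat) in zip(np.ravel(axes), mats.items()):
            im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis")
            n = mat.shape[0]
            for i in range(n):
                for j in range(n):
                    ax.text(j, i, f"{mat[i, j]:.2f}", ha="center", va="center",
                            color="w" if mat[i, j] < 0.6 else "k")
            ax.set_xticks(range(n), [str(k + 1) for k in range(n)])
            ax.set_yticks(range(n), [str(k + 1) for k in range(n)])
            ax.set_xlabel("destination AOI")
            ax.set_ylabel("source AOI")
            ax.set_title(name)
            plt.colorbar(im, ax=ax, fraction=0.046)
        plt.tight_layout()
        return axes

    def plot_condition_means(self, measure: str = "gte_norm", ax=None):
        """Marginal means with 95% CI error bars for one measure."""
        import matplotlib.pyplot as plt

        summ = self.condition_summaries(measure)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        x = np.arange(len(summ))
        ax.bar(x, summ["mean"], color="0.7", edgecolor="k")
        ax.errorbar(
            x, summ["mean"],
            yerr=[summ["mean"] - summ["ci95_low"], summ["ci95_high"] - summ["mean"]],
            fmt="none", ecolor="k", capsize=4,
        )
        ax.set_xticks(x, summ["condition"], rotation=20)
        ax.set_ylabel(measure)
        return ax
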