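import math

import numpy as np
import pandas as pd
import pytest

from gazentropy.exceptions import DesignError, ValidationError
from gazentropy.inference import (
    bf10_bic,
    condition_summaries,
    exclude_participants,
    jeffreys_label,
    mixed_anova_2x2,
)


def participants_table(rates):
    return pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(len(rates))],
        "monitoring_error_rate": rates,
    })


class TestExclusion:
    def test_one_of_forty_above_threshold(self):
        rates = [0.1] * 39 + [0.62]
        retained, excluded = exclude_participants(participants_table(rates))
        assert len(retained) == 39
        assert excluded == ["P39"]

    def test_all_clean_is_identity(self):
        retained, excluded = exclude_participants(participants_table([0.0] * 5))
        assert len(retained) == 5 and excluded == []

    def test_exactly_half_is_retained(self):
        retained, excluded = exclude_participants(participants_table([0.50, 0.1]))
        assert len(retained) == 2 and excluded == []

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            exclude_participants(participants_table([1.2]))

    def test_everyone_excluded_is_error(self):
        with pytest.raises(ValidationError):
            exclude_participants(participants_table([0.9, 0.8]))


def long_table(values_by_participant, groups):
    """values_by_participant: {pid: (easy, difficult)}; groups: {pid: level}"""
    rows = []
    for pid, (e, d) in values_by_participant.items():
        rows.append((pid, groups[pid], "Easy", e))
        rows.append((pid, groups[pid], "Difficult", d))
    return pd.DataFrame(rows, columns=["participant_id", "comm_frequency",
                                       "difficulty", "value"])


def manual_split_plot(data):
    """From-scratch SS decomposition of the balanced 2x2 split-plot design.

    Independent of both the package and pingouin: everything is computed
    from cell/subject means with textbook formulas.
    """
    piv = data.pivot_table(index=["participant_id", "comm_frequency"],
                           columns="difficulty", values="value")
    y = piv.to_numpy()                      # subjects x within-levels
    groups = piv.index.get_level_values(1).to_numpy()
    levels = sorted(set(groups))
    N, w = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    ss_subjects = w * ((subj_means - grand) ** 2).sum()
    ss_between = w * sum(
        (groups == g).sum() * (subj_means[groups == g].mean() - grand) ** 2
        for g in levels
    )
    ss_err_between = ss_subjects - ss_between
    ss_within_total = ((y - subj_means[:, None]) ** 2).sum()
    col_means = y.mean(axis=0)
    ss_within = N * ((col_means - grand) ** 2).sum()
    ss_inter = 0.0
    for g in levels:
        sel = groups == g
        cell = y[sel].mean(axis=0)
        ss_inter += sel.sum() * ((cell - subj_means[sel].mean()
                                  - col_means + grand) ** 2).sum()
    ss_err_within = ss_within_total - ss_within - ss_inter
    df_between, df_err_b = len(levels) - 1, N - len(levels)
    df_within = w - 1
    df_err_w = df_err_b * df_within
    out = {}
    for name, ss, df, ss_err, df_err in (
        ("between_main", ss_between, df_between, ss_err_between, df_err_b),
        ("within_main", ss_within, df_within, ss_err_within, df_err_w),
        ("interaction", ss_inter, df_between * df_within, ss_err_within, df_err_w),
    ):
        F = (ss / df) / (ss_err / df_err)
        eta = ss / (ss + ss_err_between + ss_err_within)
        out[name] = (F, df, df_err, eta)
    return out


class TestMixedAnova:
    def test_error_df_is_n_minus_groups(self):
        rng = np.random.default_rng(0)
        vals = {f"P{i}": tuple(rng.normal(0, 1, 2)) for i in range(39)}
        groups = {f"P{i}": ("High" if i < 20 else "Low") for i in range(39)}
        res = mixed_anova_2x2(long_table(vals, groups))
        assert all(r.df1 == 1 and r.df2 == 37 for r in res)

    def test_constant_values_give_zero_F(self):
        vals = {f"P{i}": (1.0, 1.0) for i in range(8)}
        groups = {f"P{i}": ("High" if i % 2 else "Low") for i in range(8)}
        res = mixed_anova_2x2(long_table(vals, groups))
        assert all(r.F == 0.0 and r.eta2_G == 0.0 for r in res)

    def test_hand_dataset_matches_manual_decomposition(self):
        vals = {
            "P0": (5.0, 3.0), "P1": (6.0, 4.5), "P2": (5.5, 3.5),   # High
            "P3": (4.0, 3.8), "P4": (4.5, 4.1), "P5": (3.9, 3.0),   # Low
        }
        groups = {p: ("High" if p in ("P0", "P1", "P2") else "Low") for p in vals}
        data = long_table(vals, groups)
        res = {r.effect: r for r in mixed_anova_2x2(data)}
        oracle = manual_split_plot(data)
        for effect, (F, df1, df2, eta) in oracle.items():
            assert res[effect].F == pytest.approx(F, abs=1e-8)
            assert res[effect].df1 == df1 and res[effect].df2 == df2
            assert res[effect].eta2_G == pytest.approx(eta, abs=1e-8)

    def test_missing_within_level_names_participant(self):
        data = long_table({"P0": (1, 2), "P1": (2, 1)},
                          {"P0": "High", "P1": "Low"})
        data = data.drop(index=3)
        with pytest.raises(DesignError, match="P1"):
            mixed_anova_2x2(data)

    def test_eta2G_in_unit_interval(self):
        rng = np.random.default_rng(5)
        vals = {f"P{i}": tuple(rng.normal(0, 1, 2)) for i in range(10)}
        groups = {f"P{i}": ("High" if i < 5 else "Low") for i in range(10)}
        for r in mixed_anova_2x2(long_table(vals, groups)):
            assert 0.0 <= r.eta2_G <= 1.0


class TestBayesFactor:
    def test_null_F_closed_form(self):
        n = 39
        assert bf10_bic(0.0, 1, 37, n) == pytest.approx(math.exp(-math.log(n) / 2))

    def test_unit_bf_when_bics_tie(self):
        # (1 + F/df2)^n = n  <=>  delta BIC = 0  <=>  BF10 = 1
        n, df2 = 20, 18
        f = df2 * (n ** (1 / n) - 1)
        assert bf10_bic(f, 1, df2, n) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_F(self):
        bfs = [bf10_bic(f, 1, 37, 39) for f in (0.0, 1.0, 5.0, 20.0, 100.0)]
        assert bfs == sorted(bfs)
        assert bfs[-1] > 1.0 > bfs[0]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bf10_bic(float("nan"), 1, 37, 39)
        with pytest.raises(ValidationError):
            bf10_bic(1.0, 0, 37, 39)


class TestJeffreysLabels:
    @pytest.mark.parametrize("bf,label", [
        (665.12, "decisive"),
        (5.96, "substantial"),
        (17.50, "strong"),
        (2.0, "anecdotal"),
        (1.0, "no evidence"),
        (50.0, "very strong"),
        (1 / 4.13, "substantial (for null)"),
        (0.005, "decisive (for null)"),
    ])
    def test_bands(self, bf, label):
        assert jeffreys_label(bf) == label

    def test_positive_required(self):
        with pytest.raises(ValidationError):
            jeffreys_label(0.0)


class TestConditionSummaries:
    def test_identical_values_zero_width(self):
        data = long_table({f"P{i}": (2.0, 2.0) for i in range(4)},
                          {"P0": "High", "P1": "High", "P2": "Low", "P3": "Low"})
        for s in condition_summaries(data):
            assert s.ci95_low == pytest.approx(s.mean)
            assert s.ci95_high == pytest.approx(s.mean)

    def test_hand_t_interval(self):
        import scipy.stats

        vals = [1.0, 2.0, 3.0, 6.0]
        data = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(4)],
            "difficulty": ["Easy"] * 4,
            "comm_frequency": ["High", "High", "Low", "Low"],
            "value": vals,
        })
        s = condition_summaries(data, factors=("difficulty",))[0]
        m = np.mean(vals)
        half = scipy.stats.t.ppf(0.975, 3) * np.std(vals, ddof=1) / 2
        assert s.mean == pytest.approx(m)
        assert s.ci95_high - s.mean == pytest.approx(half)

    def test_margins_recombine_to_grand_mean(self):
        rng = np.random.default_rng(2)
        vals = {f"P{i}": tuple(rng.normal(0, 1, 2)) for i in range(6)}
        groups = {f"P{i}": ("High" if i < 3 else "Low") for i in range(6)}
        data = long_table(vals, groups)
        summ = condition_summaries(data, factors=("difficulty",))
        weighted = sum(s.mean * s.n for s in summ) / sum(s.n for s in summ)
        assert weighted == pytest.approx(data["value"].mean())

    def test_tiny_margin_rejected(self):
        data = pd.DataFrame({
            "participant_id": ["P0"], "difficulty": ["Easy"],
            "comm_frequency": ["High"], "value": [1.0],
        })
        with pytest.raises(ValidationError):
            condition_summaries(data, factors=("difficulty",))
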