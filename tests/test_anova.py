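"""Cell aggregation, normality screen, and the mixed ANOVA against
independent oracles (explicit sum-of-squares enumeration and pingouin)."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from trunksway import anova as an


def cells_from_matrix(Y, groups, feature="f", direction="AP"):
    """Long-format cells from a subjects x 6 matrix (days 1/3/5 x AM/PM)."""
    rows = []
    for i, (row, g) in enumerate(zip(Y, groups)):
        for k, v in enumerate(row):
            rows.append(
                dict(participant=f"s{i:02d}", group=g, day=[1, 3, 5][k // 2],
                     period=["AM", "PM"][k % 2], direction=direction,
                     feature=feature, value=float(v))
            )
    return pd.DataFrame(rows)


def simulated_cells(n_pg, n_csp, shift=0.0, trend=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pg + n_csp
    groups = ["PG"] * n_pg + ["CSPG"] * n_csp
    base = rng.normal(0, 1, size=(n, 1))
    Y = base + rng.normal(0, 0.8, size=(n, 6)) + trend * np.arange(6)
    Y[n_pg:] += shift
    return cells_from_matrix(Y, groups)


def brute_force_ss(Y, groups):
    """Sum-of-squares decomposition by direct enumeration of the means."""
    n, k = Y.shape
    uniq = sorted(set(groups))
    grand = Y.mean()
    ss = {}
    subj = Y.mean(axis=1)
    ss["between_subj"] = sum(k * (subj[i] - grand) ** 2 for i in range(n))
    ss["group"] = 0.0
    for g in uniq:
        idx = [i for i in range(n) if groups[i] == g]
        mg = np.mean([subj[i] for i in idx])
        ss["group"] += len(idx) * k * (mg - grand) ** 2
    ss["subj_within"] = ss["between_subj"] - ss["group"]
    tm = [Y[:, j].mean() for j in range(k)]
    ss["week"] = sum(n * (tm[j] - grand) ** 2 for j in range(k))
    ss["inter"] = 0.0
    for g in uniq:
        idx = [i for i in range(n) if groups[i] == g]
        mg = np.mean([subj[i] for i in idx])
        for j in range(k):
            cell = np.mean([Y[i, j] for i in idx])
            ss["inter"] += len(idx) * (cell - mg - tm[j] + grand) ** 2
    ss["within"] = sum((Y[i, j] - subj[i]) ** 2 for i in range(n) for j in range(k))
    ss["err_within"] = ss["within"] - ss["week"] - ss["inter"]
    ss["total"] = sum((Y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    return ss


class TestMixedAnovaOracle:
    def test_tiny_fixture_matches_enumeration(self):
        # 2 groups x 2 participants x 6 within levels, values fixed by hand
        Y = np.array(
            [
                [1.0, 2.0, 1.5, 2.5, 1.0, 2.0],
                [2.0, 3.0, 2.5, 3.5, 2.0, 3.0],
                [4.0, 5.0, 4.5, 5.0, 4.0, 5.5],
                [5.0, 6.0, 5.5, 6.5, 5.0, 6.0],
            ]
        )
        groups = ["PG", "PG", "CSPG", "CSPG"]
        tab = an.mixed_anova(cells_from_matrix(Y, groups), "f", "AP",
                             sphericity_correction="never")
        ss = brute_force_ss(Y, groups)
        assert np.isclose(tab.effects["group"].ss, ss["group"])
        assert np.isclose(tab.effects["week"].ss, ss["week"])
        assert np.isclose(tab.effects["week_x_group"].ss, ss["inter"])
        assert np.isclose(tab.effects["group"].ss_error, ss["subj_within"])
        assert np.isclose(tab.effects["week"].ss_error, ss["err_within"])
        # F and np2 from the same decomposition
        f_group = (ss["group"] / 1) / (ss["subj_within"] / 2)
        assert np.isclose(tab.effects["group"].F, f_group)
        assert np.isclose(
            tab.effects["group"].np2, ss["group"] / (ss["group"] + ss["subj_within"])
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_designs_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(0, 1, size=(8, 6))
        groups = ["PG"] * 3 + ["CSPG"] * 5
        tab = an.mixed_anova(cells_from_matrix(Y, groups), "f", "AP",
                             sphericity_correction="never")
        ss = brute_force_ss(Y, groups)
        for eff, key in [("group", "group"), ("week", "week"), ("week_x_group", "inter")]:
            assert np.isclose(tab.effects[eff].ss, ss[key], rtol=1e-10)

    def test_ss_conservation(self):
        cells = simulated_cells(6, 10, shift=0.5, seed=3)
        tab = an.mixed_anova(cells, "f", "AP")
        parts = (
            tab.effects["group"].ss
            + tab.effects["group"].ss_error
            + tab.effects["week"].ss
            + tab.effects["week_x_group"].ss
            + tab.effects["week"].ss_error
        )
        assert np.isclose(parts, tab.ss_total, rtol=1e-8)

    def test_matches_pingouin_unbalanced(self):
        cells = simulated_cells(6, 10, shift=0.4, trend=0.1, seed=5)
        tab = an.mixed_anova(cells, "f", "AP", sphericity_correction="never")
        d = cells.copy()
        d["week"] = d["day"].astype(str) + d["period"]
        aov = pg.mixed_anova(data=d, dv="value", within="week",
                             subject="participant", between="group")
        for eff, src in [("group", "group"), ("week", "week"),
                         ("week_x_group", "Interaction")]:
            ref = aov[aov.Source == src].iloc[0]
            assert np.isclose(tab.effects[eff].F, ref.F)
            assert np.isclose(tab.effects[eff].p, ref.p_unc)
            assert np.isclose(tab.effects[eff].np2, ref.np2)


class TestSphericityMachinery:
    def test_epsilon_bounds(self):
        for seed in range(5):
            cells = simulated_cells(4, 5, seed=seed)
            tab = an.mixed_anova(cells, "f", "AP")
            assert 1.0 / 5 <= tab.epsilon_gg <= 1.0

    def test_gg_shrinks_dfs(self):
        cells = simulated_cells(5, 6, seed=2)
        never = an.mixed_anova(cells, "f", "AP", "never")
        always = an.mixed_anova(cells, "f", "AP", "always")
        assert always.effects["week"].df1 <= never.effects["week"].df1
        assert always.effects["week"].gg_applied

    def test_degenerate_all_identical(self):
        Y = np.full((6, 6), 3.0)
        tab = an.mixed_anova(cells_from_matrix(Y, ["PG"] * 3 + ["CSPG"] * 3), "f", "AP")
        assert tab.degenerate
        assert tab.effects["group"].np2 == 0.0


class TestAggregation:
    def window_rows(self):
        rows = []
        for label, period, v in [
            ("AM1", "AM", 1.0), ("AM2", "AM", 2.0), ("AM3", "AM", 3.0),
            ("Lunch", "Lunch", 99.0), ("PM1", "PM", 4.0),
        ]:
            rows.append(dict(participant="p1", group="PG", day=1, period=period,
                             window=label, direction="AP", feature="sd", value=v))
        return pd.DataFrame(rows)

    def test_mean_over_am_windows(self):
        cells = an.aggregate_cells(self.window_rows())
        am = cells[(cells.period == "AM")].value.iloc[0]
        assert am == 2.0

    def test_lunch_excluded(self):
        cells = an.aggregate_cells(self.window_rows())
        assert set(cells.period) == {"AM", "PM"}

    def test_only_lunch_warns(self):
        rows = self.window_rows()
        with pytest.warns(RuntimeWarning):
            an.aggregate_cells(rows[rows.period == "Lunch"])

    def test_incomplete_grid_names_participant(self):
        cells = simulated_cells(3, 3, seed=1)
        cells = cells[~((cells.participant == "s01") & (cells.day == 3))]
        with pytest.raises(an.UnbalancedDesignError, match="s01"):
            an.mixed_anova(cells, "f", "AP")


class TestShapiroScreen:
    def test_normal_samples_pass(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cells = pd.DataFrame(
                dict(feature="f", direction="AP", group="PG",
                     value=rng.standard_normal(50))
            )
            hits += an.shapiro_wilk_screen(cells).p.iloc[0] > 0.05
        assert hits >= 18

    def test_heavy_tails_rejected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cells = pd.DataFrame(
                dict(feature="f", direction="AP", group="PG",
                     value=rng.standard_t(df=1, size=50))
            )
            hits += an.shapiro_wilk_screen(cells).p.iloc[0] < 0.05
        assert hits >= 18

    def test_constant_skipped(self):
        cells = pd.DataFrame(
            dict(feature="f", direction="AP", group="PG", value=np.ones(10))
        )
        rep = an.shapiro_wilk_screen(cells)
        assert rep.skipped.iloc[0] and rep.reason.iloc[0] == "constant"


class TestEffectSizeCategory:
    @pytest.mark.parametrize(
        "np2,expected",
        [(0.05, "small"), (0.10, "medium"), (0.20, "large"),
         (0.0, "small"), (0.06, "medium"), (0.14, "medium"), (1.0, "large")],
    )
    def test_boundaries(self, np2, expected):
        assert an.effect_size_category(np2) == expected

    @pytest.mark.parametrize("np2", [-0.01, 1.01])
    def test_out_of_range(self, np2):
        with pytest.raises(ValueError):
            an.effect_size_category(np2)


def test_injected_group_shift_detected():
    """A clear between-group shift produces a significant, large group effect
    in nearly all simulated cohorts."""
    hits = 0
    for seed in range(20):
        cells = simulated_cells(6, 10, shift=2.5, seed=100 + seed)
        tab = an.mixed_anova(cells, "f", "AP")
        g = tab.effects["group"]
        hits += (g.p < 0.05) and (g.np2 > 0.14)
    assert hits >= 18
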