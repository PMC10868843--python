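"""Agreement statistics: RMSD, Pearson R, banding, ROM, RM-ANOVA, post-hoc."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imuknee import stats as ast
from imuknee.pipeline import NormalizedCurve


def curve(values):
    return NormalizedCurve(values=np.asarray(values, dtype=float))


class TestRmsd:
    def test_identical_zero(self):
        x = np.sin(np.linspace(0, 6, 101))
        assert ast.rmsd(x, x) == 0.0

    def test_constant_offset(self):
        x = np.linspace(0, 50, 101)
        assert ast.rmsd(x, x + 2.0) == pytest.approx(2.0, abs=1e-12)

    def test_alternating_differences(self):
        # differences alternating 3, 4 -> sqrt((9+16)/2) = 3.5355...
        a = np.zeros(100)
        b = np.tile([3.0, 4.0], 50)
        assert ast.rmsd(a, b) == pytest.approx(np.sqrt(12.5), abs=1e-9)
        assert ast.rmsd(a, b) == pytest.approx(3.5355, abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ast.rmsd(np.zeros(101), np.zeros(100))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1), st.floats(-50, 50))
    def test_symmetric_and_shift_invariant(self, seed, const):
        g = np.random.default_rng(seed)
        a, b = g.normal(size=101), g.normal(size=101)
        assert ast.rmsd(a, b) == pytest.approx(ast.rmsd(b, a), abs=1e-12)
        assert ast.rmsd(a + const, b + const) == pytest.approx(ast.rmsd(a, b), abs=1e-9)


class TestPearson:
    def test_self_correlation_one(self):
        x = np.sin(np.linspace(0, 6, 101))
        assert ast.pearson_r(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        x = np.sin(np.linspace(0, 6, 101))
        assert ast.pearson_r(x, 2 * x + 5) == pytest.approx(1.0, abs=1e-12)
        assert ast.pearson_r(x, -3 * x + 1) == pytest.approx(-1.0, abs=1e-12)

    def test_sin_vs_cos_orthogonal(self):
        t = np.linspace(0, 1, 101, endpoint=False)
        r = ast.pearson_r(np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))
        assert abs(r) < 0.02

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ast.pearson_r(np.ones(101), np.arange(101.0))


class TestBanding:
    @pytest.mark.parametrize(
        "r,band",
        [
            (0.50, "poor"),
            (0.0, "poor"),
            (0.60, "moderate"),
            (0.74, "moderate"),
            (0.75, "good"),
            (0.85, "very good"),
            (0.94, "very good"),
            (0.95, "excellent"),  # boundary assigned upward
            (0.97, "excellent"),
            (1.0, "excellent"),
        ],
    )
    def test_band_boundaries(self, r, band):
        assert ast.stratify_r(r) == band

    def test_negative_banded_poor_with_warning(self):
        with pytest.warns(UserWarning, match="negative"):
            assert ast.stratify_r(-0.3) == "poor"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ast.stratify_r(1.2)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(0, 1))
    def test_every_r_maps_to_exactly_one_band(self, r):
        band = ast.stratify_r(r)
        matches = [
            lbl for lbl, lo, hi in ast.R_BANDS
            if (lo <= r < hi) or (lbl == "excellent" and 0.95 <= r <= 1.0)
        ]
        assert band in matches and len(set(matches)) >= 1


class TestRangeOfMotion:
    def test_sinusoid_twice_amplitude(self):
        t = np.linspace(0, 1, 101)
        assert ast.range_of_motion(7.5 * np.sin(2 * np.pi * t)) == pytest.approx(15.0, abs=1e-9)

    def test_constant_zero(self):
        assert ast.range_of_motion(np.full(101, 4.0)) == 0.0

    def test_ramp(self):
        assert ast.range_of_motion(np.linspace(10, 70, 101)) == pytest.approx(60.0)

    def test_invariant_under_centering(self):
        from imuknee.pipeline import mean_center

        x = np.random.default_rng(0).normal(size=101).cumsum()
        c = curve(x)
        assert ast.range_of_motion(mean_center(c)) == ast.range_of_motion(c)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ast.range_of_motion(np.array([]))


def hand_rm_anova_f(table):
    """Brute-force sums-of-squares oracle, spelled out independently."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.mean()
    ss_between_methods = sum(n * (table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_between_subjects = sum(k * (table[i, :].mean() - grand) ** 2 for i in range(n))
    ss_total = sum((x - grand) ** 2 for x in table.ravel())
    ss_err = ss_total - ss_between_methods - ss_between_subjects
    return (ss_between_methods / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestRmAnova:
    TOY = np.array(
        [[60.0, 58.0, 57.5], [72.0, 70.5, 71.0], [65.0, 66.0, 63.0], [80.0, 77.0, 76.0]]
    )

    def test_identical_methods_f_zero_p_one(self):
        rom = np.tile(np.array([[60.0], [70.0], [80.0]]), (1, 3))
        res = ast.rm_anova(rom)
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_toy_table_matches_hand_sums_of_squares(self):
        res = ast.rm_anova(self.TOY)
        assert res.f_statistic == pytest.approx(hand_rm_anova_f(self.TOY), abs=1e-9)
        assert (res.df_num, res.df_den) == (2, 6)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        long = pd.DataFrame(
            [
                {"subject": i, "method": f"m{j}", "rom": self.TOY[i, j]}
                for i in range(4)
                for j in range(3)
            ]
        )
        sm = AnovaRM(long, depvar="rom", subject="subject", within=["method"]).fit()
        res = ast.rm_anova(self.TOY)
        assert res.f_statistic == pytest.approx(float(sm.anova_table["F Value"].iloc[0]), abs=1e-9)
        assert res.p_value == pytest.approx(float(sm.anova_table["Pr > F"].iloc[0]), abs=1e-9)

    def test_matches_pingouin(self):
        import pingouin as pg

        g = np.random.default_rng(42)
        table = g.normal(70, 10, size=(8, 3))
        long = pd.DataFrame(
            [
                {"subject": i, "method": f"m{j}", "rom": table[i, j]}
                for i in range(8)
                for j in range(3)
            ]
        )
        aov = pg.rm_anova(data=long, dv="rom", within="method", subject="subject")
        res = ast.rm_anova(table)
        assert res.f_statistic == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_random_tables_match_hand_oracle(self, seed):
        g = np.random.default_rng(seed)
        table = g.normal(70, 12, size=(g.integers(2, 12), 3))
        assert ast.rm_anova(table).f_statistic == pytest.approx(hand_rm_anova_f(table), abs=1e-9)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ast.rm_anova(np.array([[60.0, 61.0, 62.0]]))

    def test_missing_cell_names_participant(self):
        df = pd.DataFrame(
            {"OMC": [60.0, 70.0], "m_IMU": [59.0, np.nan], "r_IMU": [58.0, 69.0]},
            index=["P01", "P02"],
        )
        with pytest.raises(ValueError, match="P02"):
            ast.rm_anova(df)


def hand_paired_t(a, b):
    """Explicit paired-t formula: t = d̄ / (s_d / √n), CI = d̄ ± t* s_d/√n."""
    from scipy.stats import t as tdist

    d = np.asarray(a) - np.asarray(b)
    n = len(d)
    mean = d.mean()
    sd = np.sqrt(((d - mean) ** 2).sum() / (n - 1))
    se = sd / np.sqrt(n)
    t_stat = mean / se
    p = 2 * tdist.sf(abs(t_stat), n - 1)
    tcrit = tdist.ppf(0.975, n - 1)
    return t_stat, p, (mean - tcrit * se, mean + tcrit * se), mean


class TestPosthoc:
    def test_corrected_threshold(self):
        res = ast.posthoc_bonferroni(np.random.default_rng(0).normal(70, 8, (6, 3)))
        assert res.corrected_threshold == pytest.approx(0.017, abs=1e-12)

    def test_identical_columns_zero_difference(self):
        rom = np.tile(np.array([[60.0], [70.0], [80.0], [65.0]]), (1, 3))
        res = ast.posthoc_bonferroni(rom)
        for comp in res.comparisons:
            assert comp.mean_diff == 0.0
            assert comp.ci_low == comp.ci_high == 0.0
            assert comp.p_value == 1.0

    def test_five_pair_toy_matches_hand_formula(self):
        a = np.array([61.2, 70.4, 58.9, 66.0, 73.3])
        b = np.array([59.8, 68.0, 60.1, 63.2, 70.9])
        c = np.array([60.0, 69.5, 59.0, 64.8, 71.8])
        df = pd.DataFrame({"OMC": a, "m_IMU": b, "r_IMU": c}, index=list("ABCDE"))
        res = ast.posthoc_bonferroni(df)
        cols = {"OMC": a, "m_IMU": b, "r_IMU": c}
        assert [comp.pair for comp in res.comparisons] == list(ast.METHOD_PAIRS)
        for comp in res.comparisons:
            t_stat, p, (lo, hi), mean = hand_paired_t(cols[comp.pair[0]], cols[comp.pair[1]])
            assert comp.t_statistic == pytest.approx(t_stat, abs=1e-9)
            assert comp.p_value == pytest.approx(p, abs=1e-9)
            assert comp.mean_diff == pytest.approx(mean, abs=1e-9)
            assert comp.ci_low == pytest.approx(lo, abs=1e-9)
            assert comp.ci_high == pytest.approx(hi, abs=1e-9)

    def test_ci_brackets_mean(self):
        rom = np.random.default_rng(5).normal(70, 8, (10, 3))
        for comp in ast.posthoc_bonferroni(rom).comparisons:
            assert comp.ci_low <= comp.mean_diff <= comp.ci_high


class TestSummarizeCohort:
    def mk(self, r, rmsd_deg, task="walk", method="r_IMU", plane="sagittal", pid="P01"):
        return ast.AgreementResult(
            participant=pid, task=task, method=method, plane=plane, r=r, rmsd_deg=rmsd_deg
        )

    def test_single_trial_degenerate(self):
        df = ast.summarize_cohort([self.mk(0.9, 4.0)])
        row = df.iloc[0]
        assert row.n == 1 and row.r_mean == 0.9 and row.r_sd == 0.0
        assert row.rmsd_min == row.rmsd_max == 4.0

    def test_two_trials_hand_values(self):
        df = ast.summarize_cohort([self.mk(0.90, 3.0), self.mk(1.00, 5.0, pid="P02")])
        row = df.iloc[0]
        assert row.r_mean == pytest.approx(0.95)
        assert row.r_sd == pytest.approx(0.0707, abs=1e-4)
        assert (row.rmsd_min, row.rmsd_max) == (3.0, 5.0)
        assert row.band == "excellent"

    def test_empty_warns(self):
        with pytest.warns(UserWarning, match="no agreement results"):
            df = ast.summarize_cohort([])
        assert df.empty


class TestAnalyzeAngleTable:
    def make_table(self):
        """Two participants, one task, constructed curves with known stats."""
        t = np.linspace(0, 1, 101)
        base = 40 - 40 * np.cos(2 * np.pi * t)
        rows = []
        for pid, shift in (("P01", 2.0), ("P02", -3.0)):
            for method, extra in (("OMC", 0.0), ("r_IMU", shift)):
                for plane in ("sagittal", "frontal", "transverse"):
                    vals = base + (extra if plane == "sagittal" else 0.0)
                    if plane != "sagittal":
                        vals = 5 * np.sin(2 * np.pi * t)
                    row = {"participant": pid, "task": "squat", "method": method, "plane": plane}
                    row.update({f"pct_{i}": v for i, v in enumerate(vals)})
                    rows.append(row)
        return pd.DataFrame(rows)

    def test_constant_offset_removed_by_centering(self):
        res = ast.analyze_angle_table(self.make_table(), center=True)
        for a in res["agreement"]:
            assert a.rmsd_deg == pytest.approx(0.0, abs=1e-9)
            assert a.r == pytest.approx(1.0, abs=1e-12)

    def test_rom_and_anova_structure(self):
        res = ast.analyze_angle_table(self.make_table(), center=True)
        wide = res["rom"]["squat"]
        assert set(wide.columns) == {"OMC", "r_IMU"}
        np.testing.assert_allclose(wide.to_numpy(), 80.0, atol=1e-9)
        assert res["anova"]["squat"].f_statistic == 0.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="pct_0"):
            ast.analyze_angle_table(
                pd.DataFrame({"participant": [], "task": [], "method": [], "plane": []})
            )
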