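"""Statistics layer: Grubbs, t-tests, Dunnett (vs scipy and Monte-Carlo),
power/sample size (vs statsmodels), and ddCT."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glycoforms.stats import (
    analyze_design,
    anova_dunnett,
    ddct_percent,
    dunnett_pvalue,
    dunnett_pvalue_mc,
    grubbs_critical,
    grubbs_outliers,
    power_two_sample_t,
    sample_size_t,
    two_sample_t,
)


class TestGrubbs:
    def test_critical_values_match_closed_form(self):
        """G_crit = ((n-1)/sqrt(n)) sqrt(t^2/(n-2+t^2)) over n = 3..30."""
        for n in range(3, 31):
            t = sps.t.ppf(1 - 0.05 / (2 * n), n - 2)
            expected = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
            assert grubbs_critical(n, 0.05) == pytest.approx(expected, rel=1e-12)

    def test_gross_outlier_removed(self):
        kept, removed = grubbs_outliers([1, 2, 3, 2, 2, 50], alpha=0.05)
        assert removed == [50.0]
        assert sorted(kept) == [1.0, 2.0, 2.0, 2.0, 3.0]

    def test_small_spread_kept(self):
        kept, removed = grubbs_outliers([1, 2, 3], alpha=0.05)
        assert removed == [] and len(kept) == 3

    def test_constant_list_guarded(self):
        kept, removed = grubbs_outliers([5, 5, 5, 5], alpha=0.05)
        assert removed == []

    def test_n_below_three_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="glycoforms.stats"):
            kept, removed = grubbs_outliers([1.0, 9.0])
        assert kept == [1.0, 9.0] and removed == []
        assert "skipped" in caplog.text

    def test_single_pass_vs_iterative(self):
        values = [10.0, 10.2, 9.8, 10.1, 9.9, 10.0, 10.3, 100.0, 55.0]
        _, one = grubbs_outliers(values, max_rounds=1)
        _, full = grubbs_outliers(values)
        assert one == [100.0]
        assert full == [100.0, 55.0]


class TestTwoSampleT:
    def test_textbook_pair(self):
        res = two_sample_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.p_value == pytest.approx(
            2 * sps.t.sf(1.224744871, 4), abs=1e-6
        )

    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_swap_flips_sign_same_p(self):
        a = two_sample_t([1, 2, 3], [4, 5, 7])
        b = two_sample_t([4, 5, 7], [1, 2, 3])
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_variance_convention(self, caplog):
        with caplog.at_level("WARNING", logger="glycoforms.stats"):
            res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_welch_flag(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [10.0, 30.0, 50.0]
        ours = two_sample_t(x, y, welch=True)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def _design(groups: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": g, "value": v} for g, vals in groups.items() for v in vals]
    )


class TestDunnett:
    def test_two_groups_reduce_to_pooled_t(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        _, comps = anova_dunnett(_design({"ref": x, "trt": y}), "ref")
        t_ref = sps.ttest_ind(y, x, equal_var=True)
        assert comps[0].p_value == pytest.approx(t_ref.pvalue, abs=1e-6)
        assert comps[0].statistic == pytest.approx(t_ref.statistic, abs=1e-9)

    def test_identical_groups_null(self):
        base = [1.0, 2.0, 3.0, 4.0, 2.5]
        anova, comps = anova_dunnett(
            _design({"a": base, "b": base, "c": base}), "a"
        )
        assert anova.statistic == pytest.approx(0.0, abs=1e-12)
        for c in comps:
            assert c.p_value == pytest.approx(1.0, abs=1e-9)

    def test_anova_f_equals_t_squared_on_two_groups(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 9), rng.normal(0.7, 1, 9)
        anova, _ = anova_dunnett(_design({"a": x, "b": y}), "a")
        t = sps.ttest_ind(x, y, equal_var=True)
        assert anova.statistic == pytest.approx(t.statistic**2, rel=1e-10)

    def test_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(12)
        groups = {g: rng.normal(m, 1, 10) for g, m in [("r", 0), ("a", 0.5), ("b", 1.0)]}
        _, comps = anova_dunnett(_design(groups), "r")
        nu = 27
        for c in comps:
            raw = 2 * sps.t.sf(abs(c.statistic), nu)
            assert c.p_value >= raw - 1e-12

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(13)
        ref = rng.normal(0, 1, 10)
        a = rng.normal(1, 1, 10)
        b = rng.normal(0.5, 1, 12)  # unbalanced
        _, comps = anova_dunnett(_design({"ref": ref, "a": a, "b": b}), "ref")
        scipy_res = sps.dunnett(a, b, control=ref, rng=1)
        ours = {c.label.split(" ")[0]: c.p_value for c in comps}
        assert ours["a"] == pytest.approx(scipy_res.pvalue[0], abs=5e-4)
        assert ours["b"] == pytest.approx(scipy_res.pvalue[1], abs=5e-4)

    def test_matches_monte_carlo_oracle(self):
        """Balanced (10,10,10), means (0,0,1), sd 1: the quadrature adjusted
        p agrees with a seeded 1e5-draw Monte-Carlo evaluation."""
        rng = np.random.default_rng(14)
        groups = {
            "r": rng.normal(0, 1, 10),
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(1, 1, 10),
        }
        _, comps = anova_dunnett(_design(groups), "r")
        for c in comps:
            p_mc = dunnett_pvalue_mc(c.statistic, nu=27, n_ref=10, ns=[10, 10],
                                     n_draws=100_000, seed=0)
            se = math.sqrt(max(p_mc * (1 - p_mc), 1e-6) / 100_000)
            assert c.p_value == pytest.approx(p_mc, abs=3 * se)

    def test_reference_absent_rejected(self):
        with pytest.raises(ValueError):
            anova_dunnett(_design({"a": [1, 2, 3], "b": [2, 3, 4]}), "zzz")

    def test_one_comparison_equals_t_sf_analytically(self):
        # with a single comparison the max-|t| distribution is Student's t
        for t_obs, nu in [(1.5, 8), (2.5, 20), (3.2, 40)]:
            assert dunnett_pvalue(t_obs, nu, 5, [5]) == pytest.approx(
                2 * sps.t.sf(t_obs, nu), abs=1e-8
            )


class TestPowerSampleSize:
    def test_reference_sample_sizes(self):
        assert sample_size_t(1.66, 0.05, 0.80) == 7
        assert sample_size_t(0.5, 0.05, 0.80) == 64

    def test_returned_n_is_minimal(self):
        for d in (0.5, 0.9, 1.66):
            n = sample_size_t(d, 0.05, 0.80)
            assert power_two_sample_t(n, d) >= 0.80
            assert power_two_sample_t(n - 1, d) < 0.80

    def test_monotone_in_effect_size(self):
        sizes = [sample_size_t(d) for d in (0.4, 0.8, 1.2, 1.66, 2.5)]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        solver = TTestIndPower()
        for d in (0.5, 1.0, 1.66):
            n_sm = math.ceil(solver.solve_power(effect_size=d, alpha=0.05, power=0.80))
            assert sample_size_t(d) == n_sm

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_size_t(-1.0)
        with pytest.raises(ValueError):
            sample_size_t(1.0, alpha=1.5)
        with pytest.raises(ValueError, match="unattainable"):
            sample_size_t(1e-6, 0.05, 0.99, max_n=50)


class TestDdct:
    def test_reference_sample_at_its_mean_is_100(self):
        out = ddct_percent([25.0, 26.0], [20.0, 21.0], [True, True])
        assert np.mean(out) >= 100.0  # geometric centring: mean of 2^x >= 100
        out_single = ddct_percent([25.0], [20.0], [True])
        assert out_single[0] == pytest.approx(100.0)

    def test_one_cycle_doubles_or_halves(self):
        # reference dCT = 5; sample dCT 4 -> 200%, dCT 6 -> 50%
        out = ddct_percent([25.0, 24.0, 26.0], [20.0, 20.0, 20.0],
                           [True, False, False])
        assert out[1] == pytest.approx(200.0)
        assert out[2] == pytest.approx(50.0)

    def test_missing_housekeeping_excluded(self, caplog):
        with caplog.at_level("WARNING", logger="glycoforms.stats"):
            out = ddct_percent([25.0, 25.0], [20.0, np.nan], [True, False])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ddct_percent([25.0], [20.0], [False])

    def test_median_centring_option(self):
        out = ddct_percent([25.0, 26.0, 30.0], [20.0, 20.0, 20.0],
                           [True, True, True], center="median")
        assert sorted(out)[1] == pytest.approx(100.0)


class TestAnalyzeDesign:
    def test_three_groups_use_dunnett_two_use_t(self):
        rng = np.random.default_rng(15)
        rows = []
        for g, mu in [("Sham-Pla", 0.0), ("OVX-Pla", 0.0), ("OVX-E2", 1.0)]:
            for i, v in enumerate(rng.normal(mu, 1, 7)):
                rows.append({"mouse": f"{g}-{i}", "group": g, "readout": "IgG",
                             "value": v})
        design = pd.DataFrame(rows)
        table, report = analyze_design(design, reference="OVX-Pla")
        assert set(table["test"]) == {"dunnett"}
        assert report["readouts"]["IgG"]["test"] == "anova_dunnett"

        two = design[design["group"] != "Sham-Pla"]
        table2, report2 = analyze_design(two, reference="OVX-Pla")
        assert set(table2["test"]) == {"student_t"}

    def test_outliers_removed_before_comparison(self):
        rows = (
            [{"mouse": f"a{i}", "group": "A", "readout": "r", "value": v}
             for i, v in enumerate([1, 2, 3, 2, 2, 50])]
            + [{"mouse": f"b{i}", "group": "B", "readout": "r", "value": v}
               for i, v in enumerate([1.5, 2.5, 2.0, 1.8, 2.2, 2.1])]
        )
        table, report = analyze_design(pd.DataFrame(rows), reference="B")
        assert report["readouts"]["r"]["outliers_removed"]["A"] == [50.0]
        assert table["outliers_removed"].iloc[0] == 1
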