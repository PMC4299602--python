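"""The delta-V statistic, binned Wilcoxon/Fisher comparison, classification,
condition invariance and the budded-phase analysis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sizescreen import (
    binned_offset,
    budded_phase_control,
    classify_strain,
    condition_invariance,
    delta_v,
    overlap_bins,
    size_control_regression,
    strain_summary,
)
from sizescreen.size_control import (
    NoOverlapError,
    SparseBinsError,
    doubling_time_estimate,
    expected_false_positives,
    fisher_combine,
    wilcoxon_rank_sum,
)
from sizescreen.simkit import SimConfig, simulate_lineage

from conftest import cohort


class TestDeltaV:
    @pytest.mark.parametrize(
        "vb, vs, expected",
        [(30.0, 45.0, math.log(1.5)), (25.0, 25.0, 0.0), (20.0, 40.0, math.log(2.0))],
    )
    def test_closed_form(self, vb, vs, expected):
        assert delta_v(vb, vs) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_volume(self):
        with pytest.raises(ValueError):
            delta_v(0.0, 40.0)


class TestOverlapBins:
    def uniform_with_decile_interval(self, lo, hi, n=1001):
        # linspace(a, b) has 10th/90th percentiles at a + 0.1/0.9 * (b - a).
        span = (hi - lo) / 0.8
        a = lo - 0.1 * span
        return np.linspace(a, a + span, n)

    def test_interval_intersection(self):
        ref = self.uniform_with_decile_interval(10.0, 30.0)
        mut = self.uniform_with_decile_interval(20.0, 40.0)
        edges = overlap_bins(ref, mut, n_bins=10)
        assert np.allclose(edges, np.arange(20.0, 31.0), atol=1e-6)

    def test_identical_samples_use_own_interval(self):
        x = self.uniform_with_decile_interval(10.0, 30.0)
        edges = overlap_bins(x, x, n_bins=10)
        assert edges[0] == pytest.approx(10.0, abs=1e-6)
        assert edges[-1] == pytest.approx(30.0, abs=1e-6)

    def test_disjoint_intervals(self):
        with pytest.raises(NoOverlapError):
            overlap_bins(np.linspace(0, 1, 101), np.linspace(2, 3, 101))


class TestWilcoxon:
    def exact_two_sided_p(self, x, y):
        """Enumeration oracle: distribution of the rank sum over all
        C(n+m, n) assignments of the pooled ranks."""
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        n = len(x)
        observed = ranks[:n].sum()
        sums = [sum(c) for c in itertools.combinations(ranks, n)]
        mean = np.mean(sums)
        dev = abs(observed - mean)
        extreme = sum(abs(s - mean) >= dev - 1e-12 for s in sums)
        return extreme / len(sums)

    def test_exact_small_sample(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert wilcoxon_rank_sum(np.array(x), np.array(y)) == pytest.approx(0.1)
        assert self.exact_two_sided_p(x, y) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.5, 1, 6)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(self.exact_two_sided_p(x, y))

    def test_complete_ties(self):
        assert wilcoxon_rank_sum(np.ones(10), np.ones(12)) == 1.0


class TestFisherCombination:
    def test_closed_form_ten_halves(self):
        x2, df, p = fisher_combine([0.5] * 10)
        assert x2 == pytest.approx(20 * math.log(2.0))
        assert df == 20
        assert p == pytest.approx(stats.chi2.sf(20 * math.log(2.0), 20))

    def test_uniform_p_is_calibrated(self):
        # Under the null, -2*sum(ln U_i) is exactly chi-square(2k): the
        # combined P of uniform draws is itself uniform.
        rng = np.random.default_rng(1)
        ps = [fisher_combine(rng.uniform(size=10))[2] for _ in range(500)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestBinnedOffset:
    def test_self_comparison_is_null(self, sizer_cohort):
        ref = sizer_cohort
        comp = binned_offset(ref, ref.copy(), "g1_duration")
        assert np.allclose(comp.per_bin_median_diff[np.isfinite(comp.per_bin_median_diff)], 0.0)
        assert comp.mean_offset == 0.0
        assert comp.combined_p >= 0.5
        assert comp.fisher_df == 2 * np.isfinite(comp.per_bin_p).sum()

    def test_sparse_bins_error(self):
        rec = cohort(5, n=60)
        tiny = rec.iloc[:6]
        with pytest.raises(SparseBinsError):
            binned_offset(rec, tiny, "g1_duration", min_count=30)

    def test_injected_g1_offset_recovered(self):
        tau0 = math.log(40.0) / 0.007
        ref = cohort(31, control_mode="size_programmed")
        for delta in (10.0, -10.0):
            mut = cohort(32, control_mode="size_programmed", size_programmed_tau0=tau0 + delta)
            comp = binned_offset(ref, mut, "g1_duration")
            assert comp.mean_offset == pytest.approx(delta, abs=1.0)

    def test_injected_delta_v_offset_recovered(self):
        c0 = math.log(40.0) - 0.5 * math.log(25.0)
        ref = cohort(41, control_mode="weak_sizer")
        for delta in (0.2, -0.2):
            mut = cohort(42, control_mode="weak_sizer", weak_sizer_intercept=c0 + delta)
            comp = binned_offset(ref, mut, "delta_v")
            assert comp.mean_offset == pytest.approx(delta, abs=0.02)


class TestSizeControlRegression:
    def test_checkpoint_slope_minus_one(self, sizer_cohort):
        fit = size_control_regression(sizer_cohort, "delta_v")
        lo, hi = fit.slope_ci()
        assert lo <= -1.0 <= hi

    def test_timer_slope_zero(self):
        rec = cohort(5, n=3000, control_mode="timer", birth_mu=math.log(20.0))
        fit = size_control_regression(rec, "delta_v")
        lo, hi = fit.slope_ci()
        assert lo <= 0.0 <= hi

    @pytest.mark.parametrize("gain", [0.3, 0.5, 0.8])
    def test_weak_sizer_slope_is_gain_minus_one(self, gain):
        rec = cohort(
            int(gain * 100),
            n=3000,
            control_mode="weak_sizer",
            weak_sizer_gain=gain,
            weak_sizer_intercept=math.log(40.0) - gain * math.log(20.0),
            birth_mu=math.log(20.0),
        )
        fit = size_control_regression(rec, "delta_v")
        lo, hi = fit.slope_ci()
        assert lo <= gain - 1.0 <= hi

    def test_insufficient_records(self):
        rec = cohort(5, n=40).iloc[:10]
        with pytest.raises(ValueError):
            size_control_regression(rec)


class TestClassification:
    def test_null_replicate_is_normal(self):
        res = classify_strain(cohort(1000), cohort(1001))
        assert res.category == "normal/normal"
        assert res.regulator_label == "none"

    def test_lowered_threshold_is_negative_regulator(self):
        ref = cohort(50)
        mut = cohort(51, threshold_volume=32.0)
        res = classify_strain(ref, mut)
        assert res.g1_call == "shorter"
        assert res.dv_call == "decreased"
        assert res.regulator_label == "negative"

    def test_raised_timer_is_positive_regulator(self):
        ref = cohort(52, control_mode="timer")
        mut = cohort(53, control_mode="timer", timer_mean=78.0)
        res = classify_strain(ref, mut)
        assert res.g1_call == "longer"
        assert res.dv_call == "increased"
        assert res.regulator_label == "positive"

    def test_shorter_g1_alone_is_not_negative(self):
        # The label demands both calls; construct the result invariant
        # directly from a G1-only perturbation of a timer strain.
        ref = cohort(54, control_mode="timer", timer_sd=8.0)
        mut = cohort(55, control_mode="timer", timer_mean=45.0, timer_sd=8.0)
        res = classify_strain(ref, mut)
        if res.dv_call == "normal":
            assert res.regulator_label != "negative"

    def test_wild_type_doubling_time_in_band(self, wt_lineage):
        _, rec = wt_lineage
        td = doubling_time_estimate(rec)
        assert 86.0 <= td <= 124.0

    def test_expected_false_positive_count(self):
        assert expected_false_positives(0.001, 800, 2) == pytest.approx(1.6)


@pytest.fixture(scope="module")
def two_rates():
    kw = dict(
        control_mode="size_programmed",
        n_founders=800,
        movie_length=600.0,
        max_cells=32,
        birth_mu=math.log(20.0),
        size_programmed_tau0=math.log(40.0) / 0.007,
        size_programmed_tau1=1.0 / 0.007,
    )
    fast = simulate_lineage(SimConfig(seed=11, **kw))
    slow = simulate_lineage(SimConfig(seed=12, mean_growth_rate=0.0049, **kw))
    fast = fast[fast["generation"] == 0]
    slow = slow[slow["generation"] == 0]
    return fast, slow


class TestConditionInvariance:

    def test_g1_at_matched_birth_size_is_growth_rate_invariant(self, two_rates):
        fast, slow = two_rates
        tab = condition_invariance({"fast": fast, "slow": slow}, "g1_duration")
        p = tab["p_fast_vs_slow"].dropna()
        assert (p >= 0.001).sum() >= 9

    def test_delta_v_scales_with_growth_rate(self, two_rates):
        fast, slow = two_rates
        tab = condition_invariance({"fast": fast, "slow": slow}, "delta_v")
        ratio = (tab["median_fast"] / tab["median_slow"]).dropna()
        assert np.median(ratio) == pytest.approx(0.007 / 0.0049, rel=0.1)

    def test_single_condition_no_tests(self, two_rates):
        fast, _ = two_rates
        tab = condition_invariance({"only": fast}, "g1_duration")
        assert not any(c.startswith("p_") for c in tab.columns)
        assert "median_only" in tab.columns


class TestBuddedPhaseControl:
    def eight_strains(self, slope, noise=15.0, base_seed=100):
        strains = {}
        for i, vstar in enumerate([1400, 1600, 1800, 2000, 2100, 2200, 2400, 2600]):
            cfg = SimConfig(
                seed=base_seed + i,
                n_founders=300,
                strain_id=f"s{i}",
                threshold_volume=float(vstar),
                birth_mu=math.log(0.625 * vstar),
                budded_base=85.0,
                budded_size_slope=slope,
                budded_noise_sd=noise,
            )
            strains[f"s{i}"] = simulate_lineage(cfg)
        return strains

    def test_generator_slope_recovered(self):
        fit, curve = budded_phase_control(self.eight_strains(0.01), n_per_strain=300, seed=5)
        assert abs(fit.slope - (-0.01)) <= 2 * fit.slope_se
        assert fit.n == 8 * 300
        assert len(curve) == 10

    def test_null_slope_and_no_g1_budded_coupling(self):
        strains = self.eight_strains(0.0, base_seed=200)
        fit, _ = budded_phase_control(strains, n_per_strain=300, seed=5)
        assert abs(fit.slope) <= 2 * fit.slope_se
        d = strains["s0"]
        r = stats.pearsonr(
            d["budding_time"] - d["birth_time"], d["division_time"] - d["budding_time"]
        )
        assert abs(r.statistic) < 0.1

    def test_seeded_subsample_is_deterministic(self):
        strains = self.eight_strains(0.01)
        fit1, _ = budded_phase_control(strains, n_per_strain=300, seed=9)
        fit2, _ = budded_phase_control(strains, n_per_strain=300, seed=9)
        assert fit1 == fit2


class TestStrainSummary:
    def single_cell(self):
        return pd.DataFrame(
            [
                {
                    "strain_id": "x",
                    "cell_id": 0,
                    "mother_id": -1,
                    "generation": 0,
                    "cell_role": "daughter",
                    "birth_time": 0.0,
                    "birth_volume": 20.0,
                    "budding_time": 60.0,
                    "budding_volume": 40.0,
                    "division_time": 120.0,
                    "division_volume": 60.0,
                    "growth_rate": 0.007,
                    "censored": False,
                }
            ]
        )

    def test_single_cell_echoed(self):
        s = strain_summary(self.single_cell())
        assert s["median_birth_volume"] == 20.0
        assert s["median_budding_volume"] == 40.0
        assert s["median_g1"] == 60.0
        assert s["median_budded"] == 60.0

    def test_idempotent_on_duplicates(self):
        one = strain_summary(self.single_cell())
        two = strain_summary(pd.concat([self.single_cell()] * 2, ignore_index=True))
        for key in ("median_birth_volume", "mean_g1", "median_budded"):
            assert one[key] == two[key]
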