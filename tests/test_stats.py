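"""Kruskal-Wallis implementation against hand computation, enumeration and scipy."""

import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from terminvest import synthetic_data as synth
from terminvest.errors import DomainError, InsufficientDataError
from terminvest.growth import fit_plate
from terminvest.stats import chisq_sf, daily_tests, kruskal_wallis, kw_permutation_p
from terminvest.synthetic_data import ExperimentDesign, GrowthBaseline


class TestKruskalWallis:
    def test_hand_computed_two_group_case(self):
        """Ranks 1-3 vs 4-6: H = 12/(6*7) * (6^2+15^2)/3 - 21 = 27/7."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.h == pytest.approx(27 / 7, abs=1e-12)
        assert res.df == 1
        assert res.tie_correction == 1.0

    def test_all_values_identical_is_the_no_evidence_limit(self):
        res = kruskal_wallis([[5, 5], [5, 5]])
        assert res.h == 0.0 and res.p_chisq == 1.0

    def test_four_groups_have_three_degrees_of_freedom(self, rng):
        res = kruskal_wallis([rng.normal(size=6) for _ in range(4)])
        assert res.df == 3

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            groups = [rng.integers(0, 6, size=rng.integers(4, 10)) for _ in range(3)]
            if len(np.unique(np.concatenate(groups))) == 1:
                continue
            ours = kruskal_wallis(groups)
            ref = scipy.stats.kruskal(*groups)
            assert ours.h == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_chisq == pytest.approx(ref.pvalue, abs=1e-10)

    @given(st.sampled_from(["exp", "cube", "logistic"]))
    @settings(max_examples=10, deadline=None)
    def test_invariant_under_monotone_transforms(self, transform):
        rng = np.random.default_rng(99)
        groups = [rng.normal(size=8) for _ in range(3)]
        f = {"exp": np.exp, "cube": lambda x: x**3, "logistic": lambda x: 1 / (1 + np.exp(-x))}[
            transform
        ]
        assert kruskal_wallis(groups).h == pytest.approx(
            kruskal_wallis([f(g) for g in groups]).h, abs=1e-10
        )

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            kruskal_wallis([[1, 2, 3]])

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            kruskal_wallis([[1, 2], []])


class TestChiSquareTail:
    def test_against_numerical_integration(self):
        """Upper-tail probability agrees with direct pdf integration to 1e-8."""
        for df in range(1, 11):
            for h in [0.0, 0.5, 2.0, 7.81, 15.0, 30.0]:
                oracle, _ = scipy.integrate.quad(
                    lambda x: scipy.stats.chi2.pdf(x, df), h, np.inf, limit=200
                )
                assert chisq_sf(h, df) == pytest.approx(oracle, abs=1e-8)


class TestPermutationP:
    def test_exact_enumeration_of_separated_groups(self):
        """Only the observed split and its mirror attain the maximal H: 2/20."""
        assert kw_permutation_p([[1, 2, 3], [4, 5, 6]]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert kw_permutation_p([[3, 3], [3, 3]]) == 1.0

    def test_monte_carlo_approaches_exact(self):
        p = kw_permutation_p([[1, 2, 3], [4, 5, 6]], n_permutations=9999, seed=1)
        assert p == pytest.approx(0.1, abs=0.02)

    def test_chisq_and_permutation_agree_under_null(self, rng):
        """Balanced n=12 null groups: the chi-square approximation tracks the
        permutation reference closely."""
        diffs = []
        for i in range(100):
            groups = [rng.normal(size=12) for _ in range(3)]
            res = kruskal_wallis(groups)
            p_perm = kw_permutation_p(groups, n_permutations=4999, seed=i)
            diffs.append(abs(res.p_chisq - p_perm))
        assert max(diffs) < 0.03

    def test_type_one_error_is_calibrated(self, rng):
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            groups = [rng.normal(size=10) for _ in range(4)]
            rejections += kruskal_wallis(groups).p_chisq <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.08


class TestDailyTests:
    def test_df_structure_of_the_design(self, noisy_dataset):
        curves, _ = noisy_dataset
        dt_table, _ = fit_plate(curves)
        all_four = daily_tests(dt_table, grouping="all-four")
        exposed = daily_tests(dt_table, grouping="exposed-only")
        assert list(all_four["df"]) == [3, 3, 3, 3]
        assert list(exposed["df"]) == [2, 2, 2, 2]
        assert not all_four["flagged"].any()

    def test_day_with_missing_groups_is_flagged(self):
        dt_table = pd.DataFrame(
            {"Day": [1, 1, 1, 2, 2], "Phages": ["a", "a", "b", "a", "a"], "dt": [1, 2, 3, 4, 5]}
        )
        out = daily_tests(dt_table, grouping="all-four")
        assert not out.loc[out["day"] == 1, "flagged"].item()
        assert out.loc[out["day"] == 2, "flagged"].item()

    def test_unknown_grouping_rejected(self, noisy_dataset):
        curves, _ = noisy_dataset
        dt_table, _ = fit_plate(curves)
        with pytest.raises(DomainError):
            daily_tests(dt_table, grouping="pairs")

    def test_day1_effect_detected_day4_not(self):
        """Strong day-1 rate increase (1.9x at the highest density) is
        declared significant while the no-effect day is not, in >= 90% of
        seeds — the power pattern the daily rank tests must resolve."""
        effect = {
            1: {"control": 1.0, "ratio_1_10": 1.5, "ratio_1_2": 1.7, "ratio_1_1": 1.9},
            2: {t: 1.0 for t in synth.TREATMENTS},
        }
        design = ExperimentDesign(n_days=2)
        baseline = GrowthBaseline(noise_sd=0.005)
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            curves, _ = synth.generate_growth_dataset(design, effect, seed=seed, baseline=baseline)
            dt_table, _ = fit_plate(curves)
            out = daily_tests(dt_table, grouping="all-four").set_index("day")
            hits += (out.loc[1, "p_chisq"] < 0.05) and (out.loc[2, "p_chisq"] > 0.05)
        assert hits >= 0.9 * n_seeds
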