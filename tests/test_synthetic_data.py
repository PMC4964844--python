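"""Generators: determinism, invariants, truth recoverability, effect patterns."""

import numpy as np
import pandas as pd
import pytest

from terminvest import synthetic_data as synth
from terminvest.cytometry import ks_two_sample, summarize_table
from terminvest.errors import DomainError, InvalidDesignError
from terminvest.growth import fit_plate
from terminvest.synthetic_data import (
    CytometryTruth,
    ExperimentDesign,
    GrowthBaseline,
    default_cytometry_truth,
    generate_binding_counts,
    generate_cytometry_dataset,
    generate_growth_dataset,
)


class TestExperimentDesign:
    def test_defaults_mirror_the_study_layout(self):
        d = ExperimentDesign()
        assert d.treatments == ("control", "ratio_1_10", "ratio_1_2", "ratio_1_1")
        assert d.phage_density_per_ml["ratio_1_2"] == 5e6
        assert d.n_days == 4 and d.replicates_per_treatment == 6
        assert d.reads_per_day == 250 and d.read_span_h == 24.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"replicates_per_treatment": 0},
            {"reads_per_day": 2},
            {"n_days": 0},
            {"treatments": ("a", "a"), "phage_density_per_ml": {"a": 0}},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(InvalidDesignError):
            ExperimentDesign(**kwargs)


class TestGrowthGenerator:
    def test_byte_identical_under_same_seed(self):
        a_curves, a_truth = generate_growth_dataset(seed=9)
        b_curves, b_truth = generate_growth_dataset(seed=9)
        assert a_curves.to_csv(index=False) == b_curves.to_csv(index=False)
        assert a_truth.to_csv(index=False) == b_truth.to_csv(index=False)
        c_curves, _ = generate_growth_dataset(seed=10)
        assert a_curves.to_csv(index=False) != c_curves.to_csv(index=False)

    def test_layout_and_positivity(self):
        curves, truth = generate_growth_dataset(seed=2)
        assert curves["well"].nunique() == 96
        assert (curves["od650"] > 0).all()
        assert curves.groupby("well").size().eq(250).all()
        assert len(truth) == 96 and (truth["r_per_h"] > 0).all()

    def test_noiseless_curves_recover_truth_exactly(self, noiseless_dataset):
        curves, truth = noiseless_dataset
        _, diagnostics = fit_plate(curves)
        diag = pd.DataFrame(diagnostics).merge(truth, on="well")
        assert np.max(np.abs(diag["slope"] / diag["r_per_h"] - 1)) < 1e-6

    def test_noisy_recovery_within_five_percent_median(self, noisy_dataset):
        """At the 2%-of-K noise stress level the estimator still recovers
        the true rates with small median relative error."""
        curves, truth = noisy_dataset
        _, diagnostics = fit_plate(curves)
        diag = pd.DataFrame(diagnostics)[["well", "slope"]].merge(truth, on="well")
        rel_err = np.abs(diag["slope"] / diag["r_per_h"] - 1)
        assert rel_err.median() <= 0.05

    def test_day1_multiplier_accelerates_exposed_growth(self):
        """Day-1 rate multiplier 1.9 on exposed wells shows up as shorter
        estimated doubling times than the control's."""
        effect = {
            1: {"control": 1.0, "ratio_1_10": 1.9, "ratio_1_2": 1.9, "ratio_1_1": 1.9},
        }
        design = ExperimentDesign(n_days=1)
        curves, _ = generate_growth_dataset(design, effect, seed=42)
        dt_table, _ = fit_plate(curves)
        means = dt_table.groupby("Phages")["dt"].mean()
        assert (means.drop("control") < means["control"]).all()

    def test_nonpositive_multiplier_rejected(self):
        effect = {1: {"control": 0.0}}
        with pytest.raises(InvalidDesignError):
            generate_growth_dataset(ExperimentDesign(n_days=1), effect, seed=0)


class TestCytometryGenerator:
    def test_deterministic_and_sized(self):
        truth = default_cytometry_truth(ExperimentDesign(n_days=2), events=500)
        a = generate_cytometry_dataset(truth, seed=4)
        b = generate_cytometry_dataset(truth, seed=4)
        assert a.equals(b)
        assert a.groupby(["day", "treatment"]).size().eq(500).all()

    def test_null_samples_are_indistinguishable(self):
        """Two treatments generated from identical distributions pass the
        two-sample test at alpha=0.05 in >= 90% of seeds (the permutation
        seed is decoupled from the generation seed)."""
        passes = 0
        n_seeds = 100
        for seed in range(1, n_seeds + 1):
            truth = CytometryTruth(
                fsc_meanlog={(1, "a"): 2.0, (1, "b"): 2.0},
                ssc_meanlog={(1, "a"): 2.0, (1, "b"): 2.0},
                events=10_000,
            )
            table = generate_cytometry_dataset(truth, seed=seed)
            samples = {t: g["fsc"].to_numpy() for t, g in table.groupby("treatment")}
            res = ks_two_sample(samples["a"], samples["b"], n_permutations=199, seed=seed + 10_000)
            passes += res.p_perm > 0.05
        assert passes >= 0.9 * n_seeds

    def test_mean_ratio_tracks_the_configured_shift(self):
        """A true 2.5x control:treated mean size ratio is estimated inside
        the 2-3x band for >= 95% of seeds at 10^4 events."""
        in_band = 0
        n_seeds = 40
        for seed in range(n_seeds):
            truth = default_cytometry_truth(
                ExperimentDesign(n_days=1), size_ratio_by_day={1: 2.5}, events=10_000
            )
            table = generate_cytometry_dataset(truth, seed=seed)
            s = summarize_table(table).set_index("treatment")
            ratio = s.loc["control", "mean_fsc"] / s.loc["ratio_1_1", "mean_fsc"]
            in_band += 2.0 <= ratio <= 3.0
        assert in_band >= 0.95 * n_seeds

    def test_zero_dispersion_rejected(self):
        with pytest.raises(InvalidDesignError):
            CytometryTruth(
                fsc_meanlog={(1, "a"): 1.0}, ssc_meanlog={(1, "a"): 1.0}, fsc_sdlog=0.0
            )

    def test_zero_events_rejected(self):
        with pytest.raises(InvalidDesignError):
            default_cytometry_truth(events=0)


class TestBindingCounts:
    def test_zero_mean_gives_all_zeros(self):
        assert not generate_binding_counts(0.0, 100, seed=1).any()

    def test_poisson_mean_converges(self):
        counts = generate_binding_counts(1000.0, 100_000, seed=2)
        assert abs(counts.mean() / 1000.0 - 1) < 0.01
        assert (counts >= 0).all()

    def test_empty_request(self):
        assert generate_binding_counts(5.0, 0, seed=3).size == 0

    def test_negative_mean_rejected(self):
        with pytest.raises(DomainError):
            generate_binding_counts(-1.0, 10, seed=0)
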