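"""Statistically significant interval and multi-tissue assignment."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tissuetau import (
    ExtendedTau,
    assign_specific_tissues,
    compute_dist_ss,
    gene_sigma_nonzero,
    optimize_ratio_threshold,
    ratio_to_z,
    run_extended_tau,
)
from tissuetau.errors import DimensionError, InsufficientDataError, MalformedInputError
from tissuetau.synthetic import generate_dataset
from conftest import small_config


class TestRatioToZ:
    @pytest.mark.parametrize(
        "ratio,expected,tol",
        [(0.5, 0.0, 1e-12), (0.158655, 1.0, 1e-3), (0.05, 1.6449, 1e-4)],
    )
    def test_upper_tail_quantile(self, ratio, expected, tol):
        assert ratio_to_z(ratio) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(MalformedInputError):
            ratio_to_z(bad)

    def test_round_trip_through_normal_cdf(self):
        for ratio in np.arange(0.01, 1.0, 0.01):
            z = ratio_to_z(ratio)
            assert sps.norm.cdf(z) == pytest.approx(1.0 - ratio, abs=1e-9)


class TestThresholdOptimization:
    def test_constant_ratios_any_method(self):
        for method in ("mean", "median", "linear-trend"):
            thr = optimize_ratio_threshold([0.2, 0.2, 0.2], method)
            assert thr.ratio_opt == pytest.approx(0.2)
            assert thr.z_val == pytest.approx(ratio_to_z(0.2))

    def test_mean_and_median_methods(self):
        assert optimize_ratio_threshold([0.1, 0.2, 0.3], "mean").ratio_opt == pytest.approx(0.2)
        assert optimize_ratio_threshold([0.1, 0.1, 0.4], "median").ratio_opt == pytest.approx(0.1)

    def test_linear_trend_evaluates_fit_at_mid_rank(self):
        thr = optimize_ratio_threshold([0.1, 0.3, 0.2], "linear-trend")
        assert thr.ratio_opt == pytest.approx(0.2, abs=1e-12)

    def test_degenerate_ratios_skipped_and_empty_rejected(self):
        thr = optimize_ratio_threshold([0.3, None, 0.1])
        assert thr.ratio_opt == pytest.approx(0.2)
        with pytest.raises(InsufficientDataError):
            optimize_ratio_threshold([])
        with pytest.raises(ValueError):
            optimize_ratio_threshold([0.2], method="nope")


class TestGeneSigma:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((0.0, 0.0, 100.0), 0.0),  # single nonzero -> no dispersion estimate
            ((0.0, 10.0, 20.0), 7.0710678118654755),
            ((5.0, 5.0, 5.0), 0.0),
        ],
    )
    def test_sample_sd_over_positive_values(self, values, expected):
        assert gene_sigma_nonzero(values) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_gene_rejected(self):
        with pytest.raises(MalformedInputError):
            gene_sigma_nonzero([0.0, 0.0])


class TestDistSs:
    @pytest.mark.parametrize(
        "x_max,sigma,z,expected",
        [(100, 10, 0, 100.0), (100, 10, 1.6449, 83.551), (100, 0, 5, 100.0)],
    )
    def test_formula(self, x_max, sigma, z, expected):
        assert compute_dist_ss(x_max, sigma, z) == pytest.approx(expected)


class TestAssignTissues:
    def test_two_tissue_pattern(self):
        expr = pd.Series([2.0, 95.0, 100.0, 3.0], index=["t1", "t2", "t3", "t4"])
        assert set(assign_specific_tissues(expr, 90.0)) == {"t2", "t3"}

    def test_inclusive_boundary(self):
        expr = pd.Series([100.0, 84.0, 50.0], index=["t1", "t2", "t3"])
        assert set(assign_specific_tissues(expr, 83.551)) == {"t1", "t2"}

    def test_argmax_always_included_even_above_dist(self):
        expr = pd.Series([0.0, 0.0, 100.0], index=["t1", "t2", "t3"])
        assert assign_specific_tissues(expr, 150.0) == ["t3"]

    def test_ties_at_maximum_all_assigned(self):
        expr = pd.Series([100.0, 100.0, 1.0], index=["t1", "t2", "t3"])
        assert set(assign_specific_tissues(expr, 1e9)) == {"t1", "t2"}


class TestExtendedTauPipeline:
    def test_argmax_restriction_recovers_original_tau_assignment(self):
        matrix, _ = generate_dataset(small_config(seed=3))
        est = ExtendedTau().fit(matrix)
        argmax_pairs = {
            (g, t)
            for g, t in zip(
                est.categories_[est.categories_ == "specific"].index,
                matrix.values.loc[est.categories_ == "specific"].idxmax(axis=1),
            )
        }
        flagged = est.assignments_.table
        assert set(
            zip(flagged.loc[flagged.is_argmax, "gene_id"], flagged.loc[flagged.is_argmax, "tissue"])
        ) == argmax_pairs

    def test_pair_count_at_least_specific_count(self):
        matrix, _ = generate_dataset(small_config(seed=4))
        _, summary = run_extended_tau(matrix)
        assert summary["n_pairs"] >= summary["n_specific_genes"] > 0

    def test_argmax_containment_over_random_matrices(self, rng):
        for _ in range(5):
            df = pd.DataFrame(rng.gamma(0.3, 120.0, (120, 8)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                est = ExtendedTau().fit(df)
            for gene, grp in est.assignments_.table.groupby("gene_id"):
                argmax = df.loc[gene].idxmax()
                assert argmax in set(grp["tissue"])

    def test_pair_count_non_decreasing_in_z(self):
        # dist_ss = x_max - sigma*z: raising z lowers the threshold and can
        # only add tissues, never remove one
        matrix, _ = generate_dataset(small_config(seed=5))
        counts = [
            ExtendedTau(z_val=z).fit(matrix).assignments_.n_pairs
            for z in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_zero_z_recovers_original_tau_assignment(self):
        # at z = 0 the interval collapses to the maximum itself
        matrix, _ = generate_dataset(small_config(seed=6))
        est = ExtendedTau(z_val=0.0).fit(matrix)
        assert est.assignments_.n_pairs == est.summary_["n_specific_genes"]
        assert est.assignments_.table["is_argmax"].all()

    def test_negative_z_still_assigns_argmax(self):
        matrix, _ = generate_dataset(small_config(seed=6))
        est = ExtendedTau(z_val=-3.0).fit(matrix)
        assert est.assignments_.n_pairs == est.summary_["n_specific_genes"]

    def test_supplied_z_skips_clustering(self):
        matrix, _ = generate_dataset(small_config(seed=7))
        est = ExtendedTau(z_val=1.5).fit(matrix)
        assert est.cluster_results_ == [] and est.ratio_opt_ is None
        assert est.z_val_ == 1.5

    def test_dist_ss_never_exceeds_max_for_nonneg_z(self):
        matrix, _ = generate_dataset(small_config(seed=8))
        est = ExtendedTau().fit(matrix)
        assert est.z_val_ >= 0
        table = est.assignments_.table
        assert (table["dist_ss"] <= table["x_max"] + 1e-9).all()

    def test_no_specific_genes_warns_and_returns_empty(self):
        df = pd.DataFrame(np.full((20, 4), 50.0) + np.arange(4))
        with pytest.warns(UserWarning, match="no specific genes"):
            assignment, summary = run_extended_tau(df)
        assert assignment.n_pairs == 0 and summary["n_specific_genes"] == 0

    def test_single_tissue_matrix_rejected(self):
        with pytest.raises(DimensionError):
            ExtendedTau().fit(np.ones((5, 1)))

    def test_gene_axis_clustering_available(self):
        matrix, _ = generate_dataset(small_config(seed=9))
        est = ExtendedTau(clustering_axis="gene").fit(matrix)
        assert est.z_val_ is not None and est.assignments_.n_pairs > 0

    def test_deterministic_output(self):
        matrix, _ = generate_dataset(small_config(seed=10))
        t1 = ExtendedTau().fit(matrix).assignments_.table
        t2 = ExtendedTau().fit(matrix).assignments_.table
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.to_csv() == t2.to_csv()

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = clone(ExtendedTau(threshold_method="median", z_val=2.0))
        assert est.threshold_method == "median" and est.z_val == 2.0
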