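"""Cosine-distance scans: distances, similarity adjustment, permutations,
and bootstrap intervals, each checked against an independent oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cosine as scipy_cosine

from amsd import (
    HET,
    P1,
    P2,
    GenotypeMatrix,
    MutationTable,
    PermutationNull,
    ScanError,
    ZeroSpectrumError,
    adjust_distances,
    amsd_scan,
    bootstrap_ci,
    cosine_distance,
    group_haplotypes,
    permutation_threshold,
    similarity_correlation,
)
from amsd.scan import _group_frequency_correlations

from conftest import table_from_counts

FIG1_DISTANCE = 1 - 28 / (np.sqrt(34) * np.sqrt(40))  # groups (3,5) vs (6,2)


class TestCosineDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([2.0, 3.0, 1.0], [2.0, 3.0, 1.0], 0.0),
            ([1.0, 0.0], [0.0, 1.0], 1.0),
            ([3.0, 5.0], [6.0, 2.0], FIG1_DISTANCE),
        ],
    )
    def test_examples(self, a, b, expected):
        assert cosine_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(7), rng.random(7)
        assert cosine_distance(17.5 * a, b) == pytest.approx(
            cosine_distance(a, b), abs=1e-12
        )

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = rng.integers(0, 50, size=7).astype(float)
            b = rng.integers(0, 50, size=7).astype(float)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert cosine_distance(a, b) == pytest.approx(
                scipy_cosine(a, b), abs=1e-12
            )

    def test_zero_vector_raises(self):
        with pytest.raises(ZeroSpectrumError):
            cosine_distance([0.0, 0.0], [1.0, 2.0])

    def test_dimension_mismatch(self):
        with pytest.raises(ScanError):
            cosine_distance([1.0], [1.0, 2.0])


class TestGrouping:
    def test_het_and_missing_excluded(self, toy_dataset):
        muts, geno = toy_dataset
        g1_p1, g1_p2 = group_haplotypes(geno, "g1")
        assert g1_p1 == {"h1", "h2"} and g1_p2 == {"h3", "h4"}

    def test_groups_with_het(self):
        calls = np.array([[P1, P1, P2, HET]], dtype=np.int8)
        geno = GenotypeMatrix(["m1"], ["1"], [1.0], ["s1", "s2", "s3", "s4"], calls)
        gp1, gp2 = group_haplotypes(geno, "m1")
        assert gp1 == {"s1", "s2"} and gp2 == {"s3"}

    def test_all_het_marker_yields_empty_groups(self):
        calls = np.array([[HET, HET]], dtype=np.int8)
        geno = GenotypeMatrix(["m1"], ["1"], [1.0], ["s1", "s2"], calls)
        assert group_haplotypes(geno, "m1") == (set(), set())


class TestSimilarityCorrelation:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([P1, P2, HET], size=(8, 12), p=[0.45, 0.45, 0.1]).astype(
            np.int8
        )
        r_fast = _group_frequency_correlations(calls)
        dosage = np.where(calls == P2, 1.0, np.where(calls == HET, 0.5, 0.0))
        for i in range(8):
            in1 = calls[i] == P2
            in0 = calls[i] == P1
            if not in1.any() or not in0.any():
                assert np.isnan(r_fast[i])
                continue
            f1 = dosage[:, in1].mean(axis=1)
            f0 = dosage[:, in0].mean(axis=1)
            expected = np.corrcoef(f1, f0)[0, 1]
            assert r_fast[i] == pytest.approx(expected, abs=1e-12)

    def test_opposite_frequency_vectors_give_minus_one(self):
        # the two groups have P2-frequency vectors (0,1,0) and (1,0,1)
        calls = np.array(
            [
                [P1, P1, P2, P2],
                [P2, P2, P1, P1],
                [P1, P1, P2, P2],
            ],
            dtype=np.int8,
        )
        geno = GenotypeMatrix(
            ["m1", "m2", "m3"], ["1"] * 3, [1.0, 2.0, 3.0], list("abcd"), calls
        )
        assert similarity_correlation(geno, "m2") == pytest.approx(-1.0)

    def test_empty_group_is_an_error(self):
        calls = np.array([[P1, P1]], dtype=np.int8)
        geno = GenotypeMatrix(["m1"], ["1"], [1.0], ["a", "b"], calls)
        with pytest.raises(ScanError, match="empty"):
            similarity_correlation(geno, "m1")


class TestAdjustment:
    def test_constant_r_falls_back_to_mean_centring(self):
        raw = np.array([0.1, 0.2, 0.4])
        adj = adjust_distances(raw, np.full(3, 0.7))
        np.testing.assert_allclose(adj, raw - raw.mean(), atol=1e-15)

    def test_perfectly_linear_raw_gives_zero_residuals(self):
        r = np.array([0.1, 0.3, 0.5, 0.9])
        raw = 0.02 - 0.01 * r
        np.testing.assert_allclose(adjust_distances(raw, r), 0.0, atol=1e-15)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        r = rng.random(50)
        raw = 0.01 + 0.005 * r + rng.normal(0, 0.001, 50)
        adj = adjust_distances(raw, r)
        X = np.column_stack([np.ones(50), r])
        beta = np.linalg.solve(X.T @ X, X.T @ raw)
        np.testing.assert_allclose(adj, raw - X @ beta, atol=1e-10)
        # residuals orthogonal to r and mean ~ 0
        assert abs(adj @ (r - r.mean())) < 1e-10
        assert abs(adj.mean()) < 1e-12

    def test_nan_markers_are_passed_through(self):
        raw = np.array([0.1, np.nan, 0.3, 0.2])
        r = np.array([0.2, 0.5, np.nan, 0.9])
        adj = adjust_distances(raw, r)
        assert np.isnan(adj[1]) and np.isnan(adj[2])
        assert np.isfinite(adj[[0, 3]]).all()

    def test_too_few_markers(self):
        with pytest.raises(ScanError):
            adjust_distances([0.1], [0.5])


class TestScan:
    def test_toy_distances_match_hand_computation(self, toy_dataset):
        muts, geno = toy_dataset
        res = amsd_scan(muts, geno, adjust=False)
        tab = res.table.set_index("marker")
        assert tab.loc["g1", "raw_distance"] == pytest.approx(FIG1_DISTANCE, abs=1e-12)
        # brute-force oracle over every marker
        per_sample = {
            "h1": np.array([1.0, 3.0]),
            "h2": np.array([2.0, 2.0]),
            "h3": np.array([4.0, 1.0]),
            "h4": np.array([2.0, 1.0]),
        }
        for marker in ["g1", "g2", "g3"]:
            gp1, gp2 = group_haplotypes(geno, marker)
            a = sum(per_sample[s] for s in gp1)
            b = sum(per_sample[s] for s in gp2)
            expected = 1 - (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert tab.loc[marker, "raw_distance"] == pytest.approx(expected, abs=1e-12)

    def test_duplicating_every_sample_preserves_distances(self, toy_dataset):
        muts, geno = toy_dataset
        base = amsd_scan(muts, geno, adjust=False).table["raw_distance"]
        dup_muts = MutationTable(
            pd.concat(
                [muts.df, muts.df.assign(sample=muts.df["sample"] + "_dup")],
                ignore_index=True,
            )
        )
        dup_geno = GenotypeMatrix(
            geno.marker_ids,
            geno.marker_chrom,
            geno.marker_pos_mbp,
            geno.sample_ids + [s + "_dup" for s in geno.sample_ids],
            np.hstack([geno.calls, geno.calls]),
        )
        doubled = amsd_scan(dup_muts, dup_geno, adjust=False).table["raw_distance"]
        np.testing.assert_allclose(doubled, base, atol=1e-12)

    def test_peak_at_planted_mutator(self, sim_fixture):
        muts = sim_fixture["mutation_table"]
        geno = sim_fixture["genotype_matrix"]
        res = amsd_scan(muts, geno, adjust=True)
        assert res.peak_marker == sim_fixture["manifest"]["mutator_marker"]

    def test_conditional_scan_on_uniform_marker_equals_subset_scan(self, sim_fixture):
        muts = sim_fixture["mutation_table"]
        geno = sim_fixture["genotype_matrix"]
        # force one marker to carry only P2 alleles
        calls = geno.calls.copy()
        calls[0, :] = P2
        geno2 = GenotypeMatrix(
            geno.marker_ids,
            geno.marker_chrom,
            geno.marker_pos_mbp,
            geno.sample_ids,
            calls,
            geno.strata,
        )
        cond = amsd_scan(muts, geno2, condition=(str(geno.marker_ids[0]), "P2"))
        plain = amsd_scan(muts, geno2)
        pd.testing.assert_frame_equal(cond.table, plain.table)

    def test_missing_sample_policy(self, toy_dataset):
        muts, geno = toy_dataset
        extra = MutationTable(
            pd.concat(
                [
                    muts.df,
                    pd.DataFrame(
                        [("ghost", "1", 1, "C", "A", "TCA")],
                        columns=["sample", "chrom", "pos", "ref", "alt", "context"],
                    ),
                ],
                ignore_index=True,
            )
        )
        with pytest.raises(ScanError, match="ghost"):
            amsd_scan(extra, geno, on_missing_samples="error")
        res = amsd_scan(extra, geno, on_missing_samples="drop")
        assert res.settings["n_samples"] == 4


class TestPermutations:
    def test_same_seed_gives_identical_null(self, sim_fixture):
        muts = sim_fixture["mutation_table"]
        geno = sim_fixture["genotype_matrix"]
        kw = dict(n_permutations=50, seed=9)
        a = permutation_threshold(muts, geno, **kw)
        b = permutation_threshold(muts, geno, **kw)
        np.testing.assert_array_equal(a.max_statistics, b.max_statistics)

    def test_threshold_is_an_order_statistic(self):
        rng = np.random.default_rng(5)
        values = rng.permutation(np.arange(1.0, 1001.0))
        null = PermutationNull(values, stratified=False, seed=None)
        # 950th order statistic of 1..1000 at p = 0.05
        assert null.threshold(0.05) == 950.0
        assert null.threshold(0.5) == 500.0

    def test_stratified_requires_strata(self, sim_fixture):
        muts = sim_fixture["mutation_table"]
        geno = sim_fixture["genotype_matrix"]
        geno_nostrata = GenotypeMatrix(
            geno.marker_ids,
            geno.marker_chrom,
            geno.marker_pos_mbp,
            geno.sample_ids,
            geno.calls,
        )
        with pytest.raises(ScanError, match="strata"):
            permutation_threshold(
                muts, geno_nostrata, n_permutations=5, stratified=True
            )

    def test_stratified_runs_with_epochs(self, sim_fixture):
        muts = sim_fixture["mutation_table"]
        geno = sim_fixture["genotype_matrix"]
        null = permutation_threshold(
            muts, geno, n_permutations=30, stratified=True, seed=1
        )
        assert len(null.max_statistics) == 30
        assert np.isfinite(null.threshold()).all()

    def test_singleton_stratum_warns(self, toy_dataset):
        muts, geno = toy_dataset
        lonely = GenotypeMatrix(
            geno.marker_ids,
            geno.marker_chrom,
            geno.marker_pos_mbp,
            geno.sample_ids,
            geno.calls,
            strata=pd.Series(
                {"h1": "e1", "h2": "e1", "h3": "e1", "h4": "solo"}
            ),
        )
        with pytest.warns(UserWarning, match="single sample"):
            permutation_threshold(
                muts, lonely, n_permutations=5, stratified=True, seed=0, adjust=False
            )

    def test_planted_mutator_exceeds_threshold(self, sim_fixture):
        muts = sim_fixture["mutation_table"]
        geno = sim_fixture["genotype_matrix"]
        res = amsd_scan(muts, geno)
        null = permutation_threshold(muts, geno, n_permutations=200, seed=3)
        res.threshold = null.threshold()
        sig = res.significant()
        assert sim_fixture["manifest"]["mutator_marker"] in set(sig["marker"])


class TestBootstrap:
    def test_single_marker_chromosome_gives_degenerate_ci(self, toy_dataset):
        muts, geno = toy_dataset
        ci = bootstrap_ci(muts, geno, "2", n_bootstrap=20, seed=0, adjust=False)
        assert ci.lo_mbp == ci.hi_mbp == 5.0

    def test_ci_brackets_planted_mutator(self, sim_fixture):
        muts = sim_fixture["mutation_table"]
        geno = sim_fixture["genotype_matrix"]
        truth = geno.marker_pos_mbp[sim_fixture["manifest"]["mutator_marker_index"]]
        ci = bootstrap_ci(muts, geno, "1", n_bootstrap=200, seed=2)
        assert ci.lo_mbp <= truth <= ci.hi_mbp
        assert len(ci.peak_positions) + ci.n_discarded == 200
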