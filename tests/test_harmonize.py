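"""Harmonization, HWE exact test, QC filters and cohort-bias screen."""

import numpy as np
import pytest
from scipy.special import comb

from popstruct.data import MISSING, GenotypeDataError
from popstruct.harmonize import (
    batch_bias_test,
    filter_markers,
    hwe_exact_test,
    intersect_and_harmonize,
    ld_prune,
    maf_concordance,
)
from popstruct.simulate import SimulationConfig, simulate_subpopulations, split_platforms

from conftest import toy_matrix


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Independent brute-force enumeration of Levene's distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_rare = min(n_alt, 2 * n - n_alt)
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            continue
        # multinomial configurations times 2^h allele arrangements
        weights[h] = (
            comb(n, h, exact=True)
            * comb(n - h, hom_rare, exact=True)
            * 2**h
        )
    total = sum(weights.values())
    p_obs = weights[n_het] / total
    return sum(w for w in weights.values() if w / total <= p_obs * (1 + 1e-12)) / total


class TestHweExact:
    def test_worked_example(self):
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(17, 0, 0) == 1.0

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @pytest.mark.parametrize(
        "counts", [(5, 5, 5), (10, 1, 10), (0, 20, 0), (3, 7, 1), (12, 0, 3)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )


class TestHarmonization:
    def _cohorts(self, ref_a, alt_a, ref_b, alt_b, calls_a=None, calls_b=None):
        a = toy_matrix(
            calls_a or [[0], [1]], rs_ids=["rs1"], allele_ref=[ref_a], allele_alt=[alt_a],
            sample_ids=["A1", "A2"],
        )
        b = toy_matrix(
            calls_b or [[2], [1]], rs_ids=["rs1"], allele_ref=[ref_b], allele_alt=[alt_b],
            sample_ids=["B1", "B2"],
        )
        return a, b

    def test_complemented_pair_included(self):
        a, b = self._cohorts("A", "G", "T", "C")
        merged, rep = intersect_and_harmonize(a, b)
        assert rep.n_complemented == 1
        assert merged.n_markers == 1
        # dosages survive the relabeling
        assert merged.calls[:2, 0].tolist() == [0, 1]

    def test_ambiguous_pair_excluded(self):
        a, b = self._cohorts("A", "T", "A", "T")
        with pytest.raises(GenotypeDataError):
            intersect_and_harmonize(a, b)  # only marker is ambiguous

    def test_mismatched_pair_excluded(self):
        # second, clean marker keeps the merge non-empty
        a = toy_matrix(
            [[0, 0], [1, 1]], rs_ids=["rs1", "rs2"],
            allele_ref=["A", "A"], allele_alt=["G", "C"], sample_ids=["A1", "A2"],
        )
        b = toy_matrix(
            [[2, 0], [1, 1]], rs_ids=["rs1", "rs2"],
            allele_ref=["A", "A"], allele_alt=["C", "C"], sample_ids=["B1", "B2"],
        )
        merged, rep = intersect_and_harmonize(a, b)
        assert rep.n_allele_mismatch_excluded == 1
        assert merged.rs_ids == ["rs2"]

    def test_swapped_orientation_recodes_dosages(self):
        # same pair, A's alt is B's ref: A dosages must be recoded 2-g
        a, b = self._cohorts("G", "A", "A", "G", calls_a=[[0], [2]])
        merged, _ = intersect_and_harmonize(a, b)
        assert merged.calls[:2, 0].tolist() == [2, 0]

    def test_merge_idempotent_on_marker_set(self):
        cfg = SimulationConfig(n_subpops=2, n_per_subpop=30, n_loci=200, seed=20)
        gm, _ = simulate_subpopulations(cfg)
        a, b, _ = split_platforms(gm, 0.8, 0.2, 0.1, 0.0, seed=1)
        merged, _ = intersect_and_harmonize(a, b)
        again = merged.copy()
        again.samples["sample_id"] = ["X" + s for s in again.sample_ids]
        remerged, rep = intersect_and_harmonize(merged, again)
        assert remerged.rs_ids == merged.rs_ids
        assert rep.n_complemented == 0
        assert rep.n_ambiguous_excluded == 0

    def test_harmonization_reconstructs_expected_merge(self):
        cfg = SimulationConfig(n_subpops=2, n_per_subpop=40, n_loci=500, seed=21)
        gm, _ = simulate_subpopulations(cfg)
        a, b, expected = split_platforms(gm, 0.8, 0.2, 0.1, 0.01, seed=2)
        merged, _ = intersect_and_harmonize(a, b)
        assert merged.rs_ids == expected.rs_ids
        assert merged.sample_ids == expected.sample_ids
        assert np.array_equal(merged.calls, expected.calls)


class TestMafConcordance:
    def test_identical_cohorts_correlate_perfectly(self):
        cfg = SimulationConfig(n_subpops=1, n_per_subpop=30, n_loci=100, seed=22)
        gm, _ = simulate_subpopulations(cfg)
        gm.samples["cohort"] = ["A"] * 15 + ["B"] * 15
        doubled = gm.copy()
        doubled.calls[15:] = doubled.calls[:15]  # cohort B mirrors cohort A
        r, table = maf_concordance(doubled)
        assert r == pytest.approx(1.0)
        assert len(table) == 100

    def test_single_marker_is_error(self):
        gm = toy_matrix([[0], [1]])
        gm.samples["cohort"] = ["A", "B"]
        with pytest.raises(GenotypeDataError):
            maf_concordance(gm)


class TestFilters:
    def test_missingness_thresholds(self):
        # marker 2: 6% missing -> removed at 5%, retained at 10%
        calls = np.zeros((50, 2), dtype=np.int16)
        calls[:, 0] = np.tile([0, 1, 1, 0], 13)[:50]
        calls[:, 1] = np.tile([0, 1, 1, 0], 13)[:50]
        calls[:3, 1] = MISSING  # 6% missing
        gm = toy_matrix(calls)
        out5, rep5 = filter_markers(gm, hwe_p=1e-6, missing_max=0.05)
        assert out5.rs_ids == ["rs1"] and rep5.n_fail_missing == 1
        out10, _ = filter_markers(gm, hwe_p=1e-6, missing_max=0.10)
        assert out10.n_markers == 2

    def test_hwe_failure_removed(self):
        # all-heterozygote marker is a gross HWE violation at n=50
        calls = np.ones((50, 1), dtype=np.int16)
        gm = toy_matrix(calls)
        out, rep = filter_markers(gm, hwe_p=1e-3, missing_max=0.5)
        assert out.n_markers == 0 and rep.n_fail_hwe == 1

    def test_all_pass_identity(self):
        cfg = SimulationConfig(n_subpops=1, n_per_subpop=50, n_loci=60, seed=23)
        gm, _ = simulate_subpopulations(cfg)
        out, rep = filter_markers(gm, hwe_p=1e-10, missing_max=0.5)
        assert rep.n_pass == rep.n_input == 60
        assert out.rs_ids == gm.rs_ids


class TestLdPrune:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=100).astype(np.int16)
        calls = np.stack([col, col, rng.integers(0, 3, 100).astype(np.int16)], axis=1)
        gm = toy_matrix(calls)
        out, rep = ld_prune(gm, r2_max=0.5, window=10, step=2)
        assert rep.n_pruned_ld == 1
        assert "rs1" in out.rs_ids  # earlier position kept on ties

    def test_independent_markers_rarely_pruned(self):
        cfg = SimulationConfig(n_subpops=1, n_per_subpop=500, n_loci=400, seed=24)
        gm, _ = simulate_subpopulations(cfg)
        _, rep = ld_prune(gm, r2_max=0.5, window=30, step=5)
        assert rep.n_pruned_ld <= 1  # null r^2 ~ 1/n, far below 0.5

    def test_unattainable_threshold_prunes_nothing(self):
        cfg = SimulationConfig(n_subpops=1, n_per_subpop=20, n_loci=30, seed=25)
        gm, _ = simulate_subpopulations(cfg)
        _, rep = ld_prune(gm, r2_max=1.0, window=10, step=1)
        assert rep.n_pruned_ld == 0


class TestBatchBias:
    def test_identical_counts_score_zero(self):
        # 15 hom-alt + 85 hom-ref in both cohorts: 30/170 alleles each
        calls = np.zeros((100, 1), dtype=np.int16)
        calls[:15] = 2
        a = toy_matrix(calls, sample_ids=[f"A{i}" for i in range(100)])
        b = toy_matrix(calls.copy(), sample_ids=[f"B{i}" for i in range(100)])
        table = batch_bias_test(a, b)
        assert table["chi2"][0] == 0.0 and table["p"][0] == 1.0

    def test_hand_computed_chi2(self):
        # alleles: (40 alt, 160 ref) vs (20 alt, 180 ref) -> chi2 ~ 7.84
        calls_a = np.zeros((100, 1), dtype=np.int16)
        calls_a[:20] = 2
        calls_b = np.zeros((100, 1), dtype=np.int16)
        calls_b[:10] = 2
        a = toy_matrix(calls_a, sample_ids=[f"A{i}" for i in range(100)])
        b = toy_matrix(calls_b, sample_ids=[f"B{i}" for i in range(100)])
        table = batch_bias_test(a, b)
        assert table["chi2"][0] == pytest.approx(7.8431, abs=1e-3)
        assert table["p"][0] == pytest.approx(0.0051, abs=3e-4)

    def test_monomorphic_both_cohorts(self):
        calls = np.zeros((10, 1), dtype=np.int16)
        a = toy_matrix(calls, sample_ids=[f"A{i}" for i in range(10)])
        b = toy_matrix(calls.copy(), sample_ids=[f"B{i}" for i in range(10)])
        table = batch_bias_test(a, b)
        assert table["chi2"][0] == 0.0 and table["p"][0] == 1.0
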