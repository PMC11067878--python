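import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sagarep as sr
from sagarep.overlap import OverlapError, match_states_windowed, windowed_joint

from conftest import random_annotation


def brute_force_reproduced(base, verif, corr, w_bins):
    """Independent per-bin window scan (oracle for the vectorized indicator)."""
    out = np.zeros(base.G, dtype=bool)
    for chrom, sl in base.genome.chrom_slices().items():
        lab_b = base.labels[sl]
        lab_v = verif.labels[sl]
        n = len(lab_b)
        for g in range(n):
            if lab_b[g] < 0 or lab_v[g] < 0:
                continue
            target = corr.match[lab_b[g]]
            lo, hi = max(0, g - w_bins), min(n, g + w_bins + 1)
            out[sl.start + g] = bool((lab_v[lo:hi] == target).any())
    return out


class TestJointOverlap:
    def test_toy_counts(self, toy_pair):
        om = sr.joint_overlap(*toy_pair)
        expected = np.array([[0, 0, 0], [0, 0.3, 0.2], [0, 0, 0.5]])
        np.testing.assert_allclose(om.joint, expected, atol=1e-12)
        assert om.n_bins_used == 10

    def test_self_comparison_is_diagonal_coverages(self, toy_pair):
        base, _ = toy_pair
        om = sr.joint_overlap(base, base)
        np.testing.assert_allclose(np.diag(om.joint), base.coverages())
        assert om.joint.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(om.joint - np.diag(np.diag(om.joint)), 0)

    def test_all_missing_verification_raises(self, toy_genome, toy_pair):
        base, _ = toy_pair
        empty = sr.Annotation(toy_genome, np.full(10, -1), K=3)
        with pytest.raises(OverlapError):
            sr.joint_overlap(base, empty)


class TestIoU:
    def test_toy_values(self, toy_pair):
        iou = sr.iou_matrix(sr.joint_overlap(*toy_pair)).iou
        assert iou[1, 1] == pytest.approx(0.3 / (0.5 + 0.3 - 0.3))
        assert iou[2, 2] == pytest.approx(0.5 / 0.7)
        assert iou[2, 1] == 0.0

    def test_identical_annotations_have_unit_diagonal(self, toy_pair):
        base, _ = toy_pair
        iou = sr.iou_matrix(sr.joint_overlap(base, base)).iou
        used = base.coverages() > 0
        np.testing.assert_allclose(np.diag(iou)[used], 1.0)

    def test_zero_joint_with_positive_coverage_is_zero(self, toy_pair):
        iou = sr.iou_matrix(sr.joint_overlap(*toy_pair)).iou
        assert iou[1, 2] > 0 and iou[2, 1] == 0.0


class TestMatchStates:
    def test_toy_matching(self, toy_pair):
        corr = sr.match_states(sr.iou_matrix(sr.joint_overlap(*toy_pair)))
        assert corr.match[1] == 1 and corr.match[2] == 2

    def test_identity_on_self(self, small_synthetic):
        base = small_synthetic.base
        corr = sr.match_states(sr.iou_matrix(sr.joint_overlap(base, base)))
        assert np.array_equal(corr.match, np.arange(base.K))

    def test_tie_broken_to_lowest_id(self, caplog):
        corr = sr.match_states(sr.IoUMatrix(iou=np.array([[0.4, 0.4]])))
        assert corr.match[0] == 0


class TestReproductionIndicator:
    def test_toy_naive_fractions(self, toy_pair):
        corr = sr.match_states(sr.iou_matrix(sr.joint_overlap(*toy_pair)))
        per_state, overall = sr.naive_overlap(*toy_pair, corr)
        assert per_state[1] == pytest.approx(0.6)
        assert per_state[2] == pytest.approx(1.0)
        assert overall == pytest.approx(0.8)

    def test_toy_window_one_bin(self, toy_pair):
        corr = sr.match_states(sr.iou_matrix(sr.joint_overlap(*toy_pair)))
        ind = sr.reproduction_indicator(*toy_pair, corr, w=200)
        # bin 3's window reaches verification state 1 at bin 2; bin 4's does not
        assert ind.per_state_fraction[1] == pytest.approx(0.8)
        assert ind.per_state_fraction[2] == pytest.approx(1.0)

    def test_saturation_at_chromosome_length(self, toy_pair):
        corr = sr.match_states(sr.iou_matrix(sr.joint_overlap(*toy_pair)))
        ind = sr.reproduction_indicator(*toy_pair, corr, w=10_000)
        assert ind.per_state_fraction[1:].tolist() == [1.0, 1.0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_scan(self, seed):
        genome = sr.bin_genome({"c1": 30 * 7, "c2": 20 * 7}, 7)
        base = random_annotation(genome, 4, seed, missing_frac=0.1)
        verif = random_annotation(genome, 3, seed + 100, missing_frac=0.1)
        corr = sr.match_states(sr.iou_matrix(sr.joint_overlap(base, verif)))
        for w_bins in (0, 1, 2, 5):
            ind = sr.reproduction_indicator(base, verif, corr, w=w_bins * 7)
            oracle = brute_force_reproduced(base, verif, corr, w_bins)
            assert np.array_equal(ind.reproduced, oracle)

    def test_monotone_in_window(self, small_synthetic):
        base, verif = small_synthetic.replicate_pair
        corr = sr.match_states(sr.iou_matrix(sr.joint_overlap(base, verif)))
        prev = np.zeros(base.G, dtype=bool)
        for w in (0, 200, 400, 1000, 2000):
            rep = sr.reproduction_indicator(base, verif, corr, w).reproduced
            assert (rep | prev).sum() == rep.sum()  # pointwise nondecreasing
            prev = rep

    def test_independent_labels_match_analytic_expectation(self):
        genome = sr.bin_genome({"c1": 50_000 * 10}, 10)
        base = random_annotation(genome, 5, seed=7)
        verif = random_annotation(genome, 5, seed=8)
        corr = sr.match_states(sr.iou_matrix(sr.joint_overlap(base, verif)))
        _, overall = sr.naive_overlap(base, verif, corr)
        om = sr.joint_overlap(base, verif)
        expect = sum(
            om.marginal_base[k] * om.marginal_verif[corr.match[k]]
            for k in range(base.K)
        )
        assert overall == pytest.approx(expect, abs=0.01)


@settings(derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), kb=st.integers(2, 5), kv=st.integers(2, 5))
def test_overlap_matrix_invariants(seed, kb, kv):
    """Joint sums to 1; marginals match row/column sums; IoU transposes."""
    genome = sr.bin_genome({"c1": 300}, 10)
    base = random_annotation(genome, kb, seed, missing_frac=0.2)
    verif = random_annotation(genome, kv, seed + 1, missing_frac=0.2)
    om = sr.joint_overlap(base, verif)
    assert om.joint.sum() == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(om.joint.sum(axis=1), om.marginal_base, atol=1e-9)
    np.testing.assert_allclose(om.joint.sum(axis=0), om.marginal_verif, atol=1e-9)
    iou_fwd = sr.iou_matrix(om).iou
    iou_rev = sr.iou_matrix(sr.joint_overlap(verif, base)).iou
    np.testing.assert_allclose(iou_fwd, iou_rev.T, atol=1e-12)


def test_windowed_joint_reduces_to_plain_at_zero(self=None, seed=3):
    genome = sr.bin_genome({"c1": 500}, 10)
    base = random_annotation(genome, 4, seed)
    verif = random_annotation(genome, 4, seed + 1)
    np.testing.assert_allclose(
        windowed_joint(base, verif, 0), sr.joint_overlap(base, verif).joint
    )
    corr0 = match_states_windowed(base, verif, 0)
    corr_plain = sr.match_states(sr.iou_matrix(sr.joint_overlap(base, verif)))
    assert np.array_equal(corr0.match, corr_plain.match)
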