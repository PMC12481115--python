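"""Sparseness index and NNLS-based fractionation/merging detection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from emgsynergy import (
    detect_fractionation,
    detect_merging,
    direction_gate,
    group_sparseness,
    nnls_combination,
    sparseness,
)
from emgsynergy.exceptions import (
    DimensionError,
    InsufficientBasisError,
    UndefinedSparsenessError,
)
from tests.test_cluster import _dec


class TestSparseness:
    def test_one_hot_is_one(self):
        w = np.zeros(16)
        w[5] = 3.2
        assert sparseness(w) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        assert sparseness(np.full(16, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_half_support_closed_form(self):
        # phi([1,1,0,0]) = (2 - 2/sqrt(2)) / (2 - 1) = 2 - sqrt(2)
        assert sparseness([1.0, 1.0, 0.0, 0.0]) == pytest.approx(
            2.0 - np.sqrt(2.0))

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedSparsenessError):
            sparseness(np.zeros(8))

    def test_scalar_rejected(self):
        with pytest.raises(DimensionError):
            sparseness([1.0])

    @settings(derandomize=True, max_examples=200)
    @given(hnp.arrays(float, st.integers(2, 16),
                      elements=st.floats(0.0, 10.0)))
    def test_bounded_scale_and_permutation_invariant(self, w):
        if np.linalg.norm(w) == 0:  # zero or fully subnormal vector
            return
        phi = sparseness(w)
        assert -1e-12 <= phi <= 1.0 + 1e-12
        assert sparseness(3.0 * w) == pytest.approx(phi, abs=1e-9)
        assert sparseness(w[::-1].copy()) == pytest.approx(phi, abs=1e-9)


class TestGroupSparseness:
    def test_per_subject_mean(self):
        W = np.zeros((4, 2))
        W[0, 0] = 1.0          # one-hot: phi = 1
        W[:, 1] = 0.5          # uniform: phi = 0
        rep = group_sparseness([_dec(W)], ["s1"], group="G")
        assert rep.per_subject_mean["s1"] == pytest.approx(0.5)

    def test_identical_subjects_have_zero_spread(self, rng):
        W = rng.random((8, 3))
        rep = group_sparseness([_dec(W), _dec(W)], ["a", "b"])
        assert rep.per_subject_mean.std() == pytest.approx(0.0)


class TestNnlsCombination:
    def test_orthogonal_member_recovers_indicator(self):
        basis = np.eye(3, 6)
        coef = nnls_combination(basis[1], basis)
        np.testing.assert_allclose(coef, [0.0, 1.0, 0.0], atol=1e-12)

    def test_orthogonal_target_gives_zero(self):
        basis = np.eye(2, 6)
        target = np.zeros(6)
        target[5] = 1.0
        np.testing.assert_allclose(nnls_combination(target, basis), 0.0,
                                   atol=1e-12)

    def test_empty_basis_rejected(self):
        with pytest.raises(InsufficientBasisError):
            nnls_combination(np.ones(4), np.empty((0, 4)))

    def test_matches_active_set_enumeration(self, rng):
        # oracle: solve unconstrained LS on every subset of active
        # coefficients, keep the feasible solution with the lowest objective
        target = rng.random(8)
        basis = rng.random((5, 8))
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)

        best = np.inf
        for r in range(6):
            for active in itertools.combinations(range(5), r):
                coef = np.zeros(5)
                if active:
                    sub = basis[list(active)]
                    sol, *_ = np.linalg.lstsq(sub.T, target, rcond=None)
                    if (sol < 0).any():
                        continue
                    coef[list(active)] = sol
                obj = np.linalg.norm(target - coef @ basis)
                best = min(best, obj)

        coef = nnls_combination(target, basis)
        obj = np.linalg.norm(target - coef @ basis)
        assert obj == pytest.approx(best, abs=1e-8)

    def test_optimum_beats_hand_picked_coefficients(self, rng):
        target = rng.random(6)
        basis = rng.random((3, 6))
        coef = nnls_combination(target, basis)
        obj = np.linalg.norm(target - coef @ basis)
        for _ in range(20):
            alt = rng.random(3)
            assert obj <= np.linalg.norm(target - alt @ basis) + 1e-12


class TestDetectFractionation:
    def _orthogonal_fragments(self):
        f1 = np.zeros(16)
        f1[:3] = [0.8, 0.5, 0.3]
        f2 = np.zeros(16)
        f2[8:11] = [0.6, 0.7, 0.4]
        f1 /= np.linalg.norm(f1)
        f2 /= np.linalg.norm(f2)
        return f1, f2

    def test_forward_constructed_parent_detected(self):
        f1, f2 = self._orthogonal_fragments()
        parent = 0.7 * f1 + 0.4 * f2
        parent /= np.linalg.norm(parent)
        extra = np.zeros(16)
        extra[14] = 1.0
        res = detect_fractionation([parent], np.vstack([f1, f2, extra]))
        r = res[0]
        assert r.passed
        assert r.basis_ids == (1, 2)
        scale = np.sqrt(0.7 ** 2 + 0.4 ** 2)
        np.testing.assert_allclose(r.coefficients,
                                   [0.7 / scale, 0.4 / scale], atol=1e-8)
        assert r.reconstruction_sp == pytest.approx(1.0)

    def test_pure_copy_fails_two_term_rule(self):
        f1, f2 = self._orthogonal_fragments()
        res = detect_fractionation([f1], np.vstack([f1, f2]))
        assert not res[0].passed

    def test_orthogonal_parent_fails_sp_rule(self):
        f1, f2 = self._orthogonal_fragments()
        parent = np.zeros(16)
        parent[15] = 1.0
        res = detect_fractionation([parent], np.vstack([f1, f2]))
        assert not res[0].passed

    def test_single_fragment_basis_rejected(self):
        f1, _ = self._orthogonal_fragments()
        with pytest.raises(InsufficientBasisError):
            detect_fractionation([f1], [f1])

    def test_merging_is_exact_mirror(self, rng):
        A = rng.random((3, 10))
        A /= np.linalg.norm(A, axis=1, keepdims=True)
        B = rng.random((4, 10))
        B /= np.linalg.norm(B, axis=1, keepdims=True)
        frac = detect_fractionation(A, B)
        merg = detect_merging(A, B)
        for rf, rm in zip(frac, merg):
            assert rf.passed == rm.passed
            assert rf.basis_ids == rm.basis_ids
            np.testing.assert_allclose(rf.coefficients, rm.coefficients)

    def test_pass_decisions_match_exhaustive_oracle(self, rng):
        from scipy.optimize import nnls as scipy_nnls
        targets = rng.random((3, 8))
        targets /= np.linalg.norm(targets, axis=1, keepdims=True)
        basis = rng.random((4, 8))
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
        res = detect_fractionation(targets, basis,
                                   coef_threshold=0.2, sp_threshold=0.75)
        for i, r in enumerate(res):
            expected = False
            for size in (2, 3, 4):
                for subset in itertools.combinations(range(4), size):
                    coef, _ = scipy_nnls(basis[list(subset)].T, targets[i])
                    recon = coef @ basis[list(subset)]
                    norm = np.linalg.norm(recon)
                    sp = recon @ targets[i] / norm if norm else 0.0
                    if (coef >= 0.2).all() and sp >= 0.75:
                        expected = True
            assert r.passed == expected


class TestDetectionUnderNoise:
    def test_planted_splits_detected_and_degrade_with_noise(self):
        from emgsynergy import make_group_B_by_fractionation, make_templates
        tA = make_templates(6, seed=4)
        tB, fmap = make_group_B_by_fractionation(tA, [4, 5], seed=4)
        rates = []
        for sigma in (0.02, 0.1, 0.3):
            hits = 0
            for rep in range(10):
                rng = np.random.default_rng(100 * rep + 7)
                parents = tA.copy()
                for p_idx, (i, j), (c1, c2) in fmap:
                    v = c1 * tB[i] + c2 * tB[j] + rng.normal(0, sigma, 16)
                    v = np.clip(v, 0, None)
                    parents[p_idx] = v / np.linalg.norm(v)
                res = detect_fractionation(parents, tB)
                hits += sum(r.passed for r in res
                            if (r.target_id - 1) in (4, 5))
            rates.append(hits / 20)
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]


class TestDirectionGate:
    def test_sparser_older_group_directs_fractionation(self):
        gate = direction_gate([0.3, 0.31, 0.32, 0.3], [0.6, 0.61, 0.59, 0.6])
        assert gate["directive"] == "fractionation"

    def test_sparser_younger_group_directs_merging(self):
        gate = direction_gate([0.6, 0.61, 0.59, 0.6], [0.3, 0.31, 0.32, 0.3])
        assert gate["directive"] == "merging"

    def test_no_difference_directs_both(self, rng):
        a = rng.normal(0.5, 0.01, 6)
        gate = direction_gate(a, a + 1e-4)
        assert gate["directive"] == "both"
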