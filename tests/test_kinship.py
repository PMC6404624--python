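"""Additive kinship, Hadamard epistatic kernels and background kernels."""

import numpy as np
import pandas as pd
import pytest

from epiarm.genome_model import GenotypeMatrix, assign_arms, arm_marker_sets
from epiarm.kinship import (
    KinshipMatrix,
    additive_kinship,
    background_kernels,
    epistatic_kernel,
)


def _geno(calls, lines=None, markers=None):
    calls = np.asarray(calls, dtype=float)
    lines = lines or [f"L{i}" for i in range(calls.shape[0])]
    markers = markers or [f"m{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(lines=lines, markers=markers, calls=calls)


class TestAdditiveKinship:
    def test_matches_hand_computation_4x3(self):
        calls = np.array(
            [
                [0, 2, 2],
                [2, 0, 2],
                [0, 0, 0],
                [2, 2, 0],
            ],
            dtype=float,
        )
        K = additive_kinship(_geno(calls)).values
        # independent element-by-element computation of W W' / (2 sum p q)
        p = calls.mean(axis=0) / 2.0
        W = calls - 2.0 * p
        denom = 2.0 * sum(pj * (1 - pj) for pj in p)
        expected = np.zeros((4, 4))
        for a in range(4):
            for b in range(4):
                expected[a, b] = sum(W[a, j] * W[b, j] for j in range(3)) / denom
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_identical_lines_identical_rows(self):
        calls = np.array([[0, 2, 0], [0, 2, 0], [2, 0, 2]], dtype=float)
        K = additive_kinship(_geno(calls)).values
        np.testing.assert_allclose(K[0], K[1])
        np.testing.assert_allclose(K[:, 0], K[:, 1])

    def test_centering_makes_rows_sum_to_zero(self, tiny_sim):
        # column sums of W are zero, hence K 1 = 0
        K = additive_kinship(tiny_sim.geno).values
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-8)

    def test_missing_calls_mean_imputed(self):
        calls = np.array([[0, 2], [2, 0], [np.nan, 2], [2, 0]])
        K = additive_kinship(_geno(calls)).values
        assert np.all(np.isfinite(K))

    def test_monomorphic_only_subset_raises(self):
        calls = np.array([[2.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="monomorphic"):
            additive_kinship(_geno(calls))

    def test_unknown_marker_raises(self, tiny_sim):
        with pytest.raises(KeyError, match="nonexistent"):
            additive_kinship(tiny_sim.geno, ["nonexistent"])

    def test_allele_swap_leaves_kernel_unchanged(self, tiny_sim):
        geno = tiny_sim.geno
        K1 = additive_kinship(geno).values
        swapped = geno.calls.copy()
        rng = np.random.default_rng(0)
        cols = rng.choice(geno.n_markers, size=geno.n_markers // 2, replace=False)
        swapped[:, cols] = 2.0 - swapped[:, cols]
        K2 = additive_kinship(_geno(swapped, geno.lines, geno.markers)).values
        np.testing.assert_allclose(K1, K2, atol=1e-10)

    def test_genome_kinship_partitions_over_arms(self, tiny_sim):
        """K(all) equals the numerator-weighted combination of per-arm kernels."""
        assignment = assign_arms(tiny_sim.marker_map, tiny_sim.centromeres)
        sets = arm_marker_sets(assignment)
        all_markers = [m for ms in sets.values() for m in ms]
        K_all = additive_kinship(tiny_sim.geno, all_markers)
        num = np.zeros_like(K_all.values)
        den = 0.0
        for arm, markers in sets.items():
            K_arm = additive_kinship(tiny_sim.geno, markers, label=arm)
            d = K_arm.provenance["denominator"]
            num += d * K_arm.values
            den += d
        np.testing.assert_allclose(K_all.values, num / den, atol=1e-8)
        assert abs(den - K_all.provenance["denominator"]) < 1e-8


class TestEpistaticKernel:
    def _psd(self, entry, n=4):
        K = np.eye(n)
        K[0, 1] = K[1, 0] = entry
        return KinshipMatrix(tuple(f"L{i}" for i in range(n)), K, {"label": "x"})

    def test_worked_entries(self):
        for entry, expected in ((0.1, 0.01), (0.9, 0.81)):
            prod = epistatic_kernel([self._psd(entry), self._psd(entry)])
            assert prod.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_hadamard_with_ones_is_identity_operation(self, tiny_sim):
        K = additive_kinship(tiny_sim.geno)
        ones = KinshipMatrix(K.line_ids, np.ones((K.n_lines, K.n_lines)), {"label": "1"})
        np.testing.assert_allclose(epistatic_kernel([K, ones]).values, K.values)

    def test_schur_product_stays_psd(self):
        rng = np.random.default_rng(3)
        ids = tuple(f"L{i}" for i in range(20))
        mats = []
        for _ in range(2):
            A = rng.standard_normal((20, 20))
            mats.append(KinshipMatrix(ids, A @ A.T / 20, {"label": "r"}))
        assert epistatic_kernel(mats).min_eigenvalue() >= -1e-8

    def test_three_way_entry_is_product_of_factors(self):
        a, b, c = (self._psd(e) for e in (0.2, 0.5, -0.3))
        prod = epistatic_kernel([a, b, c])
        assert prod.values[0, 1] == pytest.approx(0.2 * 0.5 * -0.3)

    def test_mismatched_line_order_raises(self):
        k1 = self._psd(0.1)
        k2 = KinshipMatrix(tuple(reversed(k1.line_ids)), k1.values, {})
        with pytest.raises(ValueError, match="mismatched line ids"):
            epistatic_kernel([k1, k2])

    def test_wrong_factor_count(self):
        with pytest.raises(ValueError, match="2 or 3"):
            epistatic_kernel([self._psd(0.1)])


class TestBackgroundKernels:
    def test_no_exclusion_equals_genome_kinship(self, tiny_sim):
        assignment = assign_arms(tiny_sim.marker_map, tiny_sim.centromeres)
        bg_a, _ = background_kernels(tiny_sim.geno, assignment)
        sets = arm_marker_sets(assignment)
        all_markers = [m for ms in sets.values() for m in ms]
        expected = additive_kinship(tiny_sim.geno, all_markers)
        np.testing.assert_allclose(bg_a.values, expected.values, atol=1e-12)

    def test_exclusion_matches_set_difference_oracle(self, tiny_sim):
        assignment = assign_arms(tiny_sim.marker_map, tiny_sim.centromeres)
        excl = {"1AS", "1BS"}
        bg_a, _ = background_kernels(tiny_sim.geno, assignment, excl)
        # independent complement construction
        sets = arm_marker_sets(assignment)
        complement = sorted(
            set(m for arm, ms in sets.items() if arm not in excl for m in ms)
        )
        expected = additive_kinship(tiny_sim.geno, complement)
        np.testing.assert_allclose(bg_a.values, expected.values, atol=1e-12)

    def test_epistatic_diagonal_is_squared_additive_diagonal(self, tiny_sim):
        assignment = assign_arms(tiny_sim.marker_map, tiny_sim.centromeres)
        bg_a, bg_i = background_kernels(tiny_sim.geno, assignment)
        np.testing.assert_allclose(np.diag(bg_i.values), np.diag(bg_a.values) ** 2)

    def test_excluding_everything_raises(self, tiny_sim):
        assignment = assign_arms(tiny_sim.marker_map, tiny_sim.centromeres)
        with pytest.raises(ValueError, match="no markers"):
            background_kernels(tiny_sim.geno, assignment, set(arm_marker_sets(assignment)))


class TestSerialization:
    def test_tsv_roundtrip_with_provenance(self, tmp_path, tiny_sim):
        K = additive_kinship(tiny_sim.geno, label="genome")
        K.to_tsv(tmp_path / "K.tsv")
        back = KinshipMatrix.from_tsv(tmp_path / "K.tsv")
        assert back.line_ids == K.line_ids
        np.testing.assert_allclose(back.values, K.values, atol=1e-9)
        assert back.provenance["label"] == "genome"

    def test_asymmetric_matrix_rejected(self):
        M = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            KinshipMatrix(("a", "b"), M, {})
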