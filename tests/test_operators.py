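"""Operator contracts checked against independently constructed dense
matrices (entrywise formulas, brute-force row enumeration)."""

from itertools import combinations

import numpy as np
import pytest

from gpmaps import SequenceSpace, cg_solve, count_coefficients
from gpmaps.operators import (
    CGError,
    DeltaPOperator,
    DiagonalOperator,
    LaplacianOperator,
    OrderProjectionOperator,
    SubsetProjectionOperator,
    SumOperator,
    VCKernelOperator,
    delta_rows_dense,
    projection_distance_profile,
)

from conftest import dense_laplacian, dense_subset_projection, pairwise_distances

SMALL_SPACES = [("01", 3), ("01", 4), ("ACG", 3), ("ACGT", 2), ("ACGT", 3)]


def space_of(alphabet, length):
    return SequenceSpace(alphabet, length)


class TestLaplacian:
    @pytest.mark.parametrize("alphabet,length", SMALL_SPACES)
    def test_matches_dense(self, alphabet, length, rng):
        space = space_of(alphabet, length)
        ld = dense_laplacian(space)
        f = rng.normal(size=space.n_genotypes)
        np.testing.assert_allclose(
            LaplacianOperator(space).matvec(f), ld @ f, atol=1e-10
        )

    def test_annihilates_constants(self, trinuc3):
        out = LaplacianOperator(trinuc3).matvec(np.full(27, 3.7))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_order_subspace_eigenvalues(self, rng):
        # L f_k = alpha * k * f_k for f_k = P_k(random)
        space = space_of("ACGT", 3)
        lap = LaplacianOperator(space)
        z = rng.normal(size=space.n_genotypes)
        for k in range(space.length + 1):
            fk = OrderProjectionOperator(space, k).matvec(z)
            np.testing.assert_allclose(
                lap.matvec(fk), space.alpha * k * fk, atol=1e-9
            )


class TestProjections:
    @pytest.mark.parametrize("alphabet,length", [("01", 3), ("ACG", 2), ("ACGT", 2)])
    def test_subset_projection_entrywise_formula(self, alphabet, length, rng):
        space = space_of(alphabet, length)
        for r in range(length + 1):
            for sites in combinations(range(length), r):
                pd = dense_subset_projection(space, sites)
                f = rng.normal(size=space.n_genotypes)
                np.testing.assert_allclose(
                    SubsetProjectionOperator(space, sites).matvec(f),
                    pd @ f, atol=1e-10,
                )

    def test_empty_subset_is_mean(self, trinuc3, rng):
        f = rng.normal(size=27)
        out = SubsetProjectionOperator(trinuc3, ()).matvec(f)
        np.testing.assert_allclose(out, np.full(27, f.mean()), atol=1e-12)

    def test_two_state_single_site_matrix(self):
        space = SequenceSpace("01", 1)
        dense = SubsetProjectionOperator(space, (0,)).to_dense()
        np.testing.assert_allclose(dense, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)
        np.testing.assert_allclose(
            SubsetProjectionOperator(space, (0,)).matvec([0.0, 1.0]),
            [-0.5, 0.5], atol=1e-12,
        )

    @pytest.mark.parametrize("alphabet,length", [("01", 4), ("ACG", 3)])
    def test_resolution_of_identity_and_orthogonality(self, alphabet, length, rng):
        space = space_of(alphabet, length)
        n = space.n_genotypes
        f = rng.normal(size=n)
        # sum over all orders = identity; distinct orders mutually orthogonal
        parts = [OrderProjectionOperator(space, k).matvec(f)
                 for k in range(length + 1)]
        np.testing.assert_allclose(np.sum(parts, axis=0), f, atol=1e-9)
        for k in range(length + 1):
            for j in range(k + 1, length + 1):
                assert abs(parts[k] @ parts[j]) < 1e-8
        # sum over all 2^l subsets = identity
        total = np.zeros(n)
        for r in range(length + 1):
            for sites in combinations(range(length), r):
                total += SubsetProjectionOperator(space, sites).matvec(f)
        np.testing.assert_allclose(total, f, atol=1e-9)

    def test_order_projection_equals_subset_sum(self, trinuc3, rng):
        f = rng.normal(size=27)
        for k in range(4):
            subs = sum(
                SubsetProjectionOperator(trinuc3, s).matvec(f)
                for s in combinations(range(3), k)
            )
            np.testing.assert_allclose(
                OrderProjectionOperator(trinuc3, k).matvec(f), subs, atol=1e-9
            )

    def test_idempotent(self, dna2, rng):
        f = rng.normal(size=16)
        for op in (OrderProjectionOperator(dna2, 1),
                   SubsetProjectionOperator(dna2, (0,))):
            once = op.matvec(f)
            np.testing.assert_allclose(op.matvec(once), once, atol=1e-10)

    def test_additive_map_has_no_pairwise_component(self, fixtures):
        f = fixtures["additive_2x2"]
        out = OrderProjectionOperator(f.space, 2).matvec(f.values)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)


class TestDeltaP:
    @pytest.mark.parametrize("alphabet,length,P", [
        ("01", 3, 2), ("01", 4, 2), ("01", 4, 3), ("ACG", 3, 2), ("ACGT", 2, 2),
    ])
    def test_matches_row_enumeration(self, alphabet, length, P, rng):
        space = space_of(alphabet, length)
        rows = delta_rows_dense(space, P)
        assert rows.shape[0] == count_coefficients(space, P)
        dense = rows.T @ rows
        op = DeltaPOperator(space, P)
        f = rng.normal(size=space.n_genotypes)
        np.testing.assert_allclose(op.matvec(f), dense @ f, atol=1e-9)
        assert op.quadratic_form(f) == pytest.approx(
            float(np.sum((rows @ f) ** 2)), rel=1e-10
        )

    def test_annihilates_low_orders(self, trinuc3, rng):
        z = rng.normal(size=27)
        delta = DeltaPOperator(trinuc3, 2)
        for k in (0, 1):
            fk = OrderProjectionOperator(trinuc3, k).matvec(z)
            np.testing.assert_allclose(delta.matvec(fk), 0.0, atol=1e-9)

    @pytest.mark.parametrize(
        "alphabet,length,P,s",
        [("01", 2, 2, 1), ("ACGT", 9, 2, 21_233_664), ("01", 3, 1, 12)],
    )
    def test_coefficient_counts(self, alphabet, length, P, s):
        space = SequenceSpace(alphabet, length)
        assert count_coefficients(space, P) == s

    def test_additive_landscape_has_zero_quadratic_form(self, fixtures):
        f = fixtures["additive_2x2"]
        assert DeltaPOperator(f.space, 2).quadratic_form(f.values) == \
            pytest.approx(0.0, abs=1e-12)

    def test_single_epistatic_coefficient(self, fixtures):
        f = fixtures["epistatic_2x2"]  # epsilon = 1, s = 1
        assert DeltaPOperator(f.space, 2).quadratic_form(f.values) == \
            pytest.approx(1.0, rel=1e-12)


class TestVCKernel:
    def test_constant_kernel(self, dna2, rng):
        lam = np.zeros(3)
        lam[0] = 1.0
        prof = VCKernelOperator(dna2, lam).distance_profile()
        np.testing.assert_allclose(prof, 1.0 / 16, atol=1e-12)

    def test_order1_profile_closed_form(self):
        space = SequenceSpace("01", 2)
        prof = projection_distance_profile(space, 1)
        np.testing.assert_allclose(prof, [0.5, 0.0, -0.5], atol=1e-12)

    @pytest.mark.parametrize("alphabet,length", [("01", 4), ("ACG", 3)])
    def test_matvec_matches_profile_built_dense(self, alphabet, length, rng):
        space = space_of(alphabet, length)
        lam = rng.uniform(size=space.length + 1)
        op = VCKernelOperator(space, lam)
        dense = op.distance_profile()[pairwise_distances(space)]
        f = rng.normal(size=space.n_genotypes)
        np.testing.assert_allclose(op.matvec(f), dense @ f, atol=1e-10)

    def test_negative_lambda_rejected(self, dna2):
        with pytest.raises(ValueError, match="nonnegative"):
            VCKernelOperator(dna2, [-1, 0, 0])


class TestLinearity:
    def test_operators_are_linear_and_symmetric(self, trinuc3, rng):
        ops = [
            LaplacianOperator(trinuc3),
            OrderProjectionOperator(trinuc3, 2),
            SubsetProjectionOperator(trinuc3, (0, 2)),
            DeltaPOperator(trinuc3, 2),
            VCKernelOperator(trinuc3, rng.uniform(size=4)),
        ]
        u = rng.normal(size=27)
        v = rng.normal(size=27)
        for op in ops:
            lhs = op.matvec(2.5 * u - 0.3 * v)
            rhs = 2.5 * op.matvec(u) - 0.3 * op.matvec(v)
            np.testing.assert_allclose(lhs, rhs, atol=1e-10 * max(
                1, np.abs(rhs).max()))
            assert u @ op.matvec(v) == pytest.approx(v @ op.matvec(u), rel=1e-9,
                                                     abs=1e-9)


class TestCG:
    def test_identity(self, binary3, rng):
        b = rng.normal(size=8)
        x, info = cg_solve(DiagonalOperator(binary3, np.ones(8)), b)
        np.testing.assert_allclose(x, b, atol=1e-10)
        assert info["converged"]

    def test_regularized_laplacian_matches_dense(self, binary3, rng):
        b = rng.normal(size=8)
        op = SumOperator(
            [LaplacianOperator(binary3), DiagonalOperator(binary3, np.ones(8))]
        )
        x, _ = cg_solve(op, b, tol=1e-10)
        dense = dense_laplacian(binary3) + np.eye(8)
        np.testing.assert_allclose(x, np.linalg.solve(dense, b), atol=1e-8)

    def test_singular_system_fails_loudly(self, binary3):
        # Laplacian is singular on constants: b with a constant component
        b = np.ones(8)
        with pytest.raises(CGError):
            cg_solve(LaplacianOperator(binary3), b, max_iter=50)


class TestMatvecCost:
    def test_projection_uses_l_laplacian_products(self):
        # the Lagrange route costs exactly l Laplacian applies per P_k matvec,
        # keeping each distance-operator product at O(l^2 alpha^l) operations
        space = SequenceSpace("ACGT", 5)
        proj = OrderProjectionOperator(space, 2)
        proj.matvec(np.zeros(space.n_genotypes))
        assert proj._lap.n_matvecs == space.length
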