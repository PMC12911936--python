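"""Matrix-free linear operators on complete genotype-phenotype maps.

Every operator here acts on vectors indexed over a full sequence space
(alpha^l entries) without materializing an (alpha^l x alpha^l) matrix.
Two structural facts make this possible:

* Any matrix whose entries depend only on the Hamming distance between the
  two genotypes is simultaneously diagonalized by the interaction-order
  decomposition of the Hamming graph: the graph Laplacian L has eigenvalue
  ``alpha * k`` on the subspace of pure order-k interactions, so such a
  matrix equals a degree-l polynomial in L and can be applied by repeated
  Laplacian products. This covers the order projections P_k, the
  variance-component kernels K = sum_k lambda_k P_k, and the epistasis
  operators Delta(P).

* Site-factored operators are Kronecker products of alpha x alpha factors
  (e.g. the subset projections P_U) and are applied axis-by-axis on the
  tensor view of the vector, at O(l * alpha^l) cost per product.

Dense materialization (``to_dense``) is available for small spaces and is
what the test suite checks every operator against.
"""

from __future__ import annotations

from math import comb

import numpy as np
import scipy.sparse.linalg as spla

from .seqspace import SequenceSpace

#: Largest space for which dense materialization is permitted.
DENSE_BUDGET = 4096


class SpaceOperator:
    """Base class: a symmetric linear operator over one sequence space."""

    symmetric = True
    psd = False

    def __init__(self, space: SequenceSpace):
        self.space = space
        self.shape = (space.n_genotypes, space.n_genotypes)
        self.n_matvecs = 0  # operation counter, for cost assertions

    def _matvec(self, f: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def matvec(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if f.shape != (self.space.n_genotypes,):
            raise ValueError(
                f"vector of length {f.shape} does not match space "
                f"({self.space.n_genotypes} genotypes)"
            )
        self.n_matvecs += 1
        return self._matvec(f)

    __call__ = matvec

    def to_scipy(self) -> spla.LinearOperator:
        return spla.LinearOperator(
            self.shape, matvec=self.matvec, rmatvec=self.matvec, dtype=float
        )

    def to_dense(self) -> np.ndarray:
        """Materialize the operator column by column (small spaces only)."""
        n = self.space.n_genotypes
        if n > DENSE_BUDGET:
            raise ValueError(
                f"dense materialization limited to {DENSE_BUDGET} genotypes"
            )
        out = np.empty((n, n))
        eye = np.eye(n)
        for j in range(n):
            out[:, j] = self._matvec(eye[:, j])
        return out


# ---------------------------------------------------------------------- #
class LaplacianOperator(SpaceOperator):
    """Graph Laplacian of the Hamming graph: L = l(alpha-1) I - A.

    Applied through the tensor view: the adjacency contribution of site p
    is the sum over that axis minus the vector itself, so
    ``L f = l * alpha * f - sum_p (axis-p sums of f)``.
    Eigenvalue on the order-k interaction subspace: ``alpha * k``.
    """

    psd = True

    def _matvec(self, f):
        space = self.space
        t = f.reshape(space.tensor_shape)
        out = space.length * space.alpha * t.astype(float, copy=True)
        for p in range(space.length):
            out -= t.sum(axis=p, keepdims=True)
        return out.reshape(-1)

    @property
    def eigenvalues_by_order(self) -> np.ndarray:
        return self.space.alpha * np.arange(self.space.length + 1, dtype=float)


class SubsetProjectionOperator(SpaceOperator):
    """Orthogonal projection P_U onto interactions among exactly the sites U.

    Kronecker product over sites of (I - J/alpha) for sites in U and J/alpha
    elsewhere; entrywise P_U(x, x') = alpha^-l * prod_{p in U} [(alpha-1) if
    x_p = x'_p else -1]. Applied by averaging over non-U axes and centering
    the U axes.
    """

    psd = True

    def __init__(self, space, sites):
        super().__init__(space)
        sites = sorted(set(int(s) for s in sites))
        if sites and (sites[0] < 0 or sites[-1] >= space.length):
            raise ValueError(f"site subset {sites} not within 0..{space.length - 1}")
        self.sites = tuple(sites)

    def _matvec(self, f):
        t = f.reshape(self.space.tensor_shape).astype(float, copy=True)
        in_u = set(self.sites)
        for p in range(self.space.length):
            m = t.mean(axis=p, keepdims=True)
            t = (t - m) if p in in_u else np.broadcast_to(m, t.shape).copy()
        return t.reshape(-1)


class OrderProjectionOperator(SpaceOperator):
    """Orthogonal projection P_k onto pure order-k interactions.

    Realized as the Lagrange polynomial in the Laplacian selecting the
    eigenvalue alpha*k:  P_k = prod_{j != k} (L - alpha*j) / (alpha*(k - j)),
    applied factor by factor (l Laplacian products per matvec, numerically
    stable). Equals sum over |U| = k of P_U.
    """

    psd = True

    def __init__(self, space, k: int):
        super().__init__(space)
        if not 0 <= k <= space.length:
            raise ValueError(f"order {k} not within 0..{space.length}")
        self.k = int(k)
        self._lap = LaplacianOperator(space)

    def _matvec(self, f):
        alpha, ell, k = self.space.alpha, self.space.length, self.k
        g = f.astype(float, copy=True)
        for j in range(ell + 1):
            if j == k:
                continue
            g = (self._lap.matvec(g) - alpha * j * g) / (alpha * (k - j))
        return g

    def distance_profile(self) -> np.ndarray:
        """P_k(d) for d = 0..l (the Krawtchouk profile): entries of P_k
        between genotypes at Hamming distance d."""
        return projection_distance_profile(self.space, self.k)


def projection_distance_profile(space: SequenceSpace, k: int) -> np.ndarray:
    """Entry of P_k between two genotypes at Hamming distance d, d = 0..l:

    P_k(d) = alpha^-l * sum_q (-1)^q (alpha-1)^(k-q) C(d,q) C(l-d, k-q).
    """
    alpha, ell = space.alpha, space.length
    d = np.arange(ell + 1)
    out = np.zeros(ell + 1)
    for q in range(k + 1):
        out += (
            (-1.0) ** q
            * (alpha - 1.0) ** (k - q)
            * np.array([comb(int(dd), q) * comb(ell - int(dd), k - q) for dd in d])
        )
    return out / alpha**ell


class DistancePolynomialOperator(SpaceOperator):
    """Any Hamming-distance-based operator, given its eigenvalue on each
    order subspace: A = sum_k a_k P_k."""

    def __init__(self, space, order_eigenvalues):
        super().__init__(space)
        self.order_eigenvalues = np.asarray(order_eigenvalues, dtype=float)
        if self.order_eigenvalues.shape != (space.length + 1,):
            raise ValueError("need one eigenvalue per interaction order 0..l")
        self.psd = bool(np.all(self.order_eigenvalues >= 0))
        self._projs = [
            OrderProjectionOperator(space, k) for k in range(space.length + 1)
        ]

    def _matvec(self, f):
        out = np.zeros_like(f, dtype=float)
        for a_k, proj in zip(self.order_eigenvalues, self._projs):
            if a_k != 0.0:
                out += a_k * proj._matvec(f)
        return out

    def distance_profile(self) -> np.ndarray:
        """A(d) for d = 0..l."""
        profiles = np.array(
            [projection_distance_profile(self.space, k)
             for k in range(self.space.length + 1)]
        )
        return self.order_eigenvalues @ profiles


class DeltaPOperator(DistancePolynomialOperator):
    """The order-P local-epistasis operator Delta(P).

    Its quadratic form f' Delta(P) f equals the sum of squared local P-way
    epistatic coefficients: one coefficient per choice of P sites, one
    unordered allele pair at each chosen site, and one background at the
    remaining sites — the P-th finite difference of f over the induced
    2^P sub-hypercube. Summing the rank-one row contributions site-factor
    by site-factor gives Delta(P) = sum_{|T|=P} kron_p (alpha*I - J if p in
    T else I), hence the eigenvalue alpha^P * C(k, P) on the order-k
    subspace; in particular every component of order k < P is annihilated.
    """

    def __init__(self, space, P: int):
        if not 1 <= P <= space.length:
            raise ValueError(f"order P={P} not within 1..{space.length}")
        ks = np.arange(space.length + 1)
        eigs = float(space.alpha) ** P * np.array([comb(int(k), P) for k in ks],
                                                  dtype=float)
        super().__init__(space, eigs)
        self.P = int(P)
        self.psd = True

    @property
    def n_coefficients(self) -> int:
        return count_coefficients(self.space, self.P)

    def quadratic_form(self, f) -> float:
        """f' Delta(P) f = sum of squared local P-way epistatic coefficients."""
        f = np.asarray(f, dtype=float)
        return float(f @ self.matvec(f))


def count_coefficients(space: SequenceSpace, P: int) -> int:
    """Number s of local P-way epistatic coefficients:
    C(l,P) * (alpha*(alpha-1)/2)^P * alpha^(l-P)."""
    if not 1 <= P <= space.length:
        raise ValueError(f"order P={P} not within 1..{space.length}")
    alpha, ell = space.alpha, space.length
    return comb(ell, P) * (alpha * (alpha - 1) // 2) ** P * alpha ** (ell - P)


class VCKernelOperator(DistancePolynomialOperator):
    """Variance-component prior covariance K = sum_k lambda_k P_k.

    The covariance between two genotypes depends only on their Hamming
    distance; ``distance_profile`` returns that K(d) curve.
    """

    def __init__(self, space, lambdas):
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.shape != (space.length + 1,):
            raise ValueError("need one lambda per interaction order 0..l")
        if np.any(lambdas < 0):
            raise ValueError("variance components lambda must be nonnegative")
        super().__init__(space, lambdas)
        self.lambdas = lambdas
        self.psd = True


class DiagonalOperator(SpaceOperator):
    def __init__(self, space, diag):
        super().__init__(space)
        self.diag = np.asarray(diag, dtype=float)

    def _matvec(self, f):
        return self.diag * f


class SumOperator(SpaceOperator):
    """Weighted sum of operators on a common space."""

    def __init__(self, ops, weights=None):
        super().__init__(ops[0].space)
        self.ops = list(ops)
        self.weights = [1.0] * len(ops) if weights is None else list(weights)

    def _matvec(self, f):
        out = np.zeros_like(f, dtype=float)
        for w, op in zip(self.weights, self.ops):
            if w != 0.0:
                out += w * op._matvec(np.asarray(f, dtype=float))
        return out


# ---------------------------------------------------------------------- #
class CGError(RuntimeError):
    """Conjugate-gradient solve failed to converge."""


def cg_solve(op, b, tol: float = 1e-8, max_iter: int | None = None,
             x0=None):
    """Solve A x = b for a symmetric positive-definite operator by CG.

    Returns ``(x, info)`` where info carries the iteration count and final
    relative residual. Raises :class:`CGError` on non-convergence — a
    singular system (e.g. an unregularized improper prior) surfaces here
    rather than returning silently.
    """
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("right-hand side must be finite")
    n = b.shape[0]
    if max_iter is None:
        max_iter = max(200, int(10 * np.sqrt(n)) + 10)
    A = op.to_scipy() if isinstance(op, SpaceOperator) else op
    n_iter = 0

    def cb(_xk):
        nonlocal n_iter
        n_iter += 1

    x, flag = spla.cg(A, b, x0=x0, rtol=tol, atol=0.0, maxiter=max_iter,
                      callback=cb)
    resid = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300)
    if flag != 0 or not np.isfinite(resid) or resid > 10 * tol:
        raise CGError(
            f"CG did not converge in {max_iter} iterations "
            f"(relative residual {resid:.3e}); the system may be singular"
        )
    return x, {"n_iter": n_iter, "residual": float(resid), "converged": True}


# ---------------------------------------------------------------------- #
# Brute-force oracles (test support; dense-budget spaces only)

def delta_rows_dense(space: SequenceSpace, P: int) -> np.ndarray:
    """Enumerate the finite-difference rows of Delta(P) as a dense (s, n)
    matrix A with Delta(P) = A' A. Exponential in P; test support only."""
    from itertools import combinations, product

    n = space.n_genotypes
    if n > DENSE_BUDGET:
        raise ValueError("row enumeration limited to dense-budget spaces")
    alpha, ell = space.alpha, space.length
    rows = []
    sites = range(ell)
    for T in combinations(sites, P):
        rest = [p for p in sites if p not in T]
        pairs = list(combinations(range(alpha), 2))
        for allele_pairs in product(pairs, repeat=P):
            for background in product(range(alpha), repeat=len(rest)):
                row = np.zeros(n)
                for choice in product(range(2), repeat=P):
                    codes = [0] * ell
                    for p, c in zip(rest, background):
                        codes[p] = c
                    sign = 1.0
                    for (site, pair, which) in zip(T, allele_pairs, choice):
                        codes[site] = pair[which]
                        sign *= (-1.0) ** which
                    idx = 0
                    for c in codes:
                        idx = idx * alpha + c
                    row[idx] += sign
                rows.append(row)
    return np.array(rows)
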