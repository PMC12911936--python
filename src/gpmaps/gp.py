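"""Gaussian-process inference of complete genotype-phenotype maps.

Two prior families are supported, both diagonal in the interaction-order
decomposition of sequence space:

* ``DeltaPrior(P, a)`` — improper Gaussian prior with precision
  C = (a/s) Delta(P), penalizing the mean squared local P-way epistatic
  coefficient and leaving all interactions of order < P unconstrained.
  Minimum-epistasis interpolation (MEI) is this prior's posterior mean:
  with noiseless data it is the exact constrained minimizer of
  f' Delta(P) f subject to f_x = y.

* ``VCPrior(lambdas)`` — proper prior with covariance K = sum_k lambda_k
  P_k; the lambdas are the prior variance components per interaction order
  and are estimated from data by kernel alignment against the empirical
  distance-covariance function.

All posterior means and contrast variances are computed matrix-free with
conjugate gradients; the dense closed forms serve as test oracles only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .operators import (
    DeltaPOperator,
    VCKernelOperator,
    cg_solve,
    count_coefficients,
    projection_distance_profile,
)
from .seqspace import LandscapeVector, ObservedData, SequenceSpace

MAX_EXACT_PAIRS_N = 20_000


# ---------------------------------------------------------------------- #
# Priors

@dataclass
class DeltaPrior:
    """Improper precision prior C = (a/s) Delta(P)."""

    P: int = 2
    a: float | None = None  # None: default weight a = s (unit coefficient)

    def scale(self, space: SequenceSpace) -> float:
        """The coefficient a/s multiplying the Delta(P) quadratic form."""
        s = count_coefficients(space, self.P)
        a = s if self.a is None else self.a
        if a <= 0:
            raise ValueError("prior strength a must be positive")
        return a / s


@dataclass
class VCPrior:
    """Proper covariance prior K = sum_k lambda_k P_k."""

    lambdas: np.ndarray

    def kernel(self, space: SequenceSpace) -> VCKernelOperator:
        return VCKernelOperator(space, self.lambdas)


# ---------------------------------------------------------------------- #
# Replicate pooling

def estimate_replicate_variance(replicates: pd.DataFrame
                                ) -> tuple[float, pd.DataFrame]:
    """Pool replicate measurements into a common variance estimate.

    ``replicates`` has columns ``sequence, y`` with one row per replicate
    measurement. Returns ``(sigma2, table)`` where sigma2 is the pooled
    variance sum_i SS_i / sum_i (n_i - 1) over genotypes with n_i >= 2
    replicates, and the table holds each genotype's replicate mean and the
    variance of that mean, sigma2 / n_i.
    """
    g = replicates.groupby("sequence", sort=False)["y"]
    n = g.size()
    if not (n >= 2).any():
        raise ValueError("no genotype has >= 2 replicates; cannot pool variance")
    ss = (g.apply(lambda v: float(np.sum((v - v.mean()) ** 2)))).sum()
    dof = int((n - 1).sum())
    sigma2 = float(ss) / dof
    table = pd.DataFrame(
        {
            "sequence": n.index,
            "y": g.mean().values,
            "var": sigma2 / n.values,
            "n_replicates": n.values,
        }
    ).reset_index(drop=True)
    return sigma2, table


# ---------------------------------------------------------------------- #
# Empirical distance-covariance and kernel alignment

def _site_codes(space: SequenceSpace, genotypes: np.ndarray) -> np.ndarray:
    return (genotypes[:, None] // space.powers[None, :]) % space.alpha


def empirical_distance_correlation(data: ObservedData,
                                   subtract_noise_at_zero: bool = True,
                                   max_pairs: int = 200_000_000,
                                   seed: int = 0) -> pd.DataFrame:
    """Average covariance of measurements as a function of Hamming distance.

    For d >= 1, c_d is the mean of (y_i - ybar)(y_j - ybar) over unordered
    observed pairs at distance d. The d = 0 row is the mean squared
    deviation with the mean known noise variance subtracted (it estimates
    the signal variance; flagged by the ``noise_corrected`` column).
    Distance classes with no pairs are reported with n_pairs = 0 and NaN.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 observations")
    space = data.space
    n = len(data)
    rng = np.random.default_rng(seed)
    codes = _site_codes(space, data.genotypes)
    ybar = float(np.mean(data.y))
    r = data.y - ybar

    ell = space.length
    sums = np.zeros(ell + 1)
    counts = np.zeros(ell + 1, dtype=np.int64)

    if n * (n - 1) // 2 <= max_pairs:
        chunk = max(1, 2_000_000 // max(n, 1))
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            d = (codes[start:stop, None, :] != codes[None, :, :]).sum(-1)
            prod = r[start:stop, None] * r[None, :]
            for i_local, i in enumerate(range(start, stop)):
                dj = d[i_local, i + 1:]
                pj = prod[i_local, i + 1:]
                np.add.at(sums, dj, pj)
                np.add.at(counts, dj, 1)
    else:  # seeded subsample of pairs
        m = max_pairs
        ii = rng.integers(0, n, size=m)
        jj = rng.integers(0, n, size=m)
        keep = ii < jj
        ii, jj = ii[keep], jj[keep]
        d = (codes[ii] != codes[jj]).sum(-1)
        np.add.at(sums, d, r[ii] * r[jj])
        np.add.at(counts, d, 1)

    # d = 0: squared deviations of the points themselves
    sums[0] = float(np.sum(r**2))
    counts[0] = n
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    noise_corrected = np.zeros(ell + 1, dtype=bool)
    if subtract_noise_at_zero:
        cov[0] -= float(np.mean(data.noise_var))
        noise_corrected[0] = True
    corr = cov / cov[0] if cov[0] != 0 else np.full_like(cov, np.nan)
    return pd.DataFrame(
        {
            "d": np.arange(ell + 1),
            "covariance": cov,
            "correlation": corr,
            "n_pairs": counts,
            "noise_corrected": noise_corrected,
        }
    )


def kernel_alignment_fit(distance_table: pd.DataFrame, space: SequenceSpace,
                         include_d0: bool = True,
                         max_order: int | None = None) -> np.ndarray:
    """Estimate prior variance components by kernel alignment.

    Solves the nonnegative weighted least squares problem
    argmin_{lambda >= 0} sum_d n_d (c_d - sum_k lambda_k P_k(d))^2 over
    orders k = 1..l (lambda_0 is fixed to 0: alignment is done on centered
    covariances). ``max_order`` truncates the fitted orders (e.g. 1 for an
    additive-only prior).
    """
    ell = space.length
    kmax = ell if max_order is None else int(max_order)
    tab = distance_table
    mask = (tab["n_pairs"].values > 0) & np.isfinite(tab["covariance"].values)
    if not include_d0:
        mask &= tab["d"].values != 0
    if mask.sum() < 2:
        raise ValueError("need >= 2 populated distance classes for alignment")
    d = tab["d"].values[mask]
    c = tab["covariance"].values[mask]
    w = np.sqrt(tab["n_pairs"].values[mask].astype(float))
    profiles = np.array(
        [projection_distance_profile(space, k) for k in range(1, kmax + 1)]
    )  # (kmax, l+1)
    design = profiles[:, d].T  # (n_d, kmax)
    sol, _ = nnls(design * w[:, None], c * w)
    lambdas = np.zeros(ell + 1)
    lambdas[1 : kmax + 1] = sol
    return lambdas


# ---------------------------------------------------------------------- #
# Posterior

@dataclass
class GaussianPosterior:
    """Posterior over complete maps: mean vector plus a matrix-free
    contrast-variance oracle (one CG solve per contrast)."""

    space: SequenceSpace
    mean: np.ndarray
    prior: object
    data: ObservedData
    diagnostics: dict = field(default_factory=dict)
    _var_solver: object = None

    @property
    def mean_landscape(self) -> LandscapeVector:
        return LandscapeVector(self.space, self.mean)

    def _as_vector(self, w) -> np.ndarray:
        if isinstance(w, dict):
            vec = np.zeros(self.space.n_genotypes)
            for idx, val in w.items():
                i = idx if isinstance(idx, (int, np.integer)) \
                    else self.space.seq_to_index(idx)
                vec[i] += val
            return vec
        w = np.asarray(w, dtype=float)
        if w.shape != (self.space.n_genotypes,):
            raise ValueError("contrast vector does not match the space")
        return w

    def contrast(self, w) -> tuple[float, float]:
        """Posterior mean and variance of the linear combination w' f."""
        w = self._as_vector(w)
        mean = float(w @ self.mean)
        var = float(self._var_solver(w))
        return mean, max(var, 0.0)

    def contrast_variance(self, w) -> float:
        return self.contrast(w)[1]

    def contrast_interval(self, w, z: float = 1.96):
        m, v = self.contrast(w)
        sd = np.sqrt(v)
        return m, (m - z * sd, m + z * sd)

    def mutational_effect_posterior(self, background: str, site: int,
                                    allele_from: str, allele_to: str):
        """Mean and 95% interval for f(background with allele_to at site)
        - f(background with allele_from at site); site is 0-based."""
        w = {}
        for allele, sign in ((allele_to, 1.0), (allele_from, -1.0)):
            seq = background[:site] + allele + background[site + 1:]
            w[self.space.seq_to_index(seq)] = sign
        return self.contrast_interval(w)

    def epistatic_coefficient_posterior(self, background: str,
                                        mut1: tuple, mut2: tuple):
        """Mean and 95% interval for the local epistatic coefficient of two
        mutations (site, from, to) on a background: weights (+1,-1,-1,+1)
        on the four genotypes of the 2x2 sub-square."""
        (s1, a1, b1), (s2, a2, b2) = mut1, mut2
        w = {}
        for x1, x2, sign in ((b1, b2, 1.0), (a1, b2, -1.0),
                             (b1, a2, -1.0), (a1, a2, 1.0)):
            seq = list(background)
            seq[s1], seq[s2] = x1, x2
            w["".join(seq)] = w.get("".join(seq), 0.0) + sign
        return self.contrast_interval(
            {self.space.seq_to_index(k): v for k, v in w.items()}
        )

    def predict(self, genotypes) -> np.ndarray:
        return self.mean[np.asarray(genotypes, dtype=np.int64)]


def fit_posterior(data: ObservedData, prior, cg_tol: float = 1e-10
                  ) -> GaussianPosterior:
    """Compute the Gaussian posterior over the complete map.

    VC priors use the covariance form: the posterior mean is
    fhat = ybar + K_{.x} (K_xx + D)^-1 (y - ybar) and contrast variances
    are w'Kw - v' (K_xx + D)^-1 v with v = (Kw)_x. Delta priors use the
    precision form; with exactly zero noise the observed values are
    interpolated exactly and the unobserved block solves
    Delta_zz f_z = -Delta_zx y.
    """
    if isinstance(prior, VCPrior):
        return _fit_vc(data, prior, cg_tol)
    if isinstance(prior, DeltaPrior):
        return _fit_delta(data, prior, cg_tol)
    raise TypeError(f"unknown prior type {type(prior).__name__}")


def _obs_operator(space, K, obs, noise_var):
    """LinearOperator for K_xx + D_sigma2 on the observed subspace."""
    import scipy.sparse.linalg as spla

    n = space.n_genotypes

    def mv(v):
        full = np.zeros(n)
        full[obs] = v
        return K.matvec(full)[obs] + noise_var * v

    return spla.LinearOperator((len(obs), len(obs)), matvec=mv, rmatvec=mv,
                               dtype=float)


def _fit_vc(data, prior, cg_tol):
    space = data.space
    K = prior.kernel(space)
    obs = data.genotypes
    # center by the inverse-variance weighted mean (uniform if noiseless)
    wts = 1.0 / np.maximum(data.noise_var, 1e-12)
    wts /= wts.sum()
    ybar = float(wts @ data.y)
    yc = data.y - ybar

    A = _obs_operator(space, K, obs, data.noise_var)
    alpha_vec, info = cg_solve(A, yc, tol=cg_tol)
    full = np.zeros(space.n_genotypes)
    full[obs] = alpha_vec
    mean = K.matvec(full) + ybar

    def var_solver(w):
        kw = K.matvec(w)
        v = kw[obs]
        if np.allclose(v, 0.0):
            return float(w @ kw)
        sol, _ = cg_solve(A, v, tol=cg_tol)
        return float(w @ kw - v @ sol)

    return GaussianPosterior(space, mean, prior, data,
                             diagnostics={"cg": info}, _var_solver=var_solver)


def _fit_delta(data, prior, cg_tol):
    import scipy.sparse.linalg as spla

    space = data.space
    n = space.n_genotypes
    delta = DeltaPOperator(space, prior.P)
    scale = prior.scale(space)
    obs = data.genotypes
    null_dim = sum(
        __import__("math").comb(space.length, k) * (space.alpha - 1) ** k
        for k in range(prior.P)
    )
    if len(obs) < null_dim:
        raise ValueError(
            f"improper Delta(P={prior.P}) prior needs >= {null_dim} "
            f"observations to pin its null space; got {len(obs)}"
        )

    noiseless = np.all(data.noise_var == 0)
    if not noiseless and np.any(data.noise_var == 0):
        raise ValueError(
            "delta priors require noise variances that are all zero or all "
            "positive"
        )

    if noiseless:
        unobs = np.setdiff1d(np.arange(n), obs)
        fhat = np.zeros(n)
        fhat[obs] = data.y
        if len(unobs):
            # Delta_zz f_z = -(Delta pad(y))_z
            rhs = -delta.matvec(fhat)[unobs]

            def mv(v):
                full = np.zeros(n)
                full[unobs] = v
                return delta.matvec(full)[unobs]

            A = spla.LinearOperator((len(unobs), len(unobs)), matvec=mv,
                                    rmatvec=mv, dtype=float)
            sol, info = cg_solve(A, rhs, tol=cg_tol)
            fhat[unobs] = sol
        else:
            A = None
            info = {"n_iter": 0, "residual": 0.0, "converged": True}

        def var_solver(w):
            if A is None:
                return 0.0
            wz = w[unobs]
            if np.allclose(wz, 0.0):
                return 0.0
            sol, _ = cg_solve(A, wz, tol=cg_tol)
            return float(wz @ sol) / scale

        return GaussianPosterior(space, fhat, prior, data,
                                 diagnostics={"cg": info},
                                 _var_solver=var_solver)

    # noisy: H = (a/s) Delta + R' D^-1 R
    inv_var = np.zeros(n)
    inv_var[obs] = 1.0 / data.noise_var

    def mv(v):
        return scale * delta.matvec(v) + inv_var * v

    H = spla.LinearOperator((n, n), matvec=mv, rmatvec=mv, dtype=float)
    rhs = np.zeros(n)
    rhs[obs] = data.y / data.noise_var
    fhat, info = cg_solve(H, rhs, tol=cg_tol)

    def var_solver(w):
        sol, _ = cg_solve(H, w, tol=cg_tol)
        return float(w @ sol)

    return GaussianPosterior(space, fhat, prior, data,
                             diagnostics={"cg": info}, _var_solver=var_solver)


def mei(data: ObservedData, P: int = 2, a: float | None = None,
        cg_tol: float = 1e-10) -> GaussianPosterior:
    """Minimum-epistasis interpolation of order P (delta-prior posterior)."""
    return fit_posterior(data, DeltaPrior(P=P, a=a), cg_tol=cg_tol)


def vc_regression(data: ObservedData, lambdas=None, cg_tol: float = 1e-8
                  ) -> GaussianPosterior:
    """Variance-component regression; lambdas estimated by kernel alignment
    from the data when not given."""
    if lambdas is None:
        table = empirical_distance_correlation(data)
        lambdas = kernel_alignment_fit(table, data.space)
    return fit_posterior(data, VCPrior(np.asarray(lambdas, float)), cg_tol)


# ---------------------------------------------------------------------- #
# Evaluation

DEFAULT_COVERAGE_LEVELS = (0.5, 0.8, 0.9, 0.95, 0.99)


def evaluate_predictions(post: GaussianPosterior, test: ObservedData,
                         levels=DEFAULT_COVERAGE_LEVELS,
                         compute_variances: bool = True) -> dict:
    """Held-out R^2 and credible-interval calibration.

    Coverage at level q is the fraction of test measurements within
    mean +- z_q * sqrt(posterior variance + test noise variance).
    """
    from scipy.stats import norm

    if len(test) == 0:
        raise ValueError("empty test set")
    overlap = np.intersect1d(post.data.genotypes, test.genotypes)
    if len(overlap):
        import warnings

        warnings.warn(f"{len(overlap)} test genotypes overlap the training set")
    pred = post.predict(test.genotypes)
    sse = float(np.sum((test.y - pred) ** 2))
    sstot = float(np.sum((test.y - np.mean(test.y)) ** 2))
    out = {"r2": 1.0 - sse / sstot if sstot > 0 else np.nan, "n_test": len(test)}
    if compute_variances:
        var = np.array(
            [post.contrast_variance({int(g): 1.0}) for g in test.genotypes]
        )
        sd = np.sqrt(var + test.noise_var)
        calib = {}
        for q in levels:
            z = norm.ppf(0.5 + q / 2.0)
            calib[q] = float(np.mean(np.abs(test.y - pred) <= z * sd))
        out["coverage"] = calib
        out["posterior_variance_mean"] = float(var.mean())
    return out
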