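"""Density estimation over sequence space (SeqDEFT).

Models the probability of observing each sequence as
pi_i = exp(-phi_i) / sum_j exp(-phi_j), places an improper Gaussian prior
on the latent field phi that penalizes its local P-way epistatic
coefficients, log p(phi | a) ~ -(a/2s) phi' Delta(P) phi, and combines it
with a multinomial likelihood over the observed counts. The MAP field is
found by quasi-Newton optimization of the convex negative log-posterior;
the hyperparameter a is selected by cross-validated held-out
log-likelihood over a log-spaced grid bracketed by the two limiting
models: a = 0 (empirical frequencies) and a = infinity (the maximum
entropy model within the null space of Delta(P) — for P = 2, the
independent-sites model matching the observed site marginals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .operators import DeltaPOperator, OrderProjectionOperator, cg_solve, \
    count_coefficients
from .seqspace import CountData, SequenceSpace

A_GRID_SIZE = 24
A_CURVATURE_SPAN = (1e-3, 1e3)  # penalty/likelihood curvature ratio range


@dataclass
class SeqDEFTModel:
    """A fitted sequence probability distribution.

    ``phi`` is the latent field (may contain +inf at the a = 0 endpoint for
    unobserved sequences); ``pi`` the normalized probabilities.
    """

    space: SequenceSpace
    P: int
    a: float  # np.inf and 0.0 mark the limiting models
    phi: np.ndarray
    pi: np.ndarray
    counts: CountData | None = None
    diagnostics: dict = field(default_factory=dict)

    def log_pi(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.pi)


def _phi_to_pi(phi: np.ndarray) -> np.ndarray:
    lse = logsumexp(-phi)
    return np.exp(-phi - lse)


def seqdeft_objective(phi: np.ndarray, counts: CountData, P: int, a: float
                      ) -> tuple[float, np.ndarray]:
    """Negative log-posterior (up to constants) and its gradient.

    value = (a/2s) phi' Delta(P) phi + sum_i N_i phi_i
            + N_T log sum_j exp(-phi_j)
    The log-sum-exp is overflow-guarded. The gradient is
    (a/s) Delta(P) phi + N - N_T pi(phi).
    """
    if not (np.isfinite(a) and a > 0):
        raise ValueError("objective defined for finite a > 0")
    space = counts.space
    delta = DeltaPOperator(space, P)
    s = count_coefficients(space, P)
    n = counts.counts.astype(float)
    n_total = n.sum()
    dphi = delta.matvec(phi)
    lse = logsumexp(-phi)
    value = 0.5 * (a / s) * float(phi @ dphi) + float(n @ phi) + n_total * lse
    pi = np.exp(-phi - lse)
    grad = (a / s) * dphi + n - n_total * pi
    return value, grad


def _independent_sites_pi(counts: CountData) -> np.ndarray:
    """Product-of-site-marginals distribution matching observed marginals."""
    space = counts.space
    t = counts.counts.reshape(space.tensor_shape).astype(float)
    n_total = t.sum()
    pi = np.ones(space.tensor_shape)
    for p in range(space.length):
        axes = tuple(q for q in range(space.length) if q != p)
        marg = t.sum(axis=axes) / n_total
        shape = [1] * space.length
        shape[p] = space.alpha
        pi = pi * marg.reshape(shape)
    return pi.reshape(-1)


def _nullspace_maxent(counts: CountData, P: int) -> np.ndarray:
    """a = inf limit for general P: maximize the multinomial likelihood over
    phi restricted to the null space of Delta(P) (interactions of order < P),
    by optimizing an unconstrained field projected onto that subspace."""
    space = counts.space
    projs = [OrderProjectionOperator(space, k) for k in range(P)]

    def proj(v):
        return sum(p.matvec(v) for p in projs)

    n = counts.counts.astype(float)
    n_total = n.sum()

    def obj(psi):
        phi = proj(psi)
        lse = logsumexp(-phi)
        val = float(n @ phi) + n_total * lse
        pi = np.exp(-phi - lse)
        grad = proj(n - n_total * pi)
        return val, grad

    res = minimize(obj, np.zeros(space.n_genotypes), jac=True,
                   method="L-BFGS-B", options={"maxiter": 2000, "gtol": 1e-8})
    phi = proj(res.x)
    return _phi_to_pi(phi)


def seqdeft_map(counts: CountData, P: int = 2, a: float = None,
                phi0: np.ndarray | None = None, gtol: float = 1e-6
                ) -> SeqDEFTModel:
    """MAP estimate of the sequence distribution at a given prior strength.

    ``a = 0`` returns the empirical frequencies (unobserved sequences get
    probability zero); ``a = np.inf`` returns the maximum-entropy model in
    the Delta(P) null space (independent sites for P = 2). Finite ``a``
    minimizes the convex objective by limited-memory quasi-Newton, warm
    started from ``phi0`` (defaults to the a = inf solution).
    """
    space = counts.space
    if a is None:
        raise ValueError("a must be given (possibly 0 or np.inf)")
    if a == 0:
        pi = counts.frequencies().astype(float)
        with np.errstate(divide="ignore"):
            phi = -np.log(pi)
        return SeqDEFTModel(space, P, 0.0, phi, pi, counts,
                            {"note": "empirical frequencies (a=0 limit)"})
    if np.isinf(a):
        pi = (_independent_sites_pi(counts) if P == 2
              else _nullspace_maxent(counts, P))
        with np.errstate(divide="ignore"):
            phi = -np.log(pi)
        return SeqDEFTModel(space, P, np.inf, phi, pi, counts,
                            {"note": "max-ent model in the Delta(P) null space"})

    if phi0 is None:
        ref = seqdeft_map(counts, P, np.inf)
        phi0 = np.where(np.isfinite(ref.phi), ref.phi, np.nanmax(
            np.where(np.isfinite(ref.phi), ref.phi, np.nan)) + 10.0)
        phi0 = phi0 - phi0.mean()

    def fun(phi):
        return seqdeft_objective(phi, counts, P, a)

    res = minimize(fun, phi0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "gtol": gtol, "ftol": 1e-14})
    phi = res.x
    pi = _phi_to_pi(phi)
    return SeqDEFTModel(
        space=space, P=P, a=float(a), phi=phi, pi=pi, counts=counts,
        diagnostics={"n_iter": res.nit,
                     "grad_norm": float(np.max(np.abs(res.jac))),
                     "converged": bool(res.success)},
    )


def default_a_grid(counts: CountData, P: int = 2, size: int = A_GRID_SIZE
                   ) -> np.ndarray:
    """Log-spaced grid of prior strengths a.

    Scaled so that the top curvature of the penalty, (a/s) * alpha^P C(l,P),
    spans from well below to well above the likelihood curvature scale N_T.
    """
    from math import comb

    space = counts.space
    s = count_coefficients(space, P)
    d_top = float(space.alpha) ** P * comb(space.length, P)
    lo = A_CURVATURE_SPAN[0] * counts.total * s / d_top
    hi = A_CURVATURE_SPAN[1] * counts.total * s / d_top
    return np.geomspace(lo, hi, size)


def _expand_draws(counts: CountData) -> np.ndarray:
    return np.repeat(np.arange(counts.space.n_genotypes), counts.counts)


def seqdeft_cv(counts: CountData, P: int = 2, a_grid=None, n_folds: int = 5,
               seed: int = 0) -> tuple[pd.DataFrame, float]:
    """Select a by k-fold cross-validated held-out log-likelihood.

    The individual observation draws (multinomial events, not genotypes)
    are shuffled with the seed and split into folds. For each a (the grid
    plus the 0 and infinity reference limits) and each fold, the MAP model
    is fitted on the training counts and scored by the mean per-observation
    log probability of the held-out draws (log 0 reported as -inf). Returns
    the score table and the maximizing a*.
    """
    if counts.total < n_folds:
        raise ValueError("need at least n_folds observations")
    if a_grid is None:
        a_grid = default_a_grid(counts, P)
    a_values = np.concatenate([[0.0], np.sort(a_grid), [np.inf]])

    rng = np.random.default_rng(seed)
    draws = _expand_draws(counts)
    rng.shuffle(draws)
    folds = np.array_split(draws, n_folds)

    space = counts.space
    rows = []
    for fold_id, held in enumerate(folds):
        train_counts = counts.counts.copy()
        np.subtract.at(train_counts, held, 1)
        train = CountData(space, train_counts)
        held_counts = np.bincount(held, minlength=space.n_genotypes)
        # warm start along the grid from large a down to small
        phi0 = None
        scores = {}
        for a in a_values[::-1]:
            model = seqdeft_map(train, P, a, phi0=phi0)
            if np.isfinite(a):
                phi0 = model.phi
            with np.errstate(divide="ignore"):
                logpi = np.log(model.pi)
            ll = held_counts @ np.where(held_counts > 0, logpi, 0.0)
            scores[a] = ll / held_counts.sum()
        for a in a_values:
            rows.append({"a": a, "fold": fold_id, "log_likelihood": scores[a]})

    table = pd.DataFrame(rows)
    mean_curve = table.groupby("a")["log_likelihood"].mean()
    a_star = float(mean_curve.idxmax())
    return table, a_star


def seqdeft_fit(counts: CountData, P: int = 2, n_folds: int = 5,
                seed: int = 0) -> SeqDEFTModel:
    """Full SeqDEFT pipeline: CV grid search over a, then MAP at a*."""
    table, a_star = seqdeft_cv(counts, P, n_folds=n_folds, seed=seed)
    model = seqdeft_map(counts, P, a_star)
    model.diagnostics["cv_table"] = table
    model.diagnostics["a_star"] = a_star
    return model


def seqdeft_contrast_variance(model: SeqDEFTModel, w) -> float:
    """Laplace-approximate posterior variance of w' phi.

    Uses the Hessian of the objective at the MAP,
    H = (a/s) Delta(P) + N_T (diag(pi) - pi pi'), solved by CG. H
    annihilates constant fields (the gauge direction of phi), so the
    constant component of w is projected out; contrasts (sum of w zero)
    are gauge-invariant and unaffected.
    """
    import scipy.sparse.linalg as spla

    if not np.isfinite(model.a) or model.a <= 0:
        raise ValueError("Laplace variance requires a finite positive a")
    space = model.space
    n = space.n_genotypes
    delta = DeltaPOperator(space, model.P)
    s = count_coefficients(space, model.P)
    n_total = model.counts.total
    pi = model.pi
    w = np.asarray(w, dtype=float)
    if abs(w.sum()) > 1e-10 * max(np.abs(w).sum(), 1.0):
        import warnings

        warnings.warn(
            "contrast weights do not sum to zero: the result depends on the "
            "gauge of phi; projecting out the constant component"
        )
    wc = w - w.mean()

    def mv(v):
        vc = v - v.mean()
        hv = (model.a / s) * delta.matvec(vc) \
            + n_total * (pi * vc - pi * float(pi @ vc))
        return hv + v.mean()  # identity on the constant gauge direction

    H = spla.LinearOperator((n, n), matvec=mv, rmatvec=mv, dtype=float)
    sol, _ = cg_solve(H, wc, tol=1e-8)
    return max(float(wc @ sol), 0.0)
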