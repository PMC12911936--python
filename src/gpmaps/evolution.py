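"""Weak-mutation evolutionary model and diffusion-axis visualization.

In the weak-mutation (origin-fixation) regime a population occupies a
single genotype and substitutes one mutation at a time. The substitution
rate from genotype i to a Hamming neighbor j is

    Q(i, j) = M(i, j) * S / (1 - exp(-S)),    S = c * (f(j) - f(i)),

the mutation rate times the fixation probability relative to a neutral
mutation (value M at S = 0 by continuity); c is the scaled selection
coefficient per unit phenotype. The chain is reversible with stationary
distribution pi(i) proportional to pi_M(i) * exp(c * f(i)).

Diffusion axes are the subdominant right eigenvectors of Q, D_pi-normalized
and rescaled by 1/sqrt(-eigenvalue); squared distances between genotypes in
the full embedding equal commute times H(i,j) + H(j,i), and truncations
optimally approximate them. Relaxation times -1/lambda_k flag axes that
decay more slowly than neutral (neutral relaxation time: 1/alpha for a
uniform alphabet with unit mutation rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from .seqspace import LandscapeVector, SequenceSpace

DENSE_STATE_BUDGET = 256


def _fixation_factor(s: np.ndarray) -> np.ndarray:
    """S / (1 - exp(-S)), with the neutral limit 1 at S = 0."""
    s = np.asarray(s, dtype=float)
    out = np.ones_like(s)
    nz = np.abs(s) > 1e-12
    out[nz] = s[nz] / -np.expm1(-s[nz])
    return out


@dataclass
class EvoModel:
    """Weak-mutation substitution model on a phenotype landscape.

    ``edge_mutation_rates`` optionally gives a symmetric per-edge mutation
    rate (aligned with ``space.edge_list()``); the default is 1 on every
    edge, in which case the neutral stationary distribution pi_M is uniform.
    """

    space: SequenceSpace
    f: np.ndarray
    c: float = 1.0
    edge_mutation_rates: np.ndarray | None = None

    def __post_init__(self):
        self.f = self.f.values if isinstance(self.f, LandscapeVector) \
            else np.asarray(self.f, dtype=float)
        if self.f.shape != (self.space.n_genotypes,):
            raise ValueError("landscape does not match the space")
        if self.c < 0:
            raise ValueError("c must be nonnegative")
        self.edges = self.space.edge_list()
        if self.edge_mutation_rates is None:
            self.edge_mutation_rates = np.ones(len(self.edges))
        self.edge_mutation_rates = np.asarray(self.edge_mutation_rates, float)
        if np.any(self.edge_mutation_rates <= 0):
            raise ValueError("mutation rates must be positive")

    def stationary_distribution(self) -> np.ndarray:
        """pi(i) ~ pi_M(i) * exp(c f(i)), overflow-guarded by max-shift.

        With uniform edge rates pi_M is uniform; otherwise pi_M is obtained
        from the symmetric-rate random walk, whose stationary distribution
        is proportional to the (constant-degree-corrected) node strength.
        """
        log_pi = self.c * self.f
        if not np.allclose(self.edge_mutation_rates,
                           self.edge_mutation_rates[0]):
            strength = np.zeros(self.space.n_genotypes)
            np.add.at(strength, self.edges[:, 0], self.edge_mutation_rates)
            np.add.at(strength, self.edges[:, 1], self.edge_mutation_rates)
            log_pi = log_pi + np.log(strength)
        log_pi -= log_pi.max()
        pi = np.exp(log_pi)
        return pi / pi.sum()

    def rate_matrix(self) -> sp.csr_matrix:
        """Sparse substitution rate matrix Q (rows sum to zero)."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        s_fwd = self.c * (self.f[j] - self.f[i])
        q_fwd = self.edge_mutation_rates * _fixation_factor(s_fwd)
        q_bwd = self.edge_mutation_rates * _fixation_factor(-s_fwd)
        n = self.space.n_genotypes
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        vals = np.concatenate([q_fwd, q_bwd])
        q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        q.setdiag(-np.asarray(q.sum(axis=1)).ravel())
        return q

    def mean_stationary_phenotype(self, c: float | None = None) -> float:
        model = self if c is None else EvoModel(
            self.space, self.f, c, self.edge_mutation_rates)
        return float(model.stationary_distribution() @ model.f)


def calibrate_c(space: SequenceSpace, f, target_mean_phenotype: float,
                tol_factor: float = 1e-8, c_max: float = 1e4) -> float:
    """Find c >= 0 so the stationary mean phenotype hits the target.

    E_pi[f] increases strictly from mean(f) at c = 0 toward max(f) as
    c -> inf, so the target must lie in (mean(f), max(f)); solved by
    bracketed root finding to |E_pi[f] - target| <= tol_factor * range(f).
    """
    f = f.values if isinstance(f, LandscapeVector) else np.asarray(f, float)
    fbar, fmax = float(np.mean(f)), float(np.max(f))
    if np.isclose(target_mean_phenotype, fbar):
        return 0.0
    if not fbar < target_mean_phenotype < fmax:
        raise ValueError(
            f"target {target_mean_phenotype} outside the achievable range "
            f"({fbar:.6g}, {fmax:.6g}) for c >= 0"
        )

    def gap(c):
        return EvoModel(space, f, c).mean_stationary_phenotype() \
            - target_mean_phenotype

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > c_max:
            raise ValueError(f"target not reachable below c = {c_max}")
    c = brentq(gap, 0.0, hi, xtol=tol_factor * (np.ptp(f) or 1.0) / 10,
               rtol=1e-12)
    return float(c)


@dataclass
class Embedding:
    """Diffusion-axis coordinates and spectral metadata.

    ``coordinates[:, a]`` is diffusion axis a+1: the (a+2)-th right
    eigenvector of Q, normalized to unit pi-weighted norm and scaled by
    (-lambda)^(-1/2) so that full-rank squared embedding distances equal
    commute times. Eigenvalues are sorted descending (all < 0).
    """

    space: SequenceSpace
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    stationary: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def relaxation_times(self) -> np.ndarray:
        return -1.0 / self.eigenvalues

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self, f=None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"axis_{a + 1}" for a in range(self.n_axes)],
        )
        df.insert(0, "sequence", self.space.all_sequences())
        if f is not None:
            vals = f.values if isinstance(f, LandscapeVector) else np.asarray(f)
            df.insert(1, "phenotype", vals)
        df["stationary_prob"] = self.stationary
        return df


def diffusion_axes(model: EvoModel, k: int = 3, seed: int = 0,
                   full: bool = False) -> Embedding:
    """Compute the top-k diffusion axes of the substitution chain.

    Eigenpairs of Q are obtained from the symmetrized operator
    Omega = D_pi^(1/2) Q D_pi^(-1/2) (Lanczos with a seeded start vector;
    dense symmetric solve when ``full``). The trivial zero eigenvalue is
    discarded; each remaining right eigenvector r is normalized so
    r' D_pi r = 1, scaled by (-lambda)^(-1/2), and sign-fixed so its
    largest-magnitude coordinate is positive. Ties in the spectrum are
    flagged: axes within a tie span the right subspace but are an
    arbitrary orthogonal basis of it.
    """
    if k < 1:
        raise ValueError("need k >= 1 axes")
    n = model.space.n_genotypes
    if k + 1 > n:
        raise ValueError(f"at most {n - 1} axes exist")
    pi = model.stationary_distribution()
    q = model.rate_matrix()
    sqrt_pi = np.sqrt(pi)
    d = sp.diags(sqrt_pi)
    d_inv = sp.diags(1.0 / sqrt_pi)
    omega = d @ q @ d_inv
    omega = (omega + omega.T) / 2.0  # exactly symmetric (reversibility)

    if full or k + 1 >= n - 1:
        if n > DENSE_STATE_BUDGET and not full:
            raise ValueError("full spectrum limited to dense-budget spaces")
        evals, evecs = np.linalg.eigh(omega.toarray())
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        n_keep = n - 1 if full else k
        evals, evecs = evals[1:n_keep + 1], evecs[:, 1:n_keep + 1]
        resid = 0.0
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        evals, evecs = spla.eigsh(omega, k=k + 1, which="LA", v0=v0,
                                  tol=1e-12)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order][1:], evecs[:, order][:, 1:]
        resid = float(
            max(np.linalg.norm(omega @ evecs[:, a] - evals[a] * evecs[:, a])
                for a in range(evecs.shape[1]))
        )

    if np.any(evals >= -1e-12):
        raise RuntimeError("nontrivial eigenvalues must be negative; "
                           "eigensolver failure or disconnected chain")
    gaps = np.diff(evals)
    if np.any(np.abs(gaps) < 1e-10 * np.abs(evals[:-1])):
        warnings.warn("degenerate eigenvalues: tied axes form an arbitrary "
                      "orthogonal basis of their eigenspace")

    coords = np.empty_like(evecs)
    for a in range(evecs.shape[1]):
        v = evecs[:, a]
        r = v / sqrt_pi           # right eigenvector of Q
        r /= np.sqrt(pi @ r**2)   # r' D_pi r = 1
        if r[np.argmax(np.abs(r))] < 0:
            r = -r
        coords[:, a] = r / np.sqrt(-evals[a])
    return Embedding(model.space, coords, evals, pi,
                     {"eig_residual": resid})


def hitting_time(model: EvoModel, i: int, j: int) -> float:
    """Expected time to first reach j from i (dense oracle, test support).

    Solves the linear system on Q with state j absorbing:
    (Q with row/column j deleted) h = -1, H(i, j) = h_i.
    """
    n = model.space.n_genotypes
    if n > DENSE_STATE_BUDGET:
        raise ValueError("hitting-time oracle limited to dense-budget spaces")
    if i == j:
        return 0.0
    q = model.rate_matrix().toarray()
    keep = [s for s in range(n) if s != j]
    sub = q[np.ix_(keep, keep)]
    h = np.linalg.solve(sub, -np.ones(n - 1))
    return float(h[keep.index(i)])


def commute_time(model: EvoModel, i: int, j: int) -> float:
    return hitting_time(model, i, j) + hitting_time(model, j, i)


# ---------------------------------------------------------------------- #
def export_visualization(embedding: Embedding, f, nodes_path, edges_path,
                         plot_path=None):
    """Write nodes/edges CSVs and optionally a static scatter plot.

    Nodes: sequence, phenotype, axis_1..axis_k, stationary_prob. Edges:
    genotype index pairs of the Hamming graph. The plot shows axes (1, 2)
    colored by phenotype, drawing dots in the order of axis 3 (falling back
    to phenotype order, with a warning, when fewer than 3 axes exist).
    """
    nodes = embedding.to_frame(f)
    nodes.to_csv(nodes_path, index=False, float_format="%.17g")
    edges = embedding.space.edge_list()
    pd.DataFrame(edges, columns=["i", "j"]).to_csv(edges_path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vals = f.values if isinstance(f, LandscapeVector) else np.asarray(f)
        if embedding.n_axes >= 3:
            order = np.argsort(embedding.coordinates[:, 2])
        else:
            warnings.warn("fewer than 3 axes: drawing in phenotype order")
            order = np.argsort(vals)
        x = embedding.coordinates[order, 0]
        y = embedding.coordinates[order, 1]
        fig, ax = plt.subplots(figsize=(6, 5))
        for a, b in edges:
            ax.plot(
                embedding.coordinates[[a, b], 0],
                embedding.coordinates[[a, b], 1],
                color="0.8", lw=0.3, zorder=1,
            )
        sc = ax.scatter(x, y, c=vals[order], s=12, cmap="viridis", zorder=2)
        fig.colorbar(sc, ax=ax, label="phenotype")
        ax.set_xlabel("Diffusion axis 1")
        ax.set_ylabel("Diffusion axis 2")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return nodes
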