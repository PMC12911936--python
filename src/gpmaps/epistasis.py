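"""Epistasis summary statistics for complete genotype-phenotype maps.

Quantifies epistasis two ways: (i) the root mean squared local P-way
epistatic coefficient — the typical P-th order finite difference of the map
over 2^P sub-hypercubes — computed as a quadratic form with the Delta(P)
operator; and (ii) the decomposition of phenotypic variance into the
mutually orthogonal interaction-order subspaces and, more finely, into the
2^l subspaces indexed by subsets of sites, with per-site and per-pair
aggregates.

"Variance" throughout is the population variance over all alpha^l genotypes
with uniform weight — the inner product under which the projections are
orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .operators import (
    DeltaPOperator,
    SubsetProjectionOperator,
    count_coefficients,
)
from .seqspace import LandscapeVector, SequenceSpace

#: by-subset enumeration allowed up to 2^l = 4096 subsets
SUBSET_LENGTH_BUDGET = 12


def _values(f):
    return f.values if isinstance(f, LandscapeVector) else np.asarray(f, float)


def rms_epistatic_coefficient(space: SequenceSpace, f, P: int = 2) -> float:
    """Root mean squared local P-way epistatic coefficient.

    sqrt(f' Delta(P) f / s) with s the number of coefficients; same units
    as the phenotype. Zero iff the map has no interactions of order >= P.
    """
    f = _values(f)
    quad = DeltaPOperator(space, P).quadratic_form(f)
    return float(np.sqrt(max(quad, 0.0) / count_coefficients(space, P)))


def rms_mutational_effect(space: SequenceSpace, f) -> float:
    """Root mean square of f(j) - f(i) over all Hamming-graph edges
    (each unordered neighbor pair counted once)."""
    f = _values(f)
    edges = space.edge_list()
    diffs = f[edges[:, 1]] - f[edges[:, 0]]
    return float(np.sqrt(np.mean(diffs**2)))


@dataclass
class VarianceDecomposition:
    """Phenotypic variance split across interaction orders (and optionally
    across site subsets U).

    ``by_order[k]`` is the variance mass ||P_k f||^2 / alpha^l; the k = 0
    entry is the squared mean and is excluded from "variance explained"
    fractions. ``by_subset`` maps each site subset to its mass v_U, with
    sum over |U| = k of v_U equal to by_order[k].
    """

    space: SequenceSpace
    by_order: np.ndarray
    total_variance: float
    by_subset: dict | None = None

    def fractions(self) -> np.ndarray:
        """Fraction of total variance per order k >= 1 (sums to 1)."""
        v = self.by_order[1:]
        tot = v.sum()
        return v / tot if tot > 0 else np.zeros_like(v)

    def to_frame(self) -> pd.DataFrame:
        ks = np.arange(self.space.length + 1)
        frac = np.concatenate([[np.nan], self.fractions()])
        return pd.DataFrame(
            {"order": ks, "variance": self.by_order,
             "fraction_of_total_variance": frac}
        )


def variance_components(space: SequenceSpace, f,
                        by_subset: bool = False) -> VarianceDecomposition:
    """Decompose the map's variance by interaction order (and subsets).

    v_k = ||P_k f||^2 / alpha^l for k = 0..l; sum over k >= 1 equals the
    population variance of f. With ``by_subset``, every one of the 2^l
    subset masses v_U = ||P_U f||^2 / alpha^l is computed (l <= 12).
    """
    f = _values(f)
    n = space.n_genotypes
    total_var = float(np.var(f))
    subsets = None
    if by_subset:
        if space.length > SUBSET_LENGTH_BUDGET:
            raise ValueError(
                f"by-subset decomposition limited to l <= {SUBSET_LENGTH_BUDGET}"
            )
        subsets = {}
        by_order = np.zeros(space.length + 1)
        for k in range(space.length + 1):
            for U in combinations(range(space.length), k):
                g = SubsetProjectionOperator(space, U).matvec(f)
                v = float(g @ g) / n
                subsets[U] = v
                by_order[k] += v
    else:
        from .operators import OrderProjectionOperator

        by_order = np.array(
            [
                float(np.sum(OrderProjectionOperator(space, k).matvec(f) ** 2)) / n
                for k in range(space.length + 1)
            ]
        )
    return VarianceDecomposition(space, by_order, total_var, subsets)


def site_order_variance(space: SequenceSpace, f,
                        decomposition: VarianceDecomposition | None = None
                        ) -> pd.DataFrame:
    """Percentage of total variance explained by order-k interactions
    involving each site: entry (site i, order k) = 100 * sum over subsets U
    with i in U, |U| = k of v_U / total variance."""
    if decomposition is None or decomposition.by_subset is None:
        decomposition = variance_components(space, f, by_subset=True)
    tot = decomposition.by_order[1:].sum()
    table = np.zeros((space.length, space.length))
    for U, v in decomposition.by_subset.items():
        k = len(U)
        if k == 0:
            continue
        for i in U:
            table[i, k - 1] += v
    df = pd.DataFrame(
        100.0 * table / tot if tot > 0 else table,
        index=pd.Index(np.arange(1, space.length + 1), name="site"),
        columns=pd.Index(np.arange(1, space.length + 1), name="order"),
    )
    return df


def pair_variance(space: SequenceSpace, f, mode: str = "pairwise_only",
                  normalization: str = "total",
                  decomposition: VarianceDecomposition | None = None
                  ) -> pd.DataFrame:
    """Per-site-pair variance table (percent).

    mode="pairwise_only": entry (i, j) = v_{{i,j}}, the mass of the pure
    pairwise interaction between sites i and j. mode="higher_order": sum of
    v_U over U containing both sites with |U| >= 3. ``normalization`` is
    "total" (percent of total variance) or, for higher_order,
    "higher_order" (percent of the total order >= 3 mass).
    """
    if mode not in ("pairwise_only", "higher_order"):
        raise ValueError(f"unknown mode {mode!r}")
    if decomposition is None or decomposition.by_subset is None:
        decomposition = variance_components(space, f, by_subset=True)
    ell = space.length
    table = np.zeros((ell, ell))
    for U, v in decomposition.by_subset.items():
        if mode == "pairwise_only" and len(U) == 2:
            i, j = U
            table[i, j] += v
            table[j, i] += v
        elif mode == "higher_order" and len(U) >= 3:
            for i, j in combinations(U, 2):
                table[i, j] += v
                table[j, i] += v
    if normalization == "total":
        denom = decomposition.by_order[1:].sum()
    elif normalization == "higher_order":
        denom = decomposition.by_order[3:].sum()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    out = 100.0 * table / denom if denom > 0 else table
    sites = pd.Index(np.arange(1, ell + 1), name="site")
    return pd.DataFrame(out, index=sites, columns=sites)


def epistasis_report(space: SequenceSpace, f, P: int = 2) -> dict:
    """One-stop summary: rms epistatic coefficient of order P, rms
    mutational effect, and variance fractions by order."""
    dec = variance_components(space, f)
    return {
        "rms_epistatic_coefficient": rms_epistatic_coefficient(space, f, P),
        "rms_mutational_effect": rms_mutational_effect(space, f),
        "total_variance": dec.total_variance,
        "variance_fraction_by_order": dec.fractions().tolist(),
    }
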