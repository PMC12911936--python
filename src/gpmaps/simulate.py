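"""Seeded synthetic-data generators.

Landscapes are drawn from variance-component Gaussian priors by coloring
white noise with the order projections (f = sum_k sqrt(lambda_k) P_k z,
giving Cov(f) = sum_k lambda_k P_k exactly); observations are uniform
subsamples with additive Gaussian noise whose variance is recorded
truthfully; natural-sequence data are single multinomial draws. Every
generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .operators import OrderProjectionOperator
from .seqspace import CountData, LandscapeVector, ObservedData, SequenceSpace


def sample_vc_landscape(space: SequenceSpace, lambdas, seed: int
                        ) -> LandscapeVector:
    """Draw a landscape from the variance-component prior with the given
    per-order variances lambda_0..lambda_l.

    The expected variance mass at order k is lambda_k * m_k / alpha^l with
    m_k = C(l,k)(alpha-1)^k the dimension of the order-k subspace.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.shape != (space.length + 1,):
        raise ValueError("need one lambda per interaction order 0..l")
    if np.any(lambdas < 0):
        raise ValueError("lambdas must be nonnegative")
    rng = np.random.default_rng(seed)
    f = np.zeros(space.n_genotypes)
    for k, lam in enumerate(lambdas):
        if lam > 0:
            z = rng.standard_normal(space.n_genotypes)
            f += np.sqrt(lam) * OrderProjectionOperator(space, k).matvec(z)
    return LandscapeVector(space, f)


def lambdas_from_variance_fractions(space: SequenceSpace, fractions,
                                    total_variance: float = 1.0) -> np.ndarray:
    """Convert target per-order variance fractions into prior lambdas.

    Order k contributes expected variance lambda_k * m_k / alpha^l with
    m_k = C(l,k)(alpha-1)^k, so lambda_k = fraction_k * total * alpha^l / m_k.
    """
    from math import comb

    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (space.length + 1,) or np.any(fractions < 0):
        raise ValueError("need one nonnegative fraction per order 0..l")
    if fractions[1:].sum() <= 0:
        raise ValueError("at least one order k >= 1 must carry variance")
    fractions = fractions / fractions[1:].sum()
    m = np.array([comb(space.length, k) * (space.alpha - 1) ** k
                  for k in range(space.length + 1)], dtype=float)
    lam = fractions * total_variance * space.n_genotypes / m
    lam[0] = 0.0
    return lam


def make_observations(f: LandscapeVector, fraction_observed: float,
                      noise_var: float, seed: int, test_fraction: float = 0.0
                      ) -> tuple[ObservedData, ObservedData | None]:
    """Subsample genotypes uniformly and add Gaussian measurement noise.

    Returns ``(train, test)``; the test set (disjoint from train) holds
    ``test_fraction`` of the *sampled* genotypes and is None if the
    fraction is zero. ``noise_var`` is recorded as the known sigma_x^2.
    """
    if not 0 < fraction_observed <= 1:
        raise ValueError("fraction_observed must lie in (0, 1]")
    if noise_var < 0:
        raise ValueError("noise_var must be nonnegative")
    space = f.space
    rng = np.random.default_rng(seed)
    n_obs = max(1, int(round(fraction_observed * space.n_genotypes)))
    chosen = rng.choice(space.n_genotypes, size=n_obs, replace=False)
    y = f.values[chosen] + (
        np.sqrt(noise_var) * rng.standard_normal(n_obs) if noise_var > 0 else 0.0
    )
    var = np.full(n_obs, float(noise_var))
    n_test = int(round(test_fraction * n_obs))
    if n_test == 0:
        return ObservedData(space, chosen, y, var), None
    if n_test >= n_obs:
        raise ValueError("test_fraction leaves an empty training set")
    train = ObservedData(space, chosen[n_test:], y[n_test:], var[n_test:])
    test = ObservedData(space, chosen[:n_test], y[:n_test], var[:n_test])
    return train, test


def sample_counts(space: SequenceSpace, pi, n_total: int, seed: int
                  ) -> CountData:
    """One multinomial draw of n_total observations from probabilities pi."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (space.n_genotypes,) or np.any(pi < 0):
        raise ValueError("pi must be a nonnegative vector over the space")
    if not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi must sum to 1")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_total, pi / pi.sum())
    return CountData(space, counts)


# Default measurement variance for MAVE-scale simulations: pooled replicate
# variance typical of log-fluorescence sort-seq readouts.
DEFAULT_MAVE_NOISE_VAR = 0.058


def canonical_fixtures() -> dict[str, LandscapeVector]:
    """Small named landscapes used throughout the documentation and tests.

    - additive_2x2: f = (0, 1, 1, 2) on binary l=2 (no epistasis).
    - epistatic_2x2: f = (0, 1, 1, 3) (a single epistatic coefficient of 1).
    - two_peak_l3: binary l=3 with maxima at 000 and 111 and a depressed
      middle shell — the minimal rugged landscape for visualization tests.
    - delta_l2: indicator of the genotype 11.
    """
    b2 = SequenceSpace("01", 2)
    b3 = SequenceSpace("01", 3)
    two_peak = np.full(8, -1.0)
    two_peak[0] = 2.0   # 000
    two_peak[7] = 2.0   # 111
    return {
        "additive_2x2": LandscapeVector(b2, np.array([0.0, 1.0, 1.0, 2.0])),
        "epistatic_2x2": LandscapeVector(b2, np.array([0.0, 1.0, 1.0, 3.0])),
        "two_peak_l3": LandscapeVector(b3, two_peak),
        "delta_l2": LandscapeVector(b2, np.array([0.0, 0.0, 0.0, 1.0])),
    }
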