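"""Thermodynamic model of translation initiation at the Shine-Dalgarno site.

Models expected log(GFP) of a variable ribosome-binding-site sequence as
the log of background fluorescence plus the total Boltzmann occupancy of
the 16S rRNA (anti-SD) footprint summed over all binding registers:

    mu(x) = log( beta0 + sum_p exp(-E_p(x) / RT) ),
    E_p(x) = theta0 + sum_{i=1..8} ddG[i, symbol at footprint position i],

under the low-occupancy approximation (bound fraction << 1). The energy
matrix ddG (8 footprint positions x alpha alleles, kcal/mol) is
gauge-fixed by a per-position sum-to-zero constraint, so the free
parameters are 8*(alpha-1) energy contrasts plus theta0 (composite offset
absorbing the mean binding energy and the bound-state translation rate),
beta0 (background fluorescence, linear units) and an extra noise variance
sigma2 on the log scale: 27 parameters for RNA. The variable sequence is
extended by fixed flanks (defaults CCG upstream, UGAG downstream) so
registers overlapping the constant context are modeled too.

Measurements y are Gaussian on the log scale with known per-sequence
variance plus sigma2; fitting is maximum likelihood by Adam with analytic
gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .seqspace import LandscapeVector, ObservedData, SequenceSpace

#: gas constant (kcal/mol/K) times 310 K
RT_310 = 1.9872e-3 * 310.0
FOOTPRINT = 8
DEFAULT_FLANK_UP = "CCG"
DEFAULT_FLANK_DOWN = "UGAG"


def _sum_zero_basis(alpha: int) -> np.ndarray:
    """Orthonormal basis (alpha x alpha-1) of the sum-to-zero subspace."""
    q, _ = np.linalg.qr(np.eye(alpha) - 1.0 / alpha)
    # keep the alpha-1 columns spanning the centered subspace
    return q[:, :alpha - 1]


@dataclass
class ThermoParams:
    """Parameters of the register-summed occupancy model."""

    alphabet: str = "ACGU"
    ddG: np.ndarray = None                  # (FOOTPRINT, alpha), rows sum to 0
    theta0: float = 0.0                     # kcal/mol, composite offset
    beta0: float = 0.1                      # background fluorescence, >= 0
    sigma2: float = 0.0                     # extra log-scale noise variance
    rt: float = RT_310
    flank_up: str = DEFAULT_FLANK_UP
    flank_down: str = DEFAULT_FLANK_DOWN
    registers: tuple | None = None          # window start offsets; None = all

    def __post_init__(self):
        alpha = len(self.alphabet)
        if self.ddG is None:
            self.ddG = np.zeros((FOOTPRINT, alpha))
        self.ddG = np.asarray(self.ddG, dtype=float)
        if self.ddG.shape != (FOOTPRINT, alpha):
            raise ValueError(f"ddG must be ({FOOTPRINT}, {alpha})")
        if np.max(np.abs(self.ddG.sum(axis=1))) > 1e-8:
            raise ValueError("each ddG row must sum to zero")
        if self.beta0 < 0 or self.sigma2 < 0 or self.rt <= 0:
            raise ValueError("beta0, sigma2 must be >= 0 and RT > 0")

    @property
    def n_free_parameters(self) -> int:
        """FOOTPRINT*(alpha-1) energy contrasts + theta0 + beta0 + sigma2."""
        return FOOTPRINT * (len(self.alphabet) - 1) + 3

    def ddG_relative_to_strongest(self) -> np.ndarray:
        """Energy matrix shifted so the strongest binder scores 0 overall:
        per column-minimum subtraction for export/logo construction."""
        return self.ddG - self.ddG.min(axis=1, keepdims=True)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "alphabet": self.alphabet,
                    "ddG": self.ddG.tolist(),
                    "theta0": self.theta0,
                    "beta0": self.beta0,
                    "sigma2": self.sigma2,
                    "rt": self.rt,
                    "flank_up": self.flank_up,
                    "flank_down": self.flank_down,
                    "registers": list(self.registers) if self.registers else None,
                },
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        d["ddG"] = np.array(d["ddG"])
        if d["registers"] is not None:
            d["registers"] = tuple(d["registers"])
        return cls(**d)


def _encode(params: ThermoParams, sequences) -> np.ndarray:
    """Window symbol codes: (n_seqs, n_registers, FOOTPRINT) int array."""
    code = {s: i for i, s in enumerate(params.alphabet)}
    ext = [params.flank_up + s + params.flank_down for s in sequences]
    length = len(ext[0])
    if any(len(e) != length for e in ext):
        raise ValueError("sequences must share a length")
    if length < FOOTPRINT:
        raise ValueError("extended sequence shorter than the footprint")
    registers = params.registers or tuple(range(length - FOOTPRINT + 1))
    codes = np.array([[code[ch] for ch in e] for e in ext], dtype=np.int64)
    windows = np.stack(
        [codes[:, p:p + FOOTPRINT] for p in registers], axis=1
    )
    return windows


def register_energies(params: ThermoParams, sequence: str) -> np.ndarray:
    """Binding energy theta0 + additive ddG contributions, one per register."""
    w = _encode(params, [sequence])[0]  # (n_reg, FOOTPRINT)
    return params.theta0 + params.ddG[np.arange(FOOTPRINT), w].sum(axis=1)


def _mu_from_windows(params: ThermoParams, windows: np.ndarray) -> np.ndarray:
    energies = params.theta0 + params.ddG[
        np.arange(FOOTPRINT)[None, None, :], windows
    ].sum(axis=2)  # (n, n_reg)
    log_occ = -energies / params.rt
    from scipy.special import logsumexp

    log_sum = logsumexp(log_occ, axis=1)
    if params.beta0 == 0:
        return log_sum
    return np.logaddexp(np.log(params.beta0), log_sum)


def predict_mu(params: ThermoParams, sequence: str) -> float:
    """Expected log(GFP): log(beta0 + sum_p exp(-E_p/RT)), natural log."""
    return float(_mu_from_windows(params, _encode(params, [sequence]))[0])


def predict_mu_batch(params: ThermoParams, sequences) -> np.ndarray:
    return _mu_from_windows(params, _encode(params, sequences))


def predict_full_landscape(params: ThermoParams, space: SequenceSpace
                           ) -> LandscapeVector:
    """mu for every genotype of the space (input to the visualization)."""
    seqs = space.all_sequences()
    return LandscapeVector(space, predict_mu_batch(params, seqs))


# ---------------------------------------------------------------------- #
# Likelihood and fitting

def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    return y + np.log(-np.expm1(-y)) if y > 0 else -np.inf


def thermo_negloglik(params: ThermoParams, data: ObservedData,
                     sequences=None) -> float:
    """Gaussian negative log-likelihood of log-scale measurements:
    sum_x [ (y_x - mu_x)^2 / (2 v_x) + 0.5 log(2 pi v_x) ],
    v_x = known noise variance + sigma2."""
    seqs = sequences if sequences is not None else data.sequences
    mu = predict_mu_batch(params, seqs)
    v = data.noise_var + params.sigma2
    if np.any(v <= 0):
        raise ValueError("total variance must be positive for every point")
    return float(
        np.sum((data.y - mu) ** 2 / (2 * v) + 0.5 * np.log(2 * np.pi * v))
    )


class _ThermoObjective:
    """Vectorized NLL with analytic gradients in the free parameterization:
    z (FOOTPRINT x (alpha-1)) energy contrasts through a sum-zero basis,
    theta0 raw, beta0 = softplus(b), sigma2 = softplus(s) (floored)."""

    SIGMA2_FLOOR = 1e-8

    def __init__(self, data: ObservedData, template: ThermoParams,
                 sequences=None):
        self.data = data
        self.template = template
        self.alpha = len(template.alphabet)
        self.basis = _sum_zero_basis(self.alpha)  # (alpha, alpha-1)
        seqs = sequences if sequences is not None else data.sequences
        self.windows = _encode(template, seqs)  # (n, n_reg, 8)
        self.n, self.n_reg, _ = self.windows.shape
        # one-hot window encoding for gradient accumulation: counts of
        # (footprint position, allele) per (sequence, register)
        self.onehot = np.zeros((self.n, self.n_reg, FOOTPRINT, self.alpha))
        fp = np.arange(FOOTPRINT)
        for r in range(self.n_reg):
            self.onehot[np.arange(self.n)[:, None], r, fp[None, :],
                        self.windows[:, r, :]] = 1.0

    def unpack(self, theta):
        k = FOOTPRINT * (self.alpha - 1)
        z = theta[:k].reshape(FOOTPRINT, self.alpha - 1)
        ddG = z @ self.basis.T
        theta0, b_raw, s_raw = theta[k], theta[k + 1], theta[k + 2]
        beta0 = _softplus(b_raw)
        sigma2 = _softplus(s_raw) + self.SIGMA2_FLOOR
        return ddG, theta0, beta0, sigma2, b_raw, s_raw

    def params(self, theta) -> ThermoParams:
        ddG, theta0, beta0, sigma2, _, _ = self.unpack(theta)
        return ThermoParams(
            alphabet=self.template.alphabet, ddG=ddG, theta0=float(theta0),
            beta0=float(beta0), sigma2=float(sigma2), rt=self.template.rt,
            flank_up=self.template.flank_up,
            flank_down=self.template.flank_down,
            registers=self.template.registers,
        )

    def value_and_grad(self, theta):
        ddG, theta0, beta0, sigma2, b_raw, s_raw = self.unpack(theta)
        rt = self.template.rt
        # energies and occupancies
        energies = theta0 + np.einsum(
            "nrfa,fa->nr", self.onehot, ddG
        )  # (n, n_reg)
        log_occ = -energies / rt
        from scipy.special import logsumexp

        log_sum = logsumexp(log_occ, axis=1)
        mu = np.logaddexp(np.log(beta0), log_sum)
        v = self.data.noise_var + sigma2
        resid = self.data.y - mu
        value = float(np.sum(resid**2 / (2 * v) + 0.5 * np.log(2 * np.pi * v)))

        dl_dmu = -resid / v                        # (n,)
        # d mu / d E_pr = -exp(log_occ_pr - mu) / rt ; d mu/d beta0 = e^-mu
        occ_w = np.exp(log_occ - mu[:, None])      # (n, n_reg)
        dmu_dE = -occ_w / rt
        g_E = dl_dmu[:, None] * dmu_dE             # (n, n_reg)
        g_theta0 = float(g_E.sum())
        g_ddG = np.einsum("nr,nrfa->fa", g_E, self.onehot)
        g_z = g_ddG @ self.basis
        dmu_db0 = np.exp(-mu)
        g_b = float(np.sum(dl_dmu * dmu_db0)) / (1.0 + np.exp(-b_raw))
        dl_dv = np.sum(-(resid**2) / (2 * v**2) + 0.5 / v)
        g_s = float(dl_dv) / (1.0 + np.exp(-s_raw))
        grad = np.concatenate([g_z.ravel(), [g_theta0, g_b, g_s]])
        return value, grad


@dataclass
class ThermoFitResult:
    params: ThermoParams
    loss_trace: np.ndarray
    grad_norm: float
    n_iter: int

    @property
    def converged(self) -> bool:
        return np.isfinite(self.loss_trace[-1])


def _adam(obj, theta, learning_rate, n_iter, grad_tol, max_total_iter):
    """Adam with convergence monitoring: runs in ``n_iter`` blocks until the
    gradient norm drops below ``grad_tol`` or ``max_total_iter`` is hit."""
    theta = theta.copy()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    b1, b2, eps = 0.9, 0.999, 1e-8
    trace = []
    t = 0
    while True:
        for _ in range(n_iter):
            t += 1
            value, grad = obj.value_and_grad(theta)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at iteration {t}; last parameters: "
                    f"theta0={theta[-3]:.3g}"
                )
            trace.append(value)
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad**2
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            theta = theta - learning_rate * mhat / (np.sqrt(vhat) + eps)
        value, grad = obj.value_and_grad(theta)
        if np.linalg.norm(grad) <= grad_tol or t >= max_total_iter:
            break
    return theta, value, np.asarray(trace), float(np.linalg.norm(grad)), t


def _shifted_theta(obj, params, shift):
    """Re-encode a solution with its energy matrix shifted by ``shift``
    footprint rows (vacated rows zero)."""
    dd = np.zeros_like(params.ddG)
    if shift > 0:
        dd[shift:] = params.ddG[:-shift]
    elif shift < 0:
        dd[:shift] = params.ddG[-shift:]
    dd -= dd.mean(axis=1, keepdims=True)
    return np.concatenate([
        (dd @ obj.basis).ravel(),
        [params.theta0,
         _softplus_inv(max(params.beta0, 1e-3)),
         _softplus_inv(max(params.sigma2 - _ThermoObjective.SIGMA2_FLOOR,
                           1e-3))],
    ])


def fit_thermo(data: ObservedData, sequences=None,
               template: ThermoParams | None = None, seed: int = 0,
               learning_rate: float = 0.02, n_iter: int = 1500,
               grad_tol: float = 1.0, max_total_iter: int = 12000,
               phase_shifts=(-1, 1)) -> ThermoFitResult:
    """Maximum-likelihood fit by Adam (defaults: lr 0.02, 1500 iterations).

    Convergence is monitored: if after ``n_iter`` iterations the gradient
    norm still exceeds ``grad_tol`` (scaled by the number of observations),
    optimization continues in further ``n_iter`` blocks up to
    ``max_total_iter``.

    Because the likelihood sums occupancy over sliding registers it has a
    near-symmetry under shifting the whole energy matrix by one footprint
    position, which creates phase-shifted local optima (the analogue of
    column-shift moves in motif discovery). After the initial fit,
    re-optimizations started from the solution shifted by each offset in
    ``phase_shifts`` are run and the parameters with the lowest negative
    log-likelihood are returned.

    ``sequences`` overrides the genotype-index-derived sequences (needed
    when the data's space alphabet differs from the model's). Deterministic
    given the seed (which sets the small random initialization).
    """
    import warnings

    if len(data) < 50:
        warnings.warn(f"only {len(data)} training sequences; fits below ~50 "
                      "are poorly constrained")
    template = template or ThermoParams()
    obj = _ThermoObjective(data, template, sequences)
    rng = np.random.default_rng(seed)
    n_par = FOOTPRINT * (obj.alpha - 1) + 3
    theta0 = 0.01 * rng.standard_normal(n_par)
    theta0[-3] = float(np.mean(data.y))  # theta0 init: typical scale
    theta0[-2] = _softplus_inv(0.1)
    theta0[-1] = _softplus_inv(0.05)

    tol = grad_tol * max(1.0, len(data) / 1000.0)
    best = _adam(obj, theta0, learning_rate, n_iter, tol, max_total_iter)
    for shift in phase_shifts:
        start = _shifted_theta(obj, obj.params(best[0]), shift)
        cand = _adam(obj, start, learning_rate, n_iter, tol, max_total_iter)
        if cand[1] < best[1]:
            best = cand
    theta, _, trace, grad_norm, t = best
    return ThermoFitResult(obj.params(theta), trace, grad_norm, t)


def simulate_thermo_data(space: SequenceSpace, true_params: ThermoParams,
                         n: int, noise_var: float, seed: int
                         ) -> tuple[ObservedData, list]:
    """Draw n distinct sequences uniformly, compute mu under the model and
    add Gaussian log-scale noise; returns the data and the sequence list."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(space.n_genotypes, size=min(n, space.n_genotypes),
                     replace=False)
    seqs = [space.index_to_seq(i) for i in idx]
    mu = predict_mu_batch(true_params, seqs)
    y = mu + np.sqrt(noise_var) * rng.standard_normal(len(mu))
    data = ObservedData(space, idx, y, np.full(len(mu), noise_var))
    return data, seqs
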