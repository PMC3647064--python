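"""Amino-acid substitution models for likelihood evaluation and simulation.

A model couples a symmetric exchangeability matrix with equilibrium
frequencies, a discrete-gamma rate-heterogeneity shape, and a proportion
of invariant sites.  The LG matrix of Le & Gascuel (2008) is bundled as
published constants; other matrices (WAG, user-estimated) can be loaded
from PAML-format files.

The instantaneous rate matrix is built as ``q_ij = s_ij * pi_j`` with the
diagonal set so rows sum to zero, scaled so the expected substitution rate
at equilibrium is one: ``sum_i pi_i * (-q_ii) = 1``.  Branch lengths are
then in expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .types import AMINO_ACIDS

__all__ = [
    "SubstitutionModel",
    "build_rate_matrix",
    "discrete_gamma_rates",
    "lg_model",
    "read_paml_matrix",
    "LG_EXCHANGEABILITIES",
    "LG_FREQUENCIES",
]

#: Le & Gascuel (2008) exchangeabilities, lower triangle in column-major
#: order over the residue order ARNDCQEGHILKMFPSTWYV, i.e. the pairs
#: (R,A), (N,A), ..., (V,A), (N,R), (D,R), ..., (V,Y).
LG_EXCHANGEABILITIES = np.array([
    0.425093, 0.276818, 0.395144, 2.489084, 0.969894,
    1.038545, 2.06604, 0.358858, 0.14983, 0.395337,
    0.536518, 1.124035, 0.253701, 1.177651, 4.727182,
    2.139501, 0.180717, 0.218959, 2.54787, 0.751878,
    0.123954, 0.534551, 2.807908, 0.36397, 0.390192,
    2.426601, 0.126991, 0.301848, 6.326067, 0.484133,
    0.052722, 0.332533, 0.858151, 0.578987, 0.593607,
    0.31444, 0.170887, 5.076149, 0.528768, 1.695752,
    0.541712, 1.437645, 4.509238, 0.191503, 0.068427,
    2.145078, 0.371004, 0.089525, 0.161787, 4.008358,
    2.000679, 0.045376, 0.612025, 0.083688, 0.062556,
    0.523386, 5.24387, 0.844926, 0.927114, 0.01069,
    0.015076, 0.282959, 0.025548, 0.017416, 0.394456,
    1.240275, 0.42586, 0.02989, 0.135107, 0.037967,
    0.084808, 0.003499, 0.569265, 0.640543, 0.320627,
    0.594007, 0.013266, 0.89368, 1.105251, 0.075382,
    2.784478, 1.14348, 0.670128, 1.165532, 1.959291,
    4.128591, 0.267959, 4.813505, 0.072854, 0.582457,
    3.234294, 1.672569, 0.035855, 0.624294, 1.223828,
    1.080136, 0.236199, 0.257336, 0.210332, 0.348847,
    0.423881, 0.044265, 0.069673, 1.807177, 0.173735,
    0.018811, 0.419409, 0.611973, 0.604545, 0.077852,
    0.120037, 0.245034, 0.311484, 0.008705, 0.044261,
    0.296636, 0.139538, 0.089586, 0.196961, 1.73999,
    0.129836, 0.268491, 0.054679, 0.076701, 0.108882,
    0.366317, 0.697264, 0.442472, 0.682139, 0.508851,
    0.990012, 0.584262, 0.597054, 5.306834, 0.119013,
    4.145067, 0.159069, 4.273607, 1.112727, 0.078281,
    0.064105, 1.033739, 0.11166, 0.232523, 10.649107,
    0.1375, 6.312358, 2.592692, 0.24906, 0.182287,
    0.302936, 0.619632, 0.299648, 1.702745, 0.656604,
    0.023918, 0.390322, 0.748683, 1.136863, 0.049906,
    0.131932, 0.185202, 1.798853, 0.099849, 0.34696,
    2.020366, 0.696175, 0.481306, 1.898718, 0.094464,
    0.361819, 0.165001, 2.457121, 7.803902, 0.654683,
    1.338132, 0.571468, 0.095131, 0.089613, 0.296501,
    6.472279, 0.248862, 0.400547, 0.098369, 0.140825,
    0.245841, 2.188158, 3.151815, 0.18951, 0.249313,
])

#: LG equilibrium amino-acid frequencies, order ARNDCQEGHILKMFPSTWYV.
LG_FREQUENCIES = np.array([
    0.07906592093, 0.05594094406, 0.04197695802, 0.05305194695, 0.01293698706,
    0.04076695923, 0.07158592841, 0.05733694266, 0.02235497765, 0.06215693784,
    0.09908090092, 0.0645999354, 0.02295097705, 0.0423019577, 0.04403995596,
    0.0611969388, 0.05328694671, 0.01206598793, 0.03415496585, 0.06914693085,
])


def _unpack_lower_triangle(values: np.ndarray, n: int = 20) -> np.ndarray:
    """Symmetric matrix from column-major lower-triangle values."""
    if len(values) != n * (n - 1) // 2:
        raise ValueError(f"expected {n*(n-1)//2} exchangeabilities, got {len(values)}")
    S = np.zeros((n, n))
    k = 0
    for j in range(n):
        for i in range(j + 1, n):
            S[i, j] = S[j, i] = values[k]
            k += 1
    return S


def build_rate_matrix(exchangeabilities: np.ndarray, frequencies: np.ndarray) -> np.ndarray:
    """Normalized reversible rate matrix Q from S and pi."""
    S = np.asarray(exchangeabilities, dtype=float)
    if S.ndim == 1:
        S = _unpack_lower_triangle(S)
    pi = np.asarray(frequencies, dtype=float)
    if not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise ValueError(f"frequencies sum to {pi.sum()}, not 1")
    if np.any(S < 0) or not np.allclose(S, S.T) or np.any(np.diag(S) != 0):
        raise ValueError("exchangeabilities must be symmetric, non-negative, zero diagonal")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return Q / scale


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability discrete-gamma categories.

    The site rate is Gamma(alpha, alpha)-distributed (mean 1).  Each of the
    K equal-probability quantile bands contributes its conditional mean;
    the returned rates are renormalized to mean exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    K = n_categories
    if K == 1:
        return np.ones(1)
    # band boundaries in the rate domain
    bounds = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X; X <= x] for X ~ Gamma(alpha, alpha) is P(alpha+1, alpha*x)
    cum = np.array([gammainc(alpha + 1, alpha * e) if np.isfinite(e) else 1.0
                    for e in edges])
    rates = (cum[1:] - cum[:-1]) * K
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstitutionModel:
    """Exchangeability model with discrete-gamma rates and invariant sites.

    ``alpha`` is the gamma shape (smaller = more heterogeneity), ``pinv``
    the proportion of invariant sites in [0, 1), ``n_categories`` the
    number of discrete gamma categories.  Category rates are *not*
    rescaled by 1/(1-pinv); the mixture is
    ``pinv * [site constant] * pi_x + (1 - pinv) * mean_k L(rate_k)``.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float = 1.0
    pinv: float = 0.0
    n_categories: int = 4
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(
            self, "exchangeabilities",
            _unpack_lower_triangle(np.asarray(self.exchangeabilities))
            if np.asarray(self.exchangeabilities).ndim == 1
            else np.asarray(self.exchangeabilities, dtype=float),
        )
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, dtype=float))
        if not 0 <= self.pinv < 1:
            raise ValueError(f"pinv {self.pinv} outside [0, 1)")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self.exchangeabilities, self.frequencies)

    @cached_property
    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    @cached_property
    def _eigen(self):
        # reversible Q: symmetrize with sqrt(pi) similarity for a stable eigh
        pi = self.frequencies
        d = np.sqrt(pi)
        B = (self.rate_matrix * d[:, None]) / d[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        return w, U, d

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t), rows = ancestral state, cols = descendant."""
        if t < 0:
            raise ValueError("negative branch length")
        w, U, d = self._eigen
        expwt = np.exp(w * t)
        B = (U * expwt[None, :]) @ U.T
        P = (B / d[:, None]) * d[None, :]
        # clip tiny negatives from round-off
        np.clip(P, 0.0, None, out=P)
        return P

    def replace(self, **kwargs) -> "SubstitutionModel":
        import dataclasses
        return dataclasses.replace(self, **kwargs)


def lg_model(alpha: float = 1.0, pinv: float = 0.0, n_categories: int = 4) -> SubstitutionModel:
    """The LG amino-acid model with the requested +G/+I parameters."""
    return SubstitutionModel(
        exchangeabilities=LG_EXCHANGEABILITIES,
        frequencies=LG_FREQUENCIES,
        alpha=alpha,
        pinv=pinv,
        n_categories=n_categories,
        name="LG",
    )


def read_paml_matrix(path, alpha: float = 1.0, pinv: float = 0.0,
                     n_categories: int = 4, name: str | None = None) -> SubstitutionModel:
    """Load a PAML-format amino-acid matrix file (.dat layout).

    The file holds the 19 lower-triangle rows of exchangeabilities in
    row-major order followed by the 20 equilibrium frequencies.
    """
    numbers: list[float] = []
    with open(path) as fh:
        for line in fh:
            numbers.extend(float(x) for x in line.split())
    if len(numbers) < 210:
        raise ValueError(f"{path}: expected 190 exchangeabilities + 20 frequencies")
    tri_rowwise, freqs = numbers[:190], np.array(numbers[190:210])
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri_rowwise[k]
            k += 1
    return SubstitutionModel(
        exchangeabilities=S,
        frequencies=freqs / freqs.sum(),
        alpha=alpha,
        pinv=pinv,
        n_categories=n_categories,
        name=name or str(path),
    )
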