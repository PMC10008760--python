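"""Internal linear-algebra helpers for the multivariate hierarchies.

Correlation matrices are parameterised by unconstrained canonical partial
correlations (CPCs) via the C-vine construction: each unconstrained value z
maps to a partial correlation c = tanh(z), and the collection maps to a
Cholesky factor of a valid correlation matrix.  Under independent
c ~ 2*Beta(b, b) - 1 with b depending on the vine tree level, the implied
correlation matrix follows an LKJ distribution, which gives a simple exact
log-prior in the unconstrained space (Jacobian included).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "n_pairs",
    "cpc_to_cholesky",
    "lkj_cpc_logprior",
    "halfnormal_sd_logprior",
    "correlation_from_cholesky",
]


def n_pairs(dim: int) -> int:
    return dim * (dim - 1) // 2


def _pair_indices(dim: int):
    """Lower-triangle pair ordering (row, col), row-major: (1,0), (2,0), (2,1), ..."""
    rows, cols = np.tril_indices(dim, k=-1)
    return rows, cols


def cpc_to_cholesky(z: np.ndarray, dim: int) -> np.ndarray:
    """Map unconstrained CPCs ``z`` (..., n_pairs) to correlation Cholesky
    factors L (..., dim, dim) with ``L @ L.T`` a unit-diagonal correlation
    matrix."""
    z = np.asarray(z, dtype=float)
    c = np.tanh(z)
    batch = z.shape[:-1]
    L = np.zeros(batch + (dim, dim))
    L[..., 0, 0] = 1.0
    rows, cols = _pair_indices(dim)
    cvals = {}
    for p, (i, j) in enumerate(zip(rows, cols)):
        cvals[(i, j)] = c[..., p]
    for i in range(1, dim):
        rem = np.ones(batch)
        for j in range(i):
            L[..., i, j] = cvals[(i, j)] * rem
            rem = rem * np.sqrt(1.0 - cvals[(i, j)] ** 2)
        L[..., i, i] = rem
    return L


def lkj_cpc_logprior(z: np.ndarray, dim: int, eta: float) -> np.ndarray:
    """Log-density (up to a constant) of LKJ(eta) on correlation matrices,
    expressed in the unconstrained CPC space, Jacobian included.

    Each CPC in column j (0-based) sits at vine tree level j+1 and has
    2*Beta(b, b) - 1 density with b = eta + (dim - 2 - j)/2; together with
    the tanh Jacobian the contribution per pair is b * log(1 - c^2).
    """
    z = np.asarray(z, dtype=float)
    if dim < 2:
        return np.zeros(z.shape[:-1])
    c2 = np.tanh(z) ** 2
    _, cols = _pair_indices(dim)
    b = eta + (dim - 2 - cols) / 2.0
    return np.sum(b * np.log1p(-c2), axis=-1)


def halfnormal_sd_logprior(log_sd: np.ndarray, scale: float) -> np.ndarray:
    """Log-density (up to a constant) of a half-normal(scale) prior on a
    standard deviation sampled on the log scale; the ``+ log_sd`` term is
    the Jacobian of the exp transform."""
    sd = np.exp(log_sd)
    return np.sum(-0.5 * (sd / scale) ** 2 + log_sd, axis=-1)


def correlation_from_cholesky(L: np.ndarray) -> np.ndarray:
    return L @ np.swapaxes(L, -1, -2)
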