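"""Numerics for generalized coordinates of motion.

A variable in generalized coordinates is carried together with its first
``order`` temporal derivatives: an array of shape ``(order + 1, d)`` whose
row ``k`` holds the k-th derivative of a d-dimensional signal (units: base
units x s^-k).  Three primitives live here:

* the shift (derivative) operator ``D`` that maps row k+1 into row k,
* the covariance among derivative orders of a smooth random process with a
  Gaussian autocorrelation function (used to build precisions over
  generalized prediction errors), and
* Taylor (local polynomial) embedding of a sampled time series into
  generalized coordinates.

Everything here is plain linear algebra consumed by the inference engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = [
    "GeneralizedVector",
    "SmoothnessSpec",
    "shift_operator",
    "shift",
    "derivative_correlations",
    "smoothness_precision",
    "embed_sequence",
]


@dataclass
class GeneralizedVector:
    """A d-dimensional variable and its first ``order`` temporal derivatives.

    ``values[k]`` is the k-th derivative (a length-d row).
    """

    order: int
    values: np.ndarray  # (order + 1, d)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.order < 0:
            raise ValueError("embedding order must be non-negative")
        if self.values.shape[0] != self.order + 1:
            raise ValueError(
                f"expected {self.order + 1} derivative rows, "
                f"got {self.values.shape[0]}"
            )

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        """Order-major flattening (row k block = k-th derivative)."""
        return self.values.ravel()

    @classmethod
    def from_flat(cls, flat: np.ndarray, order: int, dim: int) -> "GeneralizedVector":
        return cls(order, np.asarray(flat, dtype=float).reshape(order + 1, dim))

    def shifted(self) -> "GeneralizedVector":
        return GeneralizedVector(self.order, shift(self.values))


@dataclass(frozen=True)
class SmoothnessSpec:
    """Roughness of the random fluctuations assumed by the filter.

    ``gamma`` (s^-2) parameterizes a Gaussian autocorrelation
    rho(h) = exp(-gamma h^2 / 2); larger gamma means rougher fluctuations
    and larger variance of higher temporal derivatives.
    """

    gamma: float = 4.0
    order: int = 6

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("roughness gamma must be positive")
        if self.order < 0:
            raise ValueError("embedding order must be non-negative")


def shift_operator(order: int, dim: int = 1) -> np.ndarray:
    """Block-superdiagonal derivative operator on flattened generalized vectors.

    Acting on the order-major flattening of a ``(order+1, d)`` generalized
    vector, ``D`` maps derivative row k+1 into row k and zeroes the last row.
    ``D`` is nilpotent: ``D**(order+1) == 0``.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    if dim < 1:
        raise ValueError("dim must be at least 1")
    up = np.eye(order + 1, k=1)
    return np.kron(up, np.eye(dim))


def shift(values: np.ndarray) -> np.ndarray:
    """Apply the shift operator directly to a (order+1, d) array of rows."""
    out = np.zeros_like(values)
    out[:-1] = values[1:]
    return out


def _rho_derivatives_at_zero(gamma: float, max_order: int) -> np.ndarray:
    """Derivatives rho^(m)(0) of rho(h) = exp(-gamma h^2 / 2), m = 0..max_order.

    Odd derivatives vanish; rho^(2r)(0) = (-1)^r (2r-1)!! gamma^r.
    """
    d = np.zeros(max_order + 1)
    for r in range(max_order // 2 + 1):
        m = 2 * r
        if m > max_order:
            break
        double_fact = factorial(2 * r) / (2**r * factorial(r))  # (2r-1)!!
        d[m] = (-1) ** r * double_fact * gamma**r
    return d


def derivative_correlations(spec: SmoothnessSpec) -> np.ndarray:
    """Covariance among derivative orders of a unit-variance smooth process.

    For a stationary process with autocorrelation rho(h),
    cov(x^(j), x^(k)) = (-1)^j rho^(j+k)(0); terms with odd j+k vanish,
    so a process is uncorrelated with its own first derivative.  The result
    is symmetric positive definite for every gamma > 0.
    """
    n = spec.order
    rho = _rho_derivatives_at_zero(spec.gamma, 2 * n)
    S = np.empty((n + 1, n + 1))
    for j in range(n + 1):
        for k in range(n + 1):
            S[j, k] = (-1) ** j * rho[j + k]
    return S


def smoothness_precision(spec: SmoothnessSpec) -> np.ndarray:
    """Inverse of :func:`derivative_correlations` (precision over orders)."""
    S = derivative_correlations(spec)
    # solve via Cholesky: S is SPD but ill-conditioned at high order
    L = np.linalg.cholesky(S)
    inv_l = np.linalg.inv(L)
    P = inv_l.T @ inv_l
    return 0.5 * (P + P.T)


def _taylor_matrix(offsets: np.ndarray, order: int, dt: float) -> np.ndarray:
    """E[i, k] = (offsets[i] * dt)^k / k! — Taylor design matrix."""
    t = offsets * dt
    return np.column_stack([t**k / factorial(k) for k in range(order + 1)])


def embed_sequence(samples: np.ndarray, order: int, dt: float) -> np.ndarray:
    """Embed a sampled signal into generalized coordinates at every sample.

    A local polynomial of degree ``order`` is fit through a symmetric window
    of ``order + 1`` points around each sample (asymmetric at the sequence
    boundaries); its Taylor coefficients are the derivative estimates.  The
    construction is exact for polynomial signals of degree <= order.

    Parameters
    ----------
    samples : (T,) or (T, d) array
    order : embedding order n
    dt : sample interval in seconds (> 0)

    Returns
    -------
    (T, order + 1, d) array; ``out[t, k]`` estimates the k-th derivative.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    T = samples.shape[0]
    if order < 0:
        raise ValueError("order must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    w = order + 1
    if T < w:
        raise ValueError(f"need at least {w} samples for order {order}, got {T}")

    half = order // 2
    out = np.empty((T, w, samples.shape[1]))
    inv_cache: dict[int, np.ndarray] = {}
    for t in range(T):
        start = min(max(t - half, 0), T - w)
        offsets = np.arange(start - t, start - t + w)
        key = offsets[0]
        if key not in inv_cache:
            inv_cache[key] = np.linalg.inv(_taylor_matrix(offsets, order, dt))
        out[t] = inv_cache[key] @ samples[start : start + w]
    return out
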