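"""Log-raised-cosine temporal basis for GLM response kernels.

Each task-variable kernel is a weighted sum of M = 9 basis functions
evaluated on a causal lag grid of 50 ms bins spanning 4 s: seven
raised cosines on a log-time axis, plus two decaying exponentials in
the first lag bins to capture impulse-like onset responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BasisSet", "build_basis"]


@dataclass(frozen=True)
class BasisSet:
    """Evaluated temporal basis.

    Attributes
    ----------
    dt : float
        Bin width in seconds.
    support : float
        Kernel length in seconds; ``n_lags = support / dt`` lag bins.
    a : float
        Log-stretch of the raised cosines; controls breadth of support.
    centers : ndarray, shape (n_cosine,)
        The ``b_j`` parameters (peak positions on the ``a * log(tau)`` axis).
    exp_taus : tuple of float
        Decay constants (s) of the exponential onset columns.
    B : ndarray, shape (n_lags, n_basis)
        Basis evaluated at lag-bin centers; each column peaks at 1.
    """

    dt: float
    support: float
    a: float
    centers: np.ndarray
    exp_taus: tuple
    B: np.ndarray = field(repr=False)

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]

    @property
    def n_lags(self) -> int:
        return self.B.shape[0]

    @property
    def lags(self) -> np.ndarray:
        """Lag-bin centers in seconds."""
        return (np.arange(self.n_lags) + 0.5) * self.dt

    def kernel(self, weights: np.ndarray) -> np.ndarray:
        """Reconstruct a temporal kernel k(tau) = sum_j w_j phi_j(tau)."""
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (self.n_basis,):
            raise ValueError(
                f"expected {self.n_basis} weights, got shape {weights.shape}"
            )
        return self.B @ weights


def _raised_cosine(log_tau: np.ndarray, a: float, b: float) -> np.ndarray:
    arg = a * log_tau - b
    out = 0.5 * np.cos(arg) + 0.5
    out[np.abs(arg) > np.pi] = 0.0
    return out


def build_basis(
    dt: float = 0.05,
    support: float = 4.0,
    n_cosine: int = 7,
    peak_range: tuple = (0.025, 2.0),
    exp_taus: tuple = (0.025, 0.05),
) -> BasisSet:
    """Construct the default 9-function kernel basis.

    The ``n_cosine`` raised cosines have peak lags log-linearly spaced over
    ``peak_range``; the stretch ``a`` is chosen so adjacent cosines cross at
    amplitude 0.5 (peak spacing on the ``a log tau`` axis equals pi/2).  Two
    decaying exponentials with time constants ``exp_taus`` peak in the first
    two lag bins.

    Returns a :class:`BasisSet` with ``n_basis = n_cosine + len(exp_taus)``.
    """
    if dt <= 0 or support <= 0:
        raise ValueError("dt and support must be positive")
    n_lags = int(round(support / dt))
    tau = (np.arange(n_lags) + 0.5) * dt
    log_tau = np.log(tau)

    peaks = np.exp(np.linspace(np.log(peak_range[0]), np.log(peak_range[1]), n_cosine))
    delta = (np.log(peak_range[1]) - np.log(peak_range[0])) / (n_cosine - 1)
    # adjacent peaks separated by a*delta on the log axis; crossing at 0.5
    # requires a*delta = pi/2
    a = (np.pi / 2.0) / delta
    centers = a * np.log(peaks)

    cols = []
    for j, tau_d in enumerate(exp_taus):
        col = np.zeros(n_lags)
        # exponential j starts in lag bin j and decays with constant tau_d
        idx = np.arange(j, n_lags)
        col[idx] = np.exp(-(tau[idx] - tau[j]) / tau_d)
        cols.append(col)
    for b in centers:
        cols.append(_raised_cosine(log_tau, a, b))

    B = np.column_stack(cols)
    peak_vals = B.max(axis=0)
    if np.any(peak_vals <= 0):
        raise ValueError("degenerate basis column (all zero)")
    B = B / peak_vals

    return BasisSet(dt=dt, support=support, a=a, centers=centers,
                    exp_taus=tuple(exp_taus), B=B)
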