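"""Legendre polynomial basis functions over a standardized time domain.

Random-regression models for longitudinal traits express every time-varied
term (population mean, additive genetic trajectory, permanent environmental
trajectory, SNP effect curve) as a linear combination of *normalized*
Legendre polynomials evaluated on time standardized to [-1, 1]:

    phi_k(x) = sqrt((2k + 1) / 2) * P_k(x),

where ``P_k`` is the ordinary Legendre polynomial.  The normalization is the
Kirkpatrick convention standard in animal-breeding random-regression models;
it makes the basis orthonormal under the L2 inner product on [-1, 1].
"Order" throughout this package means the highest polynomial degree, so an
order-``q`` term carries ``q + 1`` regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["TimeDomain", "standardize_time", "legendre_matrix"]


@dataclass(frozen=True)
class TimeDomain:
    """Recording-time domain [t_min, t_max] with an integer accumulation grid.

    The affine map x(t) = 2 (t - t_min) / (t_max - t_min) - 1 sends
    t_min -> -1 and t_max -> +1.  ``grid`` is the ordered integer time grid
    t_min..t_max used for accumulation sums (accumulated EBVs, cumulative
    SNP effects).
    """

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(
                f"invalid time domain: t_min={self.t_min!r} must be < t_max={self.t_max!r}"
            )

    @property
    def grid(self) -> np.ndarray:
        """Integer time points t_min..t_max (inclusive), strictly increasing."""
        return np.arange(int(np.ceil(self.t_min)), int(np.floor(self.t_max)) + 1)

    @classmethod
    def from_times(cls, times) -> "TimeDomain":
        t = np.asarray(times, dtype=float)
        return cls(float(t.min()), float(t.max()))


def standardize_time(times, domain: TimeDomain) -> np.ndarray:
    """Affinely map recording times into [-1, 1].

    Raises a ``ValueError`` naming the offending record when a time falls
    outside the domain.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    bad = np.flatnonzero((t < domain.t_min) | (t > domain.t_max))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"time {t[i]} (record index {i}) outside domain "
            f"[{domain.t_min}, {domain.t_max}]"
        )
    return 2.0 * (t - domain.t_min) / (domain.t_max - domain.t_min) - 1.0


def legendre_matrix(order: int, times, domain: TimeDomain) -> np.ndarray:
    """Normalized-Legendre basis matrix, one row per time point.

    Entry (i, k) is phi_k(x(t_i)) for k = 0..order, with
    phi_k(x) = sqrt((2k+1)/2) P_k(x).

    Parameters
    ----------
    order : int
        Highest polynomial degree (>= 0); the matrix has ``order + 1`` columns.
    times : array-like
        Recording times, all within ``domain``.
    domain : TimeDomain
        Standardization domain.
    """
    if order < 0:
        raise ValueError(f"basis order must be >= 0, got {order}")
    x = standardize_time(times, domain)
    # P_k(x) columns via the identity matrix of coefficient vectors
    vander = npleg.legvander(x, order)
    norms = np.sqrt((2.0 * np.arange(order + 1) + 1.0) / 2.0)
    return vander * norms
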