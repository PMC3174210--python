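"""GM(2,1) grey dynamic model fitted by least squares.

The model is fitted to a non-negative series ``x0`` of length n >= 4.
Writing ``x1`` for the running cumulative sums (1-AGO) and
``z1(k) = (x1(k) + x1(k-1)) / 2`` for the background values, the discrete
form of the second-order, one-variable grey equation is

    x0(k) - x0(k-1) + a1 * x0(k) + a2 * z1(k) = b,   k = 2..n

which gives the overdetermined linear system ``B @ (a1, a2, b) = Y`` with
row k of B equal to ``[-x0(k), -z1(k), 1]`` and ``Y(k) = x0(k) - x0(k-1)``.
The minimum-norm least-squares solution supplies the three coefficients;
their absolute values are the grey features used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_SERIES_LENGTH = 4  # n - 1 >= 3 equations for 3 unknowns

# singular values below max_sv * RANK_RTOL are treated as zero
_RANK_RTOL = 1e-10


class SeriesTooShortError(ValueError):
    """The series has fewer points than the GM(2,1) system requires."""


def _as_values(series) -> np.ndarray:
    """Accept a NumericSeries or any 1-D array-like of floats."""
    values = getattr(series, "values", series)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {arr.shape}")
    return arr


def ago(series) -> np.ndarray:
    """First-order accumulative generation operation (running cumsum).

    The k-th output value is the sum of the first k input values; for a
    strictly positive input the result is strictly increasing.
    """
    arr = _as_values(series)
    if arr.size == 0:
        raise ValueError("cannot accumulate an empty series")
    return np.cumsum(arr)


def inverse_ago(accumulated) -> np.ndarray:
    """First differences with retained head; exact inverse of :func:`ago`."""
    arr = _as_values(accumulated)
    if arr.size == 0:
        raise ValueError("cannot difference an empty series")
    return np.diff(arr, prepend=0.0)


@dataclass(frozen=True)
class Gm21System:
    """Design matrix and response of the discrete GM(2,1) equations.

    ``B`` has one row per k = 2..n: ``[-x0(k), -z1(k), 1]``; ``Y`` holds
    the first differences ``x0(k) - x0(k-1)``.
    """

    B: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))
        object.__setattr__(self, "Y", np.asarray(self.Y, dtype=float))
        if self.B.shape != (self.Y.size, 3):
            raise ValueError(f"inconsistent system: B {self.B.shape}, Y {self.Y.shape}")


@dataclass(frozen=True)
class GreyCoefficients:
    """Fitted GM(2,1) parameters.

    ``a1`` and ``a2`` are the developing coefficients, ``b`` the influence
    coefficient.  ``degenerate`` is set when the system was rank-deficient
    and the minimum-norm solution was returned.
    """

    a1: float
    a2: float
    b: float
    residual: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.b], dtype=float)


def build_system(series) -> Gm21System:
    """Assemble the discrete GM(2,1) linear system for a series.

    Raises
    ------
    SeriesTooShortError
        If the series has fewer than ``MIN_SERIES_LENGTH`` (4) points.
    """
    x0 = _as_values(series)
    n = x0.size
    if n < MIN_SERIES_LENGTH:
        raise SeriesTooShortError(
            f"GM(2,1) needs at least {MIN_SERIES_LENGTH} points, got {n}"
        )
    x1 = np.cumsum(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-x0[1:], -z1, np.ones(n - 1)])
    Y = np.diff(x0)
    return Gm21System(B=B, Y=Y)


def fit_gm21(series) -> GreyCoefficients:
    """Least-squares fit of the GM(2,1) coefficients to a positive series.

    Solved through an orthogonal decomposition (`numpy.linalg.lstsq`)
    rather than the normal equations; on rank deficiency the minimum-norm
    solution is returned and flagged.

    Raises
    ------
    SeriesTooShortError
        Fewer than 4 points.
    ValueError
        Any non-positive value in the series.
    """
    x0 = _as_values(series)
    if x0.size >= 1 and np.any(x0 <= 0):
        raise ValueError("GM(2,1) requires a strictly positive series")
    system = build_system(x0)
    theta, _, rank, _ = np.linalg.lstsq(system.B, system.Y, rcond=_RANK_RTOL)
    residual = float(np.linalg.norm(system.B @ theta - system.Y))
    return GreyCoefficients(
        a1=float(theta[0]),
        a2=float(theta[1]),
        b=float(theta[2]),
        residual=residual,
        degenerate=bool(rank < 3),
    )


def grey_features(series) -> tuple[float, float, float]:
    """Absolute values ``(|a1|, |a2|, |b|)`` of the fitted coefficients."""
    coeffs = fit_gm21(series)
    return (abs(coeffs.a1), abs(coeffs.a2), abs(coeffs.b))
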