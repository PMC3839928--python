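"""Closed-form mathematics of the asymmetric generalized coherent state.

A transcript set's abundance profile across gel-electrophoresis migration
distances is modelled as a two-level distribution: each transcript's profile
is an asymmetric Gaussian ``exp(-K(x)(x-b)^2/2)`` centred at its peak ``b``,
and the peaks themselves are asymmetric-Gaussian distributed around an
equilibrium migration distance ``x0``.  The curvature ``K(x)`` is a
"generalized Hooke's constant" that takes different values on the two sides
of the centre, controlled by a dimensionless asymmetry ``s``.

Convention (fixed throughout the package): ``K(x) = k`` for ``x <= centre``
and ``K(x) = k*s**2`` for ``x > centre``, so the standard deviation on the
greater-migration (shorter-transcript) side is ``1/s`` times that on the
lesser-migration side.  ``s = 1`` recovers the symmetric textbook objects
(Gaussian, Hermite functions, Hooke's law).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import eval_hermite

__all__ = [
    "GelGrid",
    "ACSParams",
    "Calibration",
    "hooke_constant",
    "asymmetric_gaussian",
    "asymmetric_hermite",
    "inflection_parabola",
    "restoring_force",
    "fit_calibration",
    "HUMAN_ANCHORS",
    "YEAST_ANCHORS",
]

# Organism calibration anchors: (migration mm, transcript length nt) at the
# two ends of the measured gel range.
HUMAN_ANCHORS = ((26.0, 6400.0), (124.0, 500.0))
YEAST_ANCHORS = ((42.0, 4500.0), (100.0, 300.0))


@dataclass(frozen=True)
class GelGrid:
    """Uniformly spaced gel-slice migration coordinates, in mm."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("GelGrid needs at least 2 slice positions")
        diffs = np.diff(pos)
        if np.any(diffs <= 0):
            raise ValueError("slice positions must be strictly increasing")
        if not np.allclose(diffs, diffs[0]):
            raise ValueError("slice positions must be uniformly spaced")
        object.__setattr__(self, "positions", pos)

    @classmethod
    def uniform(cls, start: float, n_slices: int, slice_width: float = 2.0) -> "GelGrid":
        return cls(start + slice_width * np.arange(n_slices))

    @property
    def n_slices(self) -> int:
        return int(self.positions.size)

    @property
    def slice_width(self) -> float:
        return float(self.positions[1] - self.positions[0])


def human_grid() -> GelGrid:
    """The 50-slice, 2 mm human gel grid spanning 26-124 mm."""
    return GelGrid.uniform(26.0, 50, 2.0)


def yeast_grid() -> GelGrid:
    """The 30-slice, 2 mm yeast gel grid spanning 42-100 mm."""
    return GelGrid.uniform(42.0, 30, 2.0)


@dataclass
class ACSParams:
    """Parameter bundle of the asymmetric generalized coherent state.

    Attributes
    ----------
    x0 : equilibrium migration distance (mm).
    k : magnitude of the generalized Hooke's constant (mm^-2), > 0.
    s : asymmetry of the Hooke constant (dimensionless), > 0.
    eta : geometric eigenvalue ratio in (0, 1); optional until fitted.
    amplitude : nonnegative overall scale.
    """

    x0: float
    k: float
    s: float = 1.0
    eta: Optional[float] = None
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"Hooke magnitude k must be > 0, got {self.k}")
        if not (self.s > 0):
            raise ValueError(f"asymmetry s must be > 0, got {self.s}")
        if self.eta is not None and not (0 < self.eta < 1):
            raise ValueError(f"eta must lie in (0, 1), got {self.eta}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


def hooke_constant(x, params: ACSParams, center: float):
    """Piecewise generalized Hooke's constant K(x) about ``center``.

    Returns ``k`` for ``x <= center`` and ``k*s**2`` for ``x > center``.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x <= center, params.k, params.k * params.s**2)
    return out if out.ndim else float(out)


def asymmetric_gaussian(x, center: float, params: ACSParams):
    """Unit-peak asymmetric Gaussian ``exp(-K(x)(x-center)^2 / 2)``."""
    x = np.asarray(x, dtype=float)
    kk = hooke_constant(x, params, center)
    out = np.exp(-kk * (x - center) ** 2 / 2.0)
    return out if out.ndim else float(out)


def asymmetric_hermite(q: int, x, params: ACSParams,
                       grid: Optional[GelGrid] = None):
    """The q-th asymmetric Hermite function about the equilibrium x0.

    ``psi_q(x) = H_q(sqrt(K(x)) (x - x0)) * exp(-K(x)(x - x0)^2 / 2)`` with
    ``H_q`` the physicists' Hermite polynomial; generalizes the q-th
    eigenfunction of the quantum harmonic oscillator.  If ``grid`` is given
    the function is evaluated on scalar/array ``x`` but normalized so its
    values on the grid have unit Euclidean norm (matching unit-norm
    eigenvectors).
    """
    if q < 0 or int(q) != q:
        raise ValueError(f"order q must be a nonnegative integer, got {q}")
    x = np.asarray(x, dtype=float)
    kk = hooke_constant(x, params, params.x0)
    u = np.sqrt(kk) * (x - params.x0)
    out = eval_hermite(int(q), u) * np.exp(-(u**2) / 2.0)
    if grid is not None:
        kg = hooke_constant(grid.positions, params, params.x0)
        ug = np.sqrt(kg) * (grid.positions - params.x0)
        norm = np.linalg.norm(eval_hermite(int(q), ug) * np.exp(-(ug**2) / 2.0))
        if norm == 0:
            raise ValueError("degenerate basis function on this grid")
        out = out / norm
    return out if out.ndim else float(out)


def inflection_parabola(q_max: int, params: ACSParams,
                        half_width_sigmas: float = 8.0,
                        refine: int = 100) -> np.ndarray:
    """Sample the asymmetric parabola ``K(x)(x-x0)^2`` at the inflection
    points of psi_1..psi_{q_max}.

    Inflection points are located by sign changes of the discrete second
    difference on a grid refined ``refine``-fold relative to the broadest
    side standard deviation; ties resolve to the lower coordinate.  Returns
    an array of (x, parabola value) rows sorted by x.
    """
    if q_max < 1:
        raise ValueError("q_max must be >= 1")
    sigma = 1.0 / np.sqrt(params.k)  # broad (left) side
    span = half_width_sigmas * sigma
    step = sigma / refine
    xs = np.arange(params.x0 - span, params.x0 + span + step, step)
    points = []
    for q in range(1, q_max + 1):
        y = asymmetric_hermite(q, xs, params)
        d2 = np.diff(y, 2)
        sign = np.sign(d2)
        flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        for i in flips:
            x_inf = xs[i + 1]  # lower coordinate of the flip pair
            kk = hooke_constant(x_inf, params, params.x0)
            points.append((x_inf, kk * (x_inf - params.x0) ** 2))
    pts = np.array(sorted(points))
    return pts


def restoring_force(x, center: float, params: ACSParams):
    """Linear restoring force ``-K(x) (x - center)``.

    Zero at the centre; directed opposite to the displacement, like the
    restoring force of a harmonic oscillator with an asymmetric spring.
    """
    x = np.asarray(x, dtype=float)
    out = -hooke_constant(x, params, center) * (x - center)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Calibration:
    """Log-linear migration <-> length map ``x = a - b ln(L)``, b > 0.

    Migration distance decreases with transcript length: longer transcripts
    travel less far through the gel.
    """

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ValueError("calibration slope b must be > 0")

    def migration_to_length(self, x):
        x = np.asarray(x, dtype=float)
        out = np.exp((self.intercept - x) / self.slope)
        return out if out.ndim else float(out)

    def length_to_migration(self, length):
        length = np.asarray(length, dtype=float)
        if np.any(length <= 0):
            raise ValueError("lengths must be positive")
        out = self.intercept - self.slope * np.log(length)
        return out if out.ndim else float(out)

    def length_uncertainty(self, x: float, half_window_mm: float) -> float:
        """Half the length change across ``2*half_window_mm`` at ``x``."""
        lo = self.migration_to_length(x + half_window_mm)
        hi = self.migration_to_length(x - half_window_mm)
        return float((hi - lo) / 2.0)


def fit_calibration(anchor_points: Sequence[tuple]) -> Calibration:
    """Least-squares fit of ``x = a - b ln(L)`` to (migration, length) anchors.

    With exactly two anchors the fit passes through both.
    """
    pts = np.asarray(anchor_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least 2 (migration, length) anchor points")
    x, length = pts[:, 0], pts[:, 1]
    if np.any(length <= 0):
        raise ValueError("anchor lengths must be positive")
    if np.unique(length).size < 2:
        raise ValueError("anchor lengths must be distinct")
    # regress x on ln L: x = a - b ln L
    coef = np.polyfit(np.log(length), x, 1)
    b = -coef[0]
    a = coef[1]
    return Calibration(intercept=float(a), slope=float(b))


def human_calibration() -> Calibration:
    return fit_calibration(HUMAN_ANCHORS)


def yeast_calibration() -> Calibration:
    return fit_calibration(YEAST_ANCHORS)
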