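"""Spatial grids, Gaussian connection kernels, and the shared leaky-integrator
update used by every map in the model.

All maps are rate-coded populations on uniform 1-D grids of preferred
positions (2-D maps are outer products of two such grids).  Each population
relaxes toward its instantaneous drive with a single time constant,

    tau * dr/dt = drive - r,

integrated with explicit Euler steps and clipped at zero (firing rates).
Connection weights everywhere are unnormalised Gaussians of a declared
distance metric, w(d) = K * exp(-d^2 / sigma^2); note the convention without
the factor 2 in the denominator, matching the printed readout kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError

__all__ = [
    "SpatialGrid",
    "GaussianKernel",
    "RatePopulation",
    "make_grid",
    "gaussian_kernel",
    "diagonal_kernel",
    "euler_step",
]


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform 1-D grid of preferred positions spanning [-v/2, +v/2]."""

    n: int
    v: float
    centers: np.ndarray = field(repr=False)

    @property
    def spacing(self) -> float:
        return self.v / (self.n - 1)

    def index_of(self, position: float) -> int:
        """Index of the grid cell whose center is nearest to ``position``."""
        return int(np.argmin(np.abs(self.centers - position)))


def make_grid(n: int, v: float) -> SpatialGrid:
    """Build a uniform grid of ``n`` preferred positions over ``v`` degrees.

    Centers include both endpoints: first = -v/2, last = +v/2, spacing
    v/(n-1).  Positions are in degrees; the saccade direction is positive.
    """
    if n < 2:
        raise ConfigurationError(f"grid needs at least 2 neurons, got n={n}")
    if v <= 0:
        raise ConfigurationError(f"visual field extent must be positive, got v={v}")
    centers = np.linspace(-v / 2.0, v / 2.0, n)
    return SpatialGrid(n=int(n), v=float(v), centers=centers)


@dataclass(frozen=True)
class GaussianKernel:
    """Dense Gaussian weight table from source indices to target indices.

    ``matrix[i, j]`` is the weight from source cell j onto target cell i;
    every entry equals K * exp(-d^2 / sigma^2) for the declared distance
    metric (degrees between centers, or raw index distance), optionally
    rescaled so each target's incoming weights sum to K.
    """

    K: float
    sigma: float
    direction: str
    matrix: np.ndarray = field(repr=False)


def gaussian_kernel(
    source: SpatialGrid,
    target: SpatialGrid,
    K: float,
    sigma: float,
    direction: str = "horizontal",
    units: str = "deg",
    normalize: bool = False,
) -> GaussianKernel:
    """Gaussian connectivity from a 1-D source grid onto a 1-D target grid.

    Parameters
    ----------
    direction
        ``horizontal`` or ``vertical``: which axis of a 2-D target map the
        kernel feeds (bookkeeping only; the matrix is 1-D -> 1-D either way).
        ``diagonal`` kernels onto 2-D index sets are built with
        :func:`diagonal_kernel` instead.
    units
        ``deg``: distance between preferred positions in degrees.
        ``index``: raw index distance.
    normalize
        Rescale each row to sum to K, so that convolving a broad unit bump
        yields a unit bump (used for the feedforward input kernels).
    """
    if K <= 0 or sigma <= 0:
        raise ConfigurationError("kernel gain and width must be positive")
    if direction == "diagonal":
        raise ConfigurationError(
            "direction='diagonal' requires a 2-D target; use diagonal_kernel"
        )
    if units == "deg":
        d = target.centers[:, None] - source.centers[None, :]
    elif units == "index":
        d = np.arange(target.n)[:, None] - np.arange(source.n)[None, :]
    else:
        raise ConfigurationError(f"unknown distance units {units!r}")
    matrix = K * np.exp(-(d.astype(float) ** 2) / sigma**2)
    if normalize:
        matrix *= K / matrix.sum(axis=1, keepdims=True)
    return GaussianKernel(K=float(K), sigma=float(sigma), direction=direction,
                          matrix=matrix)


def diagonal_kernel(n: int, K: float, sigma: float) -> GaussianKernel:
    """Gaussian readout along the diagonals of an n x n map.

    Connects 2-D cells (l, m) to the 2n-1 diagonal bins h with weight
    K * exp(-(h - l - m)^2 / sigma^2), the index-distance form of the
    printed readout kernels.  The returned matrix has shape
    (2n-1, n*n) and acts on the row-major raveled map.
    """
    if K <= 0 or sigma <= 0:
        raise ConfigurationError("kernel gain and width must be positive")
    h = np.arange(2 * n - 1)
    l = np.arange(n)
    m = np.arange(n)
    s = l[:, None] + m[None, :]          # l + m for every 2-D cell
    d = h[:, None] - s.ravel()[None, :]  # (2n-1, n*n)
    matrix = K * np.exp(-(d.astype(float) ** 2) / sigma**2)
    return GaussianKernel(K=float(K), sigma=float(sigma), direction="diagonal",
                          matrix=matrix)


@dataclass
class RatePopulation:
    """Leaky-integrator firing-rate population over one or two grids."""

    grid: SpatialGrid
    tau: float
    rates: np.ndarray
    grid2: SpatialGrid | None = None  # column grid for 2-D maps

    @classmethod
    def zeros(cls, grid: SpatialGrid, tau: float,
              grid2: SpatialGrid | None = None) -> "RatePopulation":
        shape = (grid.n, grid2.n) if grid2 is not None else (grid.n,)
        return cls(grid=grid, tau=float(tau), rates=np.zeros(shape), grid2=grid2)

    def step(self, drive: np.ndarray, dt: float) -> None:
        """In-place Euler update toward ``drive`` (hot path)."""
        r = self.rates
        r += (dt / self.tau) * (drive - r)
        np.maximum(r, 0.0, out=r)


def euler_step(pop: RatePopulation, drive: np.ndarray, dt: float) -> RatePopulation:
    """One explicit Euler step of tau dr/dt = drive - r, clipped at zero.

    Returns a new population; the input is left untouched.  ``dt`` must be
    at most tau/5 for the discretisation to stay well inside the stability
    region of the leaky integrator.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    if dt > pop.tau / 5.0:
        raise ConfigurationError(
            f"dt={dt} too large for tau={pop.tau}; require dt <= tau/5"
        )
    drive = np.asarray(drive, dtype=float)
    if drive.shape != pop.rates.shape:
        raise ValueError(
            f"drive shape {drive.shape} does not match rates {pop.rates.shape}"
        )
    new = RatePopulation(grid=pop.grid, tau=pop.tau,
                         rates=pop.rates.copy(), grid2=pop.grid2)
    new.step(drive, dt)
    return new
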