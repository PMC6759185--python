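"""B-spline bases over delay and time, and kernel realization.

All model kernels are parameterized as linear combinations of quadratic
(degree-2) B-splines with *simple* (non-repeated) knots, so a knot vector
with ``m`` knots yields ``m - 3`` basis functions.  Stimulus kernels live on
a tensor-product lattice ``B_{i,j}(t, tau) = U_i(tau) * V_j(t)`` where
``tau`` is the response latency (delay since stimulus onset) and ``t`` is
time relative to saccade onset.  Bases are pre-evaluated on the 1 ms lattice
and cached on the object, since fitting re-evaluates them constantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 2

# Default knot grids (ms).  Delay knots span a 150 ms-long latency kernel;
# the time/offset knots span a 1081 ms-long kernel centered on the saccade.
DELAY_KNOTS = tuple(range(-13, 163, 7))            # 26 knots -> 23 functions
TIME_KNOTS = tuple(range(-554, 553, 7))            # 159 knots -> 156 functions
OFFSET_KNOTS = tuple(range(-570, 571, 15))         # 77 knots -> 74 functions
POSTSPIKE_KNOTS = (1, 2, 3, 4, 6, 8, 15, 22, 29, 36, 43, 50, 57, 64,
                   71, 78, 92, 106, 120, 134, 148, 162, 176)  # -> 20 functions

DELAY_SUPPORT = (0, 150)       # latency lattice used for realized kernels
TIME_SUPPORT = (-540, 541)     # time lattice (1081 ms centered at saccade)


class InvalidInputError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass(frozen=True)
class KnotVector:
    """Strictly increasing knot sequence for a degree-``degree`` spline."""

    knots: tuple
    degree: int = DEGREE

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        if k.ndim != 1 or len(k) < self.degree + 2:
            raise InvalidInputError(
                f"need at least {self.degree + 2} knots, got {len(k)}")
        if not np.all(np.diff(k) > 0):
            raise InvalidInputError("knots must be strictly increasing")

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1


class BasisSet1D:
    """Degree-2 B-spline basis evaluated on an integer-ms lattice.

    Outside the knot-supported span every function is defined as 0, so
    realized kernels vanish off-support.
    """

    def __init__(self, knots, grid=None, degree: int = DEGREE):
        if not isinstance(knots, KnotVector):
            knots = KnotVector(tuple(knots), degree)
        self.knots = knots
        kn = np.asarray(knots.knots, dtype=float)
        if grid is None:
            grid = np.arange(int(np.ceil(kn[0])), int(np.floor(kn[-1])) + 1)
        self.grid = np.asarray(grid, dtype=int)
        self.n_basis = knots.n_basis
        deg = knots.degree
        # Each degree-k function is the Cox-de Boor element on its k+2
        # consecutive knots; simple knots, no clamping.
        self._elements = [BSpline.basis_element(kn[i:i + deg + 2],
                                                extrapolate=False)
                          for i in range(self.n_basis)]
        self.values = self.evaluate(self.grid.astype(float))
        self.values[self.values < 0] = 0.0      # clip fp dust; B-splines >= 0

    def __len__(self) -> int:
        return self.n_basis

    def evaluate(self, x):
        """Evaluate every basis function at arbitrary points (columns)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros((self.n_basis, len(x)))
        for i, f in enumerate(self._elements):
            out[i] = np.nan_to_num(f(x), nan=0.0)
        return out


@dataclass
class BasisSet2D:
    """Tensor product of a delay basis and a time basis."""

    delay_basis: BasisSet1D
    time_basis: BasisSet1D

    @property
    def shape(self):
        return (self.delay_basis.n_basis, self.time_basis.n_basis)

    def tensor(self, i: int, j: int) -> np.ndarray:
        """``B_{i,j}(t, tau)`` on the (time, delay) lattice."""
        return np.outer(self.time_basis.values[j], self.delay_basis.values[i])


def bspline_basis(knots, grid=None, degree: int = DEGREE) -> BasisSet1D:
    """Construct a degree-2 B-spline basis from a knot list.

    Returns ``len(knots) - 3`` functions evaluated on the integer-ms grid
    (defaults to the span of the knots).
    """
    return BasisSet1D(knots, grid=grid, degree=degree)


def default_bases():
    """The four default bases: delay U, time V, post-spike H, offset O."""
    delay = bspline_basis(DELAY_KNOTS, grid=np.arange(*DELAY_SUPPORT))
    time = bspline_basis(TIME_KNOTS, grid=np.arange(*TIME_SUPPORT))
    post = bspline_basis(POSTSPIKE_KNOTS, grid=np.arange(1, 151))
    offset = bspline_basis(OFFSET_KNOTS, grid=np.arange(*TIME_SUPPORT))
    return BasisSet2D(delay_basis=delay, time_basis=time), post, offset


@dataclass
class KernelField:
    """Realized stimulus kernels ``k_{x,y}(t, tau)`` on a dense lattice.

    values has shape (n_rows, n_cols, n_time, n_delay); time_grid and
    delay_grid carry the ms coordinates of the last two axes.
    """

    values: np.ndarray
    time_grid: np.ndarray
    delay_grid: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_grid = np.asarray(self.time_grid)
        self.delay_grid = np.asarray(self.delay_grid)
        if self.values.ndim != 4:
            raise InvalidInputError("kernel field must be 4-D (row, col, t, tau)")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("kernel field contains non-finite values")


def realize_stimulus_kernel(kappa: np.ndarray, basis2d: BasisSet2D) -> KernelField:
    """Realize ``k_{x,y}(t,tau) = sum_{i,j} kappa_{x,y,i,j} U_i(tau) V_j(t)``.

    ``kappa`` has shape (n_rows, n_cols, n_delay_basis, n_time_basis).
    """
    kappa = np.asarray(kappa, dtype=float)
    if kappa.ndim != 4:
        raise InvalidInputError("kappa must be 4-D (row, col, i, j)")
    ni, nj = basis2d.shape
    if kappa.shape[2] != ni or kappa.shape[3] != nj:
        raise InvalidInputError(
            f"kappa basis dims {kappa.shape[2:]} do not match bases {(ni, nj)}")
    U = basis2d.delay_basis.values      # (ni, n_tau)
    V = basis2d.time_basis.values       # (nj, n_t)
    # (r, c, i, j) x (j, t) -> (r, c, i, t); then x (i, tau) -> (r, c, t, tau)
    vals = np.einsum("rcij,jt,iu->rctu", kappa, V, U, optimize=True)
    return KernelField(vals, basis2d.time_basis.grid, basis2d.delay_basis.grid)


def realize_postspike_kernel(eta: np.ndarray, H: BasisSet1D) -> np.ndarray:
    """``h(tau) = -sum_i eta_i^2 H_i(tau)``: non-positive by construction."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (H.n_basis,):
        raise InvalidInputError(
            f"eta has shape {eta.shape}, expected ({H.n_basis},)")
    return -(eta ** 2) @ H.values


def realize_offset_kernel(beta: np.ndarray, O: BasisSet1D) -> np.ndarray:
    """``b(t) = sum_j beta_j O_j(t)`` on the time lattice of ``O``."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (O.n_basis,):
        raise InvalidInputError(
            f"beta has shape {beta.shape}, expected ({O.n_basis},)")
    return beta @ O.values
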