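"""Capacity, Coulomb energy, transport coefficients, and polarizability of
union-of-spheres bead models.

Conventions (Gaussian-style units with the Coulomb constant and the total
charge set to 1): the electrostatic capacity C of a sphere equals its
radius, the Coulomb energy of the equilibrium charge distribution is
E_C = 1/(2 C), the hydrodynamic radius is R_h = C, the translational
friction coefficient f_t = 6 pi eta C (an O(1%) approximation for rigid
bodies with stick boundary conditions), and the mobility mu = 1/f_t.

Two independent routes to C are implemented:

* :func:`capacity_walk` -- a path-integral (walk-on-spheres) Monte Carlo
  estimate: the capacity is the launch radius times the probability that a
  diffusing walker started on the launch sphere hits the body before
  escaping to infinity;
* :func:`capacity_mom` -- a deterministic method-of-moments solve of the
  discretized Kelvin variational principle: point charges on the bead
  centers with self-term 1/bead_radius, off-diagonal 1/distance, at unit
  surface potential.

Each serves as the oracle for the other in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import RingConfiguration


@dataclass
class BeadModel:
    """Union of equal spheres: centers (N, 3) + bead radius (sigma/2 for
    the dsDNA bead-chain mapping)."""

    centers: np.ndarray
    bead_radius: float = 0.5

    def __post_init__(self) -> None:
        self.centers = np.ascontiguousarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise ValueError("centers must be an (N, 3) array")
        if len(self.centers) < 1:
            raise ValueError("empty bead model")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")

    @classmethod
    def from_configuration(cls, config: RingConfiguration,
                           bead_radius: float = 0.5) -> "BeadModel":
        return cls(config.positions, bead_radius)


@dataclass
class ElectrostaticResult:
    capacity: float
    capacity_stderr: float
    n_walks: int

    @property
    def coulomb_energy(self) -> float:
        return coulomb_energy_of(self.capacity)


@dataclass
class TransportResult:
    hydrodynamic_radius: float
    friction: float
    mobility: float
    viscosity_eta: float


def coulomb_energy_of(capacity: float) -> float:
    """E_C = 1/(2 C) with unit charge and unit Coulomb constant."""
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    return 1.0 / (2.0 * capacity)


def transport_from_capacity(capacity: float, eta: float = 1.0) -> TransportResult:
    """Hydrodynamic radius, friction, and mobility from the capacity."""
    if capacity <= 0 or eta <= 0:
        raise ValueError("capacity and eta must be positive")
    f_t = 6.0 * math.pi * eta * capacity
    return TransportResult(hydrodynamic_radius=capacity, friction=f_t,
                           mobility=1.0 / f_t, viscosity_eta=eta)


def _grid_arrays(centers: np.ndarray, r_bead: float):
    """Uniform-grid CSR structure for nearest-sphere queries."""
    a = 3.0 * r_bead
    lo = centers.min(axis=0) - 0.5 * a
    dims = np.maximum(((centers.max(axis=0) - lo) / a).astype(np.int64) + 1, 1)
    idx = np.minimum(((centers - lo) / a).astype(np.int64), dims - 1)
    flat = (idx[:, 0] * dims[1] + idx[:, 1]) * dims[2] + idx[:, 2]
    order = np.argsort(flat, kind="stable")
    counts = np.bincount(flat, minlength=int(dims.prod()))
    start = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return lo, dims, a, start, order.astype(np.int64)


def capacity_walk(model: BeadModel, n_walks: int = 100_000,
                  seed: int = 0, eps: float = 1e-4,
                  launch_factor: float = 1.5) -> ElectrostaticResult:
    """Walk-on-spheres capacity of a union-of-spheres body.

    The walker jumps on spheres inscribed in the free space (using the
    exact distance to the union near the body, and safe lower bounds far
    from it); re-entry through the launch sphere uses the exact Poisson
    kernel, so the estimate C = R_launch * P(hit) is unbiased up to the
    eps-capture shell.  The standard error is binomial.
    """
    if n_walks < 1000:
        raise ValueError("n_walks must be at least 1e3")
    centers = model.centers - model.centers.mean(axis=0)
    r_circ = float(np.linalg.norm(centers, axis=1).max()) + model.bead_radius
    r_launch = launch_factor * r_circ
    use_grid = len(centers) > 256
    if use_grid:
        lo, dims, a, start, items = _grid_arrays(centers, model.bead_radius)
    else:
        lo = np.zeros(3)
        dims = np.ones(3, np.int64)
        a = 1.0
        start = np.zeros(2, np.int64)
        items = np.zeros(0, np.int64)
    hits = _kernels.wos_capacity(centers, model.bead_radius, r_circ, r_launch,
                                 n_walks, seed & 0x7FFFFFFF, eps, lo, dims, a,
                                 start, items, use_grid, 100_000)
    p = hits / n_walks
    cap = r_launch * p
    stderr = r_launch * math.sqrt(max(p * (1.0 - p), 1.0 / n_walks) / n_walks)
    return ElectrostaticResult(capacity=cap, capacity_stderr=stderr,
                               n_walks=n_walks)


def _merged_centers(model: BeadModel) -> np.ndarray:
    c = model.centers
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-9:
        warnings.warn("duplicate bead centers merged for the capacity solve")
        keep = np.ones(len(c), bool)
        for i in range(len(c)):
            if keep[i]:
                keep[np.flatnonzero((d[i] < 1e-9) & (np.arange(len(c)) > i))] = False
        c = c[keep]
    return c


def capacity_mom(model: BeadModel) -> float:
    """Method-of-moments capacity: solve M q = 1 with M_ii = 1/a,
    M_ij = 1/r_ij, and return the total charge (deterministic oracle)."""
    c = _merged_centers(model)
    n = len(c)
    if n > 3000:
        raise ValueError("dense method-of-moments solve limited to N <= 3000")
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    np.fill_diagonal(d, 1.0)
    m = 1.0 / d
    np.fill_diagonal(m, 1.0 / model.bead_radius)
    q = np.linalg.solve(m, np.ones(n))
    return float(q.sum())


def polarizability_mom(model: BeadModel) -> np.ndarray:
    """Electric polarizability tensor of the neutral conductor by a
    charge-plus-dipole interaction model.

    Each bead carries an induced monopole q_i and an induced point dipole
    p_i.  The monopoles enforce a constant potential at the bead centers
    (charge transfer along the body, the dominant contribution for chains);
    the dipoles respond to the local field with the single-sphere
    polarizability a^3, which makes the one-bead limit exact (alpha = a^3
    for a sphere of radius a).  Only ratios of traces are consumed
    downstream (the intrinsic-viscosity g-ratio), so the universal
    proportionality between [eta] and the polarizability trace cancels.
    """
    c = _merged_centers(model)
    n = len(c)
    a = model.bead_radius
    a3 = a ** 3
    rij = c[None, :, :] - c[:, None, :]          # r_j - r_i, (i, j, 3)
    d = np.linalg.norm(rij, axis=-1)
    np.fill_diagonal(d, np.inf)
    inv = 1.0 / d
    inv3 = inv ** 3
    rhat = rij * inv[..., None]
    nun = 4 * n + 1                              # q (n), p (3n), phi0
    A = np.zeros((nun, nun))
    # potential at center j: q_j/a + sum_i q_i/r_ij + sum_i p_i.rhat_ij/r_ij^2
    # (rhat_ij points i -> j) equals phi0 minus the external potential
    A[:n, :n] = inv.T
    A[np.arange(n), np.arange(n)] = 1.0 / a
    # dipole columns are laid out as p_0, p_1, ... each contiguous (3,)
    P = np.zeros((n, 3 * n))
    for i in range(n):
        P[:, 3 * i:3 * i + 3] = rhat[i] * (inv[i] ** 2)[:, None]
        P[i, 3 * i:3 * i + 3] = 0.0
    A[:n, n:4 * n] = P
    A[:n, 4 * n] = -1.0
    # dipole response rows: p_j - a^3 * (field at j from others) = a^3 E_ext
    for j in range(n):
        rows = slice(n + 3 * j, n + 3 * j + 3)
        A[rows, n + 3 * j:n + 3 * j + 3] = np.eye(3)
        for i in range(n):
            if i == j:
                continue
            # field at j from charge q_i: q_i * rhat_ij / r^2
            A[rows, i] = -a3 * rhat[i, j] * inv[i, j] ** 2
            # field at j from dipole p_i: (3 rhat (rhat.p) - p)/r^3
            T = (3.0 * np.outer(rhat[i, j], rhat[i, j]) - np.eye(3)) * inv3[i, j]
            A[rows, n + 3 * i:n + 3 * i + 3] = -a3 * T
    A[4 * n, :n] = 1.0                           # neutrality
    alpha = np.zeros((3, 3))
    for k in range(3):
        rhs = np.zeros(nun)
        rhs[:n] = c[:, k]                        # -phi_ext = E.r, unit E
        rhs[n + k:4 * n:3] = a3                  # a^3 * E_ext
        sol = np.linalg.solve(A, rhs)
        alpha[:, k] = sol[:n] @ c + sol[n:4 * n].reshape(n, 3).sum(axis=0)
    return 0.5 * (alpha + alpha.T)


def polarizability_trace(model: BeadModel) -> float:
    """Mean diagonal element of the polarizability tensor."""
    return float(np.trace(polarizability_mom(model)) / 3.0)


def solid_sphere_model(radius: float = 1.0, n_shell: int = 1600,
                       bead_radius: float = 0.15) -> BeadModel:
    """Dense union-of-spheres shell approximating a solid sphere.

    Bead centers sit on a Fibonacci lattice at ``radius - bead_radius`` so
    the union's outer envelope tracks the target sphere; with the default
    density the sagitta between neighboring beads is < 0.005 radius.
    """
    i = np.arange(n_shell)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    t = 1.0 - 2.0 * (i + 0.5) / n_shell
    st = np.sqrt(1.0 - t * t)
    pts = np.stack([st * np.cos(phi), st * np.sin(phi), t], axis=1)
    return BeadModel((radius - bead_radius) * pts, bead_radius)
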