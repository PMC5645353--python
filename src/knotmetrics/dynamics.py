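"""Langevin sampling of ring/linear polymer ensembles and canonical-knot
generation.

The sampler uses BAOAB Langevin dynamics (friction gamma = 1 in reduced
units) as the thermostat.  Ensemble averages of configurational observables
are thermostat-independent, so this choice is interchangeable with other
NVT thermostats for every quantity this package reports.

Canonical knots -- the apparently unique minimum-Coulomb-energy shape of a
knotted ring -- are produced by progressively charging the beads
(Z = 1, 2, 4, 7, 10) and relaxing the structure by energy minimization
after each charging step, monitoring the capacity-based Coulomb energy
E_C = 1/(2C) for convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .forcefield import ForceField
from .geometry import RingConfiguration, SIGMA_NM
from .topology import knot_determinant


class TopologyViolation(RuntimeError):
    """A trajectory changed its knot determinant (chain crossing)."""


class BondOverstretch(RuntimeError):
    """A FENE bond reached R0 during dynamics (timestep too large)."""


@dataclass
class SimulationParams:
    temperature: float = 1.0          # epsilon / k_B
    dt: float = 0.006                 # sigma (m/epsilon)^(1/2)
    n_equil_steps: int = 100_000
    n_prod_steps: int = 400_000
    sample_stride: int = 2_000
    seed: int = 0
    friction_gamma: float = 1.0
    thermostat: str = "langevin"

    def __post_init__(self) -> None:
        if not (0.0 < self.dt <= 0.01):
            raise ValueError("dt must be in (0, 0.01]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.thermostat != "langevin":
            raise ValueError("only the langevin thermostat is implemented")


@dataclass
class Ensemble:
    """Equilibrated configurations sharing topology, N, and force field."""

    configurations: list[RingConfiguration]
    params: SimulationParams
    forcefield: ForceField
    kinetic_energies: np.ndarray | None = None
    potential_energies: np.ndarray | None = None
    records: "object | None" = None   # pandas DataFrame filled by pipeline

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def n_beads(self) -> int:
        return self.configurations[0].n_beads

    @property
    def knot_label(self) -> str:
        return self.configurations[0].knot_label

    def positions_array(self) -> np.ndarray:
        return np.stack([c.positions for c in self.configurations])


def _pack(ff: ForceField) -> np.ndarray:
    style = {"wca": 0.0, "lj": 1.0, "none": 2.0}[ff.pair_style]
    return _kernels.pack_ff(ff.k_fene, ff.r0, ff.k_bend, ff.z_charge,
                            ff.coulomb_cutoff, style, ff.lj_cutoff, ff.epsilon)


def potential_energy(config: RingConfiguration, ff: ForceField) -> float:
    """Total potential energy of one configuration (reduced units)."""
    return float(_kernels.total_energy(config.positions, config.closed, _pack(ff)))


def run_md(config: RingConfiguration, ff: ForceField, *, temperature: float,
           dt: float, gamma: float, n_steps: int, stride: int, seed: int,
           velocities: np.ndarray | None = None, skin: float = 0.4):
    """Low-level driver: run dynamics from ``config``, return
    (final RingConfiguration, trajectory (n_samples,N,3), KE, PE, velocities).

    gamma = 0 gives plain velocity-Verlet NVE integration."""
    pos = config.positions.copy()
    rng = np.random.default_rng(seed)
    if velocities is None:
        vel = rng.normal(0.0, np.sqrt(temperature), size=pos.shape)
        vel -= vel.mean(axis=0)
    else:
        vel = velocities.copy()
    n_samples = n_steps // stride
    traj = np.empty((n_samples, pos.shape[0], 3))
    ke = np.empty(n_samples)
    pe = np.empty(n_samples)
    bad = _kernels.run_langevin(pos, vel, config.closed, _pack(ff), dt, gamma,
                                temperature, n_steps, stride,
                                int(rng.integers(2**31 - 1)), skin, traj, ke, pe)
    if bad >= 0:
        raise BondOverstretch(f"FENE bond reached R0 at step {bad}")
    out = RingConfiguration(pos, config.closed, config.knot_label)
    return out, traj, ke, pe, vel


def sample_ensemble(initial: RingConfiguration, ff: ForceField,
                    params: SimulationParams,
                    check_topology: bool = True) -> Ensemble:
    """Equilibrate ``initial`` and sample an NVT ensemble.

    Configurations are recorded every ``sample_stride`` production steps.
    For closed chains the knot determinant of the final configuration is
    verified against the initial one; WCA+FENE energetics make crossings
    energetically prohibitive, and this post-hoc certificate (applied
    per frame in the test suite) confirms none occurred.
    """
    det0 = None
    if initial.closed and check_topology:
        det0 = knot_determinant(initial)
    state, _, _, _, vel = run_md(
        initial, ff, temperature=params.temperature, dt=params.dt,
        gamma=params.friction_gamma, n_steps=params.n_equil_steps,
        stride=max(params.n_equil_steps, 1), seed=params.seed)
    state, traj, ke, pe, _ = run_md(
        state, ff, temperature=params.temperature, dt=params.dt,
        gamma=params.friction_gamma, n_steps=params.n_prod_steps,
        stride=params.sample_stride, seed=params.seed + 1, velocities=vel)
    configs = [RingConfiguration(traj[i], initial.closed, initial.knot_label)
               for i in range(traj.shape[0])]
    if det0 is not None:
        det1 = knot_determinant(state)
        if det1 != det0:
            raise TopologyViolation(
                f"knot determinant changed {det0} -> {det1} during sampling")
    return Ensemble(configs, params, ff, kinetic_energies=ke,
                    potential_energies=pe)


def block_stderr(x: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean from block averaging (accounts for serial
    correlation within a trajectory)."""
    x = np.asarray(x, dtype=float)
    n_blocks = min(n_blocks, len(x))
    if n_blocks < 2:
        return float("nan")
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def persistence_length(linear_ensemble: Ensemble) -> dict:
    """Persistence length l_p = <R_e . l_1> / <l_1> of an open-chain
    ensemble: the mean projection of the end-to-end vector on the first
    bond, normalized by the mean first-bond length.

    Both chain ends are used (the chain is statistically symmetric under
    reversal), and the standard error comes from block averaging.  Returns
    reduced units and nm (sigma = 2.8 nm).
    """
    if linear_ensemble.configurations[0].closed:
        raise ValueError("persistence length is defined for open chains")
    pos = linear_ensemble.positions_array()       # (F, N, 3)
    re = pos[:, -1] - pos[:, 0]
    l1 = pos[:, 1] - pos[:, 0]
    l1r = pos[:, -2] - pos[:, -1]
    proj = 0.5 * (np.einsum("ij,ij->i", re, l1)
                  + np.einsum("ij,ij->i", -re, l1r))
    blen = 0.5 * (np.linalg.norm(l1, axis=1) + np.linalg.norm(l1r, axis=1))
    lp = proj.mean() / blen.mean()
    # first-order error propagation; the denominator barely fluctuates
    se = block_stderr(proj) / blen.mean()
    return {"lp_sigma": float(lp), "lp_nm": float(lp) * SIGMA_NM,
            "stderr_sigma": se, "stderr_nm": se * SIGMA_NM,
            "n_frames": len(linear_ensemble)}


DEFAULT_CHARGE_SCHEDULE = (1.0, 2.0, 4.0, 7.0, 10.0)


def make_canonical_knot(initial: RingConfiguration, ff: ForceField,
                        schedule=DEFAULT_CHARGE_SCHEDULE,
                        tol: float = 1e-4, max_rounds: int = 8,
                        maxiter: int = 3000) -> tuple[RingConfiguration, float]:
    """Canonical (minimum-Coulomb-energy) form of a knotted ring.

    The bead charge is ramped up through ``schedule`` (final Z = 10); after
    each charging step the full potential energy (WCA + FENE + bending +
    truncated Coulomb) is minimized with L-BFGS until the relative change
    of the capacity-based Coulomb energy E_C = 1/(2C) over successive
    minimization rounds falls below ``tol``.  Returns the relaxed
    configuration and its converged E_C.  Topology is certified unchanged
    via the knot determinant.
    """
    from scipy.optimize import minimize
    from .electrostatics import BeadModel, capacity_mom

    det0 = knot_determinant(initial)
    x = initial.positions.copy().ravel()
    n = initial.n_beads
    ec_trace: list[float] = []
    for z in schedule:
        ffz = ff.with_charge(z)
        packed = _pack(ffz)
        ec_prev = None
        for _ in range(max_rounds):
            res = minimize(_kernels.energy_and_grad, x, args=(n, initial.closed, packed),
                           jac=True, method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
            x = res.x
            cap = capacity_mom(BeadModel(x.reshape(n, 3)))
            ec = 1.0 / (2.0 * cap)
            ec_trace.append(ec)
            if ec_prev is not None and abs(ec - ec_prev) <= tol * abs(ec_prev):
                break
            ec_prev = ec
        else:
            raise RuntimeError(
                f"canonical-knot relaxation did not converge at Z={z}; "
                f"E_C trace: {ec_trace}")
    out = RingConfiguration(x.reshape(n, 3), initial.closed, initial.knot_label)
    if knot_determinant(out) != det0:
        raise TopologyViolation("canonical-knot relaxation changed the topology")
    return out, ec_trace[-1]
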