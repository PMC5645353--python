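"""Integrator correctness, thermal statistics, and topology conservation."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from knotmetrics import make_linear_chain, make_tabulated_knot, knot_determinant
from knotmetrics.dynamics import (SimulationParams, make_canonical_knot,
                                  persistence_length, run_md, sample_ensemble)
from knotmetrics.forcefield import ForceField, fene_bond_energy, wca_pair_energy
from knotmetrics.shape import gyration_tensor


def test_nve_energy_conservation():
    """With the thermostat off the integrator is velocity Verlet; total
    energy drifts by less than 1e-3 relative over 1e4 steps at dt=0.006."""
    cfg = make_tabulated_knot("3_1", 63)
    ff = ForceField(k_bend=1.0)
    # thermalize first, then switch the bath off
    state, _, _, _, vel = run_md(cfg, ff, temperature=1.0, dt=0.006, gamma=1.0,
                                 n_steps=20_000, stride=20_000, seed=3)
    _, _, ke, pe, _ = run_md(state, ff, temperature=1.0, dt=0.006, gamma=0.0,
                             n_steps=10_000, stride=100, seed=4, velocities=vel)
    e = ke + pe
    assert abs(e[-1] - e[0]) / abs(e[0]) < 1e-3
    assert (e.max() - e.min()) / abs(e.mean()) < 1e-3


def test_equipartition(trefoil_ensemble):
    """<KE>/bead = (3/2) k_B T within a few standard errors."""
    ke = trefoil_ensemble.kinetic_energies / trefoil_ensemble.n_beads
    se = ke.std(ddof=1) / math.sqrt(len(ke))
    assert abs(ke.mean() - 1.5) < max(3 * se, 0.03)


def test_mean_bond_length_matches_boltzmann_oracle(trefoil_ensemble):
    """Ensemble bond length vs the 1-D Boltzmann integral over the
    FENE+WCA bond potential (radial measure r^2 e^{-U/T})."""
    def u(r):
        return fene_bond_energy(r) + wca_pair_energy(r)
    z0 = quad(lambda r: r**2 * math.exp(-u(r)), 0.4, 1.499)[0]
    z1 = quad(lambda r: r**3 * math.exp(-u(r)), 0.4, 1.499)[0]
    oracle = z1 / z0
    bonds = np.concatenate([c.bond_lengths()
                            for c in trefoil_ensemble.configurations])
    assert 0.9 < bonds.mean() < 1.1
    assert bonds.mean() == pytest.approx(oracle, abs=0.02)


def test_topology_conserved_every_frame(trefoil_ensemble):
    """The knot determinant is invariant across every sampled frame."""
    for cfg in trefoil_ensemble.configurations:
        assert knot_determinant(cfg) == 3


def test_unknot_stays_unknotted():
    params = SimulationParams(n_equil_steps=30_000, n_prod_steps=60_000,
                              sample_stride=2_000, seed=9)
    ens = sample_ensemble(make_tabulated_knot("0_1", 63),
                          ForceField(k_bend=1.0), params)
    assert all(knot_determinant(c) == 1 for c in ens.configurations)


def test_stiff_limit_is_nearly_straight():
    """Very large bending constant keeps a linear chain rod-like."""
    chain = make_linear_chain(32)
    _, traj, _, _, _ = run_md(chain, ForceField(k_bend=1000.0),
                              temperature=1.0, dt=0.006, gamma=1.0,
                              n_steps=20_000, stride=1_000, seed=2)
    bonds = traj[:, 1:] - traj[:, :-1]
    bonds /= np.linalg.norm(bonds, axis=-1, keepdims=True)
    cos = np.einsum("fij,fij->fi", bonds[:, :-1], bonds[:, 1:])
    assert cos.mean() > 0.99


def test_persistence_length_frozen_rod():
    """For a frozen straight rod, l_p equals the end-to-end length."""
    from knotmetrics.dynamics import Ensemble
    rod = make_linear_chain(126, bond_length=1.0)
    ens = Ensemble([rod, rod], SimulationParams(), ForceField())
    lp = persistence_length(ens)
    assert lp["lp_sigma"] == pytest.approx(125.0)
    assert lp["lp_nm"] == pytest.approx(125.0 * 2.8)


def test_persistence_length_rejects_rings(trefoil_ensemble):
    with pytest.raises(ValueError, match="open chains"):
        persistence_length(trefoil_ensemble)


def test_phantom_chain_bend_statistics_match_boltzmann():
    """Phantom semiflexible chain: <cos theta> = coth(k/T) - T/k exactly
    (consecutive bond directions form a Markov chain on the sphere)."""
    from knotmetrics.dynamics import block_stderr
    for k_bend in (1.0, 5.0):
        chain = make_linear_chain(64)
        ff = ForceField(k_bend=k_bend, pair_style="none")
        state, _, _, _, vel = run_md(chain, ff, temperature=1.0, dt=0.006,
                                     gamma=1.0, n_steps=50_000, stride=50_000,
                                     seed=21)
        _, traj, _, _, _ = run_md(state, ff, temperature=1.0, dt=0.006,
                                  gamma=1.0, n_steps=800_000, stride=400,
                                  seed=22, velocities=vel)
        bonds = traj[:, 1:] - traj[:, :-1]
        bonds /= np.linalg.norm(bonds, axis=-1, keepdims=True)
        cos = np.einsum("fij,fij->fi", bonds[:, :-1], bonds[:, 1:])
        expected = 1.0 / math.tanh(k_bend) - 1.0 / k_bend
        se = block_stderr(cos.mean(axis=1), 12)
        assert abs(cos.mean() - expected) < max(3 * se, 0.005)


def test_persistence_length_increases_with_stiffness():
    """l_p strictly increasing in k_bend (short runs: ordering only)."""
    lps = []
    for k_bend in (1.0, 5.0, 20.0):
        params = SimulationParams(n_equil_steps=50_000, n_prod_steps=200_000,
                                  sample_stride=500, seed=31)
        ens = sample_ensemble(make_linear_chain(64), ForceField(k_bend=k_bend),
                              params)
        lps.append(persistence_length(ens)["lp_sigma"])
    assert lps[0] < lps[1] < lps[2]


def test_canonical_unknot_is_planar_circle_and_sets_reference_energy():
    """Charging + relaxation drives the unknot to a planar circle, whose
    Coulomb energy is the normalizer E_0; the canonical trefoil lies above."""
    ff = ForceField(k_bend=1.0)
    ring, e0 = make_canonical_knot(make_tabulated_knot("0_1", 63), ff)
    s = gyration_tensor(ring)
    lam = s.eigenvalues
    assert lam[1] / lam[2] == pytest.approx(1.0, abs=1e-3)   # circular
    assert lam[0] / lam[2] < 1e-3                            # planar
    tref, ec3 = make_canonical_knot(make_tabulated_knot("3_1", 63), ff)
    assert ec3 > e0
    assert knot_determinant(tref) == 3
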