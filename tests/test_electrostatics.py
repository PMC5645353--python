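"""Capacity estimators, transport relations, and polarizability."""

import math

import numpy as np
import pytest

from knotmetrics.electrostatics import (BeadModel, ElectrostaticResult,
                                        capacity_mom, capacity_walk,
                                        coulomb_energy_of,
                                        polarizability_mom,
                                        solid_sphere_model,
                                        transport_from_capacity)


def unit_sphere():
    return BeadModel(np.zeros((1, 3)), 1.0)


def test_sphere_capacity_equals_radius():
    r = capacity_walk(unit_sphere(), n_walks=200_000, seed=1)
    assert abs(r.capacity - 1.0) < 3 * r.capacity_stderr
    assert capacity_mom(unit_sphere()) == pytest.approx(1.0)
    assert capacity_mom(BeadModel(np.zeros((1, 3)), 0.37)) == pytest.approx(0.37)


def test_coincident_spheres_are_idempotent():
    two = BeadModel(np.zeros((2, 3)), 1.0)
    r = capacity_walk(two, n_walks=100_000, seed=2)
    assert abs(r.capacity - 1.0) < 3 * r.capacity_stderr
    with pytest.warns(UserWarning, match="duplicate"):
        assert capacity_mom(two) == pytest.approx(1.0)


def test_two_distant_spheres_capacities_add():
    far = BeadModel(np.array([[0.0, 0, 0], [1e5, 0, 0]]), 1.0)
    assert capacity_mom(far) == pytest.approx(2.0, rel=1e-4)


def test_prolate_spheroid_closed_form():
    """Bead-shell prolate spheroid (a=2, b=c=1) vs the analytic capacity
    C = sqrt(a^2-b^2)/arccosh(a/b)."""
    a, b = 2.0, 1.0
    analytic = math.sqrt(a**2 - b**2) / math.acosh(a / b)
    # densify a spheroidal shell with small beads just inside the surface
    rb = 0.08
    n = 4000
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    t = 1.0 - 2.0 * (i + 0.5) / n
    st = np.sqrt(1.0 - t * t)
    pts = np.stack([(a - rb) * t, (b - rb) * st * np.cos(phi),
                    (b - rb) * st * np.sin(phi)], axis=1)
    r = capacity_walk(BeadModel(pts, rb), n_walks=150_000, seed=3)
    assert r.capacity == pytest.approx(analytic, rel=0.03)


def test_capacity_scales_linearly_with_dilation(random_coil_fixtures):
    m = BeadModel(random_coil_fixtures[0].positions, 0.5)
    big = BeadModel(random_coil_fixtures[0].positions * 2.5, 1.25)
    assert capacity_mom(big) == pytest.approx(2.5 * capacity_mom(m), rel=1e-9)


def test_walk_and_mom_agree_on_bead_chains(random_coil_fixtures):
    """Cross-validation of the two capacity routes on random ring
    fixtures.  The walk is unbiased; the point-charge discretization of
    the Kelvin principle carries a known bias that grows as the body gets
    small and blobby (~2% for chains of >= 24 beads, ~6% for 10-bead
    rings), so the band is 3 MC standard errors plus that discretization
    allowance."""
    for cfg in random_coil_fixtures:
        model = BeadModel.from_configuration(cfg)
        mom = capacity_mom(model)
        walk = capacity_walk(model, n_walks=20_000, seed=17)
        disc = 0.06 * mom if cfg.n_beads <= 16 else 0.02 * mom
        assert abs(walk.capacity - mom) < 3 * walk.capacity_stderr + disc


def test_coulomb_energy_convention():
    assert coulomb_energy_of(1.0) == 0.5
    assert coulomb_energy_of(2.0) == 0.25
    assert coulomb_energy_of(1e12) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        coulomb_energy_of(0.0)
    r = ElectrostaticResult(capacity=3.7, capacity_stderr=0.01, n_walks=1000)
    assert r.coulomb_energy * r.capacity == pytest.approx(0.5)


def test_transport_relations():
    t = transport_from_capacity(1.0, eta=1.0)
    assert t.friction == pytest.approx(6 * math.pi)
    assert t.mobility == pytest.approx(1.0 / (6 * math.pi))
    assert t.mobility * t.friction == pytest.approx(1.0)
    assert t.hydrodynamic_radius == 1.0
    assert transport_from_capacity(2.0).mobility == \
        pytest.approx(0.5 * t.mobility)


def test_walk_input_validation():
    with pytest.raises(ValueError):
        capacity_walk(unit_sphere(), n_walks=10)
    with pytest.raises(ValueError):
        BeadModel(np.zeros((0, 3)))


def test_polarizability_sphere_isotropic_and_exact():
    alpha = polarizability_mom(unit_sphere())
    assert np.allclose(alpha, np.eye(3))      # alpha = a^3 for a sphere
    w = np.linalg.eigvalsh(alpha)
    assert w[2] / w[0] == pytest.approx(1.0)


def test_polarizability_rod_largest_along_axis():
    pts = np.stack([np.arange(16.0), np.zeros(16), np.zeros(16)], axis=1)
    alpha = polarizability_mom(BeadModel(pts, 0.5))
    w, v = np.linalg.eigh(alpha)
    assert w[2] > 5 * w[1]
    assert abs(v[:, 2] @ np.array([1.0, 0, 0])) > 0.999


def test_solid_sphere_fixture_capacity_near_one():
    r = capacity_walk(solid_sphere_model(), n_walks=100_000, seed=5)
    assert r.capacity == pytest.approx(1.0, abs=0.02)
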