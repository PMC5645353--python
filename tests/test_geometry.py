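"""Knot generators, resampling, and the topology certificate."""

import math

import numpy as np
import pytest

from knotmetrics import (RingConfiguration, canonicalize,
                         knot_determinant, make_circle, make_linear_chain,
                         make_tabulated_knot, make_torus_knot,
                         resample_closed_curve)
from knotmetrics.crossings import acn_gauss_integral, project_and_count
from knotmetrics.geometry import _min_nonadjacent_distance

# determinants computed from projected diagrams by this package's own
# Fox-coloring construction, cross-checked against the torus/twist-knot
# closed forms (q for (2,q) torus; 2n+1 for n half-twists)
KNOWN_DETERMINANTS = {"0_1": 1, "3_1": 3, "4_1": 5, "5_1": 5,
                      "5_2": 7, "6_1": 9, "7_1": 7, "8_1": 13}


@pytest.mark.parametrize("label,det", sorted(KNOWN_DETERMINANTS.items()))
def test_tabulated_knots_carry_their_determinant(label, det):
    cfg = make_tabulated_knot(label, 126)
    assert cfg.closed and cfg.n_beads == 126
    assert knot_determinant(cfg) == det


@pytest.mark.parametrize("label", ["3_1", "5_2"])
def test_determinant_is_direction_independent(label, rng):
    cfg = make_tabulated_knot(label, 63)
    dets = {knot_determinant(cfg, direction=d)
            for d in rng.standard_normal((6, 3))}
    assert dets == {KNOWN_DETERMINANTS[label]}


def test_determinant_distinguishes_unknot_trefoil_figure_eight():
    dets = {lbl: knot_determinant(make_tabulated_knot(lbl, 63))
            for lbl in ("0_1", "3_1", "4_1")}
    assert len(set(dets.values())) == 3


def test_torus_knot_validation_errors():
    with pytest.raises(ValueError, match="torus"):
        make_torus_knot(2, 4, 126)        # gcd != 1
    with pytest.raises(ValueError, match="too small"):
        make_torus_knot(2, 7, 12)
    with pytest.raises(ValueError, match="[Uu]nknown knot"):
        make_tabulated_knot("9_42", 126)


def test_unknot_circle_has_no_crossings_along_normal():
    cfg = make_torus_knot(1, 1, 63)
    assert knot_determinant(cfg) == 1
    circle = make_circle(63)
    assert project_and_count(circle, [0.0, 0.0, 1.0]) == 0
    assert acn_gauss_integral(circle) == 0.0


def test_trefoil_acn_exceeds_minimal_crossing_number():
    cfg = make_torus_knot(2, 3, 126)
    assert acn_gauss_integral(cfg) >= 3.0
    # every generic projection of a trefoil shows at least 3 crossings
    assert project_and_count(cfg, [0.3, 0.5, 0.81]) >= 3


def test_bond_lengths_uniform_after_generation_and_resampling():
    for label in ("3_1", "5_2", "8_1"):
        cfg = make_tabulated_knot(label, 126)
        b = cfg.bond_lengths()
        assert b.max() / b.min() <= 1.001
        assert b.mean() == pytest.approx(0.97, rel=1e-6)


def test_resample_circle_gives_exact_bonds():
    t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
    radius = 126.0 / (2 * np.pi)
    pts = np.stack([radius * np.cos(t), radius * np.sin(t), 0 * t], axis=1)
    cfg = resample_closed_curve(pts, 126)
    bonds = cfg.bond_lengths()
    assert bonds.max() / bonds.min() <= 1.000002
    assert bonds.mean() == pytest.approx(
        2 * radius * math.sin(math.pi / 126), abs=1e-4)


def test_resample_identity_and_topology_preservation():
    tref = make_tabulated_knot("3_1", 126)
    same = resample_closed_curve(tref.positions, 126, "3_1")
    # identity up to start-point phase / canonical rigid motion
    assert np.allclose(np.sort(same.bond_lengths()),
                       np.sort(tref.bond_lengths()), atol=1e-5)
    down = resample_closed_curve(tref.positions, 63, "3_1")
    assert knot_determinant(down) == 3


def test_resample_too_coarse_raises():
    tref = make_tabulated_knot("3_1", 126)
    with pytest.raises(ValueError, match="too coarse"):
        resample_closed_curve(tref.positions, 6, "3_1")
    with pytest.raises(ValueError, match="at least 3"):
        resample_closed_curve(tref.positions, 2, "3_1")


def test_generated_knots_are_self_avoiding():
    for label in ("4_1", "6_1", "8_1"):
        cfg = make_tabulated_knot(label, 126)
        assert _min_nonadjacent_distance(cfg.positions) > 0.5


def test_linear_chain_geometry():
    chain = make_linear_chain(126, bond_length=1.0)
    assert not chain.closed
    assert chain.n_bonds == 125
    assert np.linalg.norm(chain.positions[-1] - chain.positions[0]) == \
        pytest.approx(125.0)
    two = make_linear_chain(2, bond_length=0.97)
    assert two.bond_lengths() == pytest.approx([0.97])
    # dsDNA mapping: 63 beads x 2.8 nm
    assert make_linear_chain(63).contour_length_nm == pytest.approx(176.4)


def test_canonicalize_is_rigid_motion_standardization(rng):
    cfg = make_tabulated_knot("5_1", 63)
    # random rotation + translation
    q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = RingConfiguration(cfg.positions @ q.T + rng.standard_normal(3),
                              True, "5_1")
    back = canonicalize(moved)
    assert np.allclose(back.positions.mean(axis=0), 0.0, atol=1e-10)
    assert back.positions[0, 1] == pytest.approx(0.0, abs=1e-9)
    assert back.positions[0, 2] == pytest.approx(0.0, abs=1e-9)
    # invariant scalars unchanged
    assert acn_gauss_integral(back) == pytest.approx(acn_gauss_integral(cfg),
                                                     abs=1e-9)
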