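"""Synthetic knotted-ring and linear-chain generators.

All configurations live in reduced units: the bead diameter sigma is the
unit of length (physically sigma = 2.8 nm, the effective diameter of
double-stranded DNA at ~1 M NaCl).  A ring is an ordered, closed polygon of
bead centers; a linear chain is an open polygon.  Knot types are named with
Alexander-Briggs labels ("3_1", "4_1", ...).

Supported knot family: 0_1, 3_1, 4_1, 5_1, 5_2, 6_1, 7_1, 8_1.  The
(2,q)-torus knots (3_1, 5_1, 7_1) come from an explicit torus curve; the
twist knots (4_1, 5_2, 6_1, 8_1) are built from rational-tangle closures,
see :mod:`knotmetrics.tangles`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

SIGMA_NM = 2.8
"""Physical bead diameter in nanometres (dsDNA mapping)."""

DEFAULT_BOND = 0.97
"""Default bond length in sigma units, near the FENE+WCA minimum."""

SUPPORTED_KNOTS = ("0_1", "3_1", "4_1", "5_1", "5_2", "6_1", "7_1", "8_1")

#: minimal crossing number encoded in the Alexander-Briggs label
MINIMAL_CROSSINGS = {k: int(k.split("_")[0]) for k in SUPPORTED_KNOTS}

# (p, q) torus-curve representatives for the torus members of the family
_TORUS_KNOTS = {"0_1": (1, 1), "3_1": (2, 3), "5_1": (2, 5), "7_1": (2, 7)}

# half-twist counts for the twist-knot members (determinant = 2 n + 1)
_TWIST_KNOTS = {"4_1": 2, "5_2": 3, "6_1": 4, "8_1": 6}


@dataclass
class RingConfiguration:
    """One polymer configuration: ordered bead centers of a closed ring
    (or open chain, for the linear reference system)."""

    positions: np.ndarray          # (N, 3) float, reduced sigma units
    closed: bool = True
    knot_label: str = "0_1"

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.n_beads if self.closed else self.n_beads - 1

    def bond_vectors(self) -> np.ndarray:
        p = self.positions
        if self.closed:
            return np.roll(p, -1, axis=0) - p
        return p[1:] - p[:-1]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)

    @property
    def contour_length(self) -> float:
        """Contour length in reduced units (sum of bond lengths)."""
        return float(self.bond_lengths().sum())

    @property
    def contour_length_nm(self) -> float:
        """Nominal contour length N x sigma in nm (bead-count convention)."""
        return self.n_beads * SIGMA_NM

    def copy(self) -> "RingConfiguration":
        return RingConfiguration(self.positions.copy(), self.closed, self.knot_label)


def canonicalize(config: RingConfiguration) -> RingConfiguration:
    """Return a rigid-motion-standardized copy: centroid at the origin and
    the first bead on the +x axis.  Used to make generator output
    reproducible; all downstream observables are rigid-motion invariant."""
    p = config.positions - config.positions.mean(axis=0)
    v = p[0]
    nv = np.linalg.norm(v)
    if nv > 1e-12:
        a = v / nv
        b = np.array([1.0, 0.0, 0.0])
        axis = np.cross(a, b)
        s = np.linalg.norm(axis)
        c = float(a @ b)
        if s > 1e-12:
            axis = axis / s
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + math.sin(math.atan2(s, c)) * K + (1 - c) * (K @ K)
            p = p @ R.T
        elif c < 0:  # antiparallel: rotate pi about z
            p = p * np.array([-1.0, -1.0, 1.0])
    return RingConfiguration(p, config.closed, config.knot_label)


def _equal_arclength_resample(points: np.ndarray, n_beads: int) -> np.ndarray:
    """Resample a closed polygon at n_beads equally spaced arc-length
    positions (piecewise-linear interpolation along the input polygon)."""
    pts = np.asarray(points, dtype=float)
    seg = np.roll(pts, -1, axis=0) - pts
    ell = np.linalg.norm(seg, axis=1)
    keep = ell > 1e-12          # drop exactly duplicated vertices
    pts, seg, ell = pts[keep], seg[keep], ell[keep]
    cum = np.concatenate([[0.0], np.cumsum(ell)])
    total = cum[-1]
    targets = np.arange(n_beads) * (total / n_beads)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(ell) - 1)
    frac = (targets - cum[idx]) / ell[idx]
    return pts[idx] + frac[:, None] * seg[idx]


def _equal_chord_resample(dense: np.ndarray, n_beads: int,
                          max_iter: int = 600, rtol: float = 1e-6) -> np.ndarray:
    """Place n_beads points on the closed polyline ``dense`` so that all
    successive chords (bonds) have equal length.

    A damped fixed-point iteration redistributes the points' arc-length
    parameters in proportion to the accumulated chord length; if it stalls
    (strongly curved coarse polygons), a least-squares polish on the
    parameters finishes the job.  The first point stays at the start of the
    input polyline.
    """
    pts = np.asarray(dense, dtype=float)
    seg = np.roll(pts, -1, axis=0) - pts
    ell = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(ell)])
    total = cum[-1]

    def interp(s: np.ndarray) -> np.ndarray:
        s = np.mod(s, total)
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(ell) - 1)
        frac = (s - cum[idx]) / ell[idx]
        return pts[idx] + frac[:, None] * seg[idx]

    def chords_of(s: np.ndarray) -> np.ndarray:
        p = interp(s)
        return np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)

    s = np.arange(n_beads) * (total / n_beads)
    for _ in range(max_iter):
        chords = chords_of(s)
        if chords.max() / chords.min() - 1.0 < rtol:
            return interp(s)
        u = np.concatenate([[0.0], np.cumsum(chords)])
        s_knots = np.concatenate([s, [total]])
        targets = np.arange(n_beads) * (u[-1] / n_beads)
        s = 0.5 * s + 0.5 * np.interp(targets, u, s_knots)

    from scipy.optimize import least_squares

    def resid(free: np.ndarray) -> np.ndarray:
        ss = np.concatenate([[s[0]], free])
        c = chords_of(ss)
        return c - c.mean()

    sol = least_squares(resid, s[1:], xtol=1e-14, ftol=1e-14, gtol=1e-14)
    s_fin = np.concatenate([[s[0]], sol.x])
    c = chords_of(s_fin)
    if c.max() / c.min() - 1.0 > 1e-3:
        raise ValueError("resolution too coarse")
    return interp(s_fin)


def resample_closed_curve(points: np.ndarray, n_beads: int,
                          knot_label: str = "0_1",
                          min_separation: float = 0.5) -> RingConfiguration:
    """Resample a closed polygon to ``n_beads`` beads with uniform bond
    (chord) lengths, the beads lying on the input polygon.

    Raises ``ValueError("resolution too coarse")`` if non-adjacent segments
    of the resampled polygon approach closer than ``min_separation`` (same
    length units as the input; 0.5 sigma by default), which would risk a
    change of topology when the polygon is used as a tube of radius
    sigma/2.
    """
    if n_beads < 3:
        raise ValueError("a closed curve needs at least 3 beads")
    dense = _equal_arclength_resample(points, max(20 * n_beads, 1000))
    out = _equal_chord_resample(dense, n_beads)
    cfg = RingConfiguration(out, closed=True, knot_label=knot_label)
    if _min_segment_distance(out) < min_separation:
        raise ValueError("resolution too coarse")
    return canonicalize(cfg)


def _min_nonadjacent_distance(pts: np.ndarray) -> float:
    """Minimum bead-bead distance over pairs separated by >= 2 along the
    closed chain."""
    n = len(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    i, j = np.triu_indices(n, k=2)
    mask = ~((i == 0) & (j == n - 1))
    return float(d[i[mask], j[mask]].min())


def _min_segment_distance(pts: np.ndarray) -> float:
    """Minimum 3-D distance between non-adjacent segments of the closed
    polygon (tube-overlap guard for resampling)."""
    n = len(pts)
    a0 = pts
    a1 = np.roll(pts, -1, axis=0)
    i, j = np.triu_indices(n, k=2)
    keep = ~((i == 0) & (j == n - 1))
    i, j = i[keep], j[keep]
    p, u = a0[i], a1[i] - a0[i]
    q, v = a0[j], a1[j] - a0[j]
    w = p - q
    a = np.einsum("ij,ij->i", u, u)
    b = np.einsum("ij,ij->i", u, v)
    c = np.einsum("ij,ij->i", v, v)
    d = np.einsum("ij,ij->i", u, w)
    e = np.einsum("ij,ij->i", v, w)
    den = a * c - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(den > 1e-12, (b * e - c * d) / den, 0.0)
        t = np.where(den > 1e-12, (a * e - b * d) / den, 0.0)
    s = np.clip(s, 0.0, 1.0)
    # re-project t for clamped s, then clamp and re-project s once more
    t = np.clip((e + s * b) / np.where(c > 1e-300, c, 1.0), 0.0, 1.0)
    s = np.clip((-d + t * b) / np.where(a > 1e-300, a, 1.0), 0.0, 1.0)
    diff = w + s[:, None] * u - t[:, None] * v
    return float(np.linalg.norm(diff, axis=1).min())


def _rescale_to_bond(cfg: RingConfiguration, bond_length: float) -> RingConfiguration:
    scale = bond_length / cfg.bond_lengths().mean()
    return RingConfiguration(cfg.positions * scale, cfg.closed, cfg.knot_label)


def make_torus_knot(p: int, q: int, n_beads: int,
                    major_radius: float = 2.0, minor_radius: float = 1.0,
                    bond_length: float = DEFAULT_BOND) -> RingConfiguration:
    """Closed (p, q) torus curve resampled to ``n_beads`` beads.

    The curve winds p times around the torus axis and q times around the
    tube; for coprime p, q > 1 it realizes the (p, q) torus knot, and for
    p = 1 or q = 1 the unknot.  The output is rescaled so that the mean
    bond length equals ``bond_length``.
    """
    if p < 1 or q < 1:
        raise ValueError("winding numbers must be positive")
    if math.gcd(p, q) != 1:
        raise ValueError("not a torus knot: gcd(p, q) must be 1")
    crossing_number = 0 if min(p, q) == 1 else min(p * (q - 1), q * (p - 1))
    if n_beads < max(3, 3 * crossing_number):
        raise ValueError(
            f"n_beads={n_beads} too small to resolve a ({p},{q}) torus knot")
    if minor_radius >= major_radius:
        raise ValueError("minor_radius must be smaller than major_radius")
    # oversample, then resample at uniform arc length
    t = np.linspace(0.0, 2.0 * np.pi, 40 * n_beads, endpoint=False)
    rad = major_radius + minor_radius * np.cos(q * t)
    pts = np.stack([rad * np.cos(p * t), rad * np.sin(p * t),
                    minor_radius * np.sin(q * t)], axis=1)
    label = next((k for k, v in _TORUS_KNOTS.items()
                  if v in ((p, q), (q, p))), f"torus_{p}_{q}")
    if min(p, q) == 1:
        label = "0_1"
    cfg = resample_closed_curve(pts, n_beads, knot_label=label,
                                min_separation=0.0)
    cfg = _rescale_to_bond(cfg, bond_length)
    if _min_nonadjacent_distance(cfg.positions) < 0.5 * bond_length:
        raise ValueError("resolution too coarse")
    return cfg


def make_tabulated_knot(label: str, n_beads: int,
                        bond_length: float = DEFAULT_BOND) -> RingConfiguration:
    """Representative of any supported knot type, resampled to ``n_beads``.

    Torus members use :func:`make_torus_knot`; twist members are generated
    from rational-tangle closures and carry a determinant certificate.
    """
    if label not in SUPPORTED_KNOTS:
        raise ValueError(
            f"unknown knot label {label!r}; supported: {', '.join(SUPPORTED_KNOTS)}")
    if label == "0_1":
        return make_circle(n_beads, bond_length=bond_length)
    if label in _TORUS_KNOTS:
        p, q = _TORUS_KNOTS[label]
        return make_torus_knot(p, q, n_beads, bond_length=bond_length)
    from .tangles import twist_knot_polygon
    pts = twist_knot_polygon(_TWIST_KNOTS[label])
    cfg = resample_closed_curve(pts, n_beads, knot_label=label,
                                min_separation=0.0)
    cfg = _rescale_to_bond(cfg, bond_length)
    if _min_nonadjacent_distance(cfg.positions) < 0.5 * bond_length:
        raise ValueError("resolution too coarse")
    return cfg


def make_circle(n_beads: int,
                bond_length: float = DEFAULT_BOND) -> RingConfiguration:
    """Planar regular n-gon (unknot) with the requested bond length."""
    if n_beads < 3:
        raise ValueError("a closed curve needs at least 3 beads")
    radius = bond_length / (2.0 * math.sin(math.pi / n_beads))
    t = 2.0 * math.pi * np.arange(n_beads) / n_beads
    pts = np.stack([radius * np.cos(t), radius * np.sin(t),
                    np.zeros(n_beads)], axis=1)
    return RingConfiguration(pts, closed=True, knot_label="0_1")


def make_linear_chain(n_beads: int,
                      bond_length: float = DEFAULT_BOND) -> RingConfiguration:
    """Straight open chain along the x axis (linear reference topology)."""
    if n_beads < 2:
        raise ValueError("a chain needs at least 2 beads")
    x = np.arange(n_beads, dtype=float) * bond_length
    pts = np.stack([x, np.zeros(n_beads), np.zeros(n_beads)], axis=1)
    pts -= pts.mean(axis=0)
    return RingConfiguration(pts, closed=False, knot_label="linear")
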