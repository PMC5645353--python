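"""Topology certificate: the knot determinant |Delta(-1)| from a diagram.

A generic projection of the closed bead polygon yields a regular knot
diagram (transversal double points with over/under information).  From the
diagram we build the Fox-coloring relation matrix -- one relation
``2 x_over - x_under_in - x_under_out = 0`` per crossing -- and the knot
determinant is the absolute value of any maximal minor, evaluated in exact
integer arithmetic.  The determinant is a knot invariant, so it is constant
under resampling and under any dynamics that cannot pass the chain through
itself; that is exactly the property the simulator tests assert.

Values for the supported family (computed by this module, not assumed):
unknot 1, 3_1 -> 3, 4_1 -> 5, 5_1 -> 5, 5_2 -> 7, 6_1 -> 9, 7_1 -> 7,
8_1 -> 13.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RingConfiguration


class DegenerateProjection(Exception):
    """The projection direction produced a non-regular diagram."""


@dataclass
class Crossing:
    """One transversal double point of a projected diagram.

    ``over_param``/``under_param`` are positions along the closed chain in
    units of segments (segment index plus fractional position)."""
    over_param: float
    under_param: float


def _projection_frame(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return np.stack([e1, e2, d])  # rows: in-plane x, in-plane y, depth


def projected_crossings(positions: np.ndarray, direction: np.ndarray,
                        closed: bool = True, tol: float = 1e-9) -> list[Crossing]:
    """All transversal crossings of the polygon projected along ``direction``.

    Adjacent segments (sharing a bead; including the first/last pair of a
    closed chain) are excluded.  Raises :class:`DegenerateProjection` when
    two segments are near-parallel and near-touching in projection, when an
    intersection falls within ``tol`` of a segment endpoint, or when the two
    depths at a crossing coincide -- callers should jitter the direction and
    retry (see :func:`knot_determinant`).
    """
    frame = _projection_frame(direction)
    pts = np.asarray(positions, dtype=float) @ frame.T
    xy, z = pts[:, :2], pts[:, 2]
    n = len(pts)
    n_seg = n if closed else n - 1
    nxt = (np.arange(n_seg) + 1) % n
    d2 = xy[nxt] - xy[:n_seg]
    i, j = np.triu_indices(n_seg, k=2)
    if closed:
        keep = ~((i == 0) & (j == n_seg - 1))
        i, j = i[keep], j[keep]
    ri = xy[j] - xy[i]
    def cross2(a, b):
        return a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]

    den = cross2(d2[i], d2[j])
    num_s = cross2(ri, d2[j])
    num_t = cross2(ri, d2[i])
    scale = np.linalg.norm(d2[i], axis=1) * np.linalg.norm(d2[j], axis=1)
    parallel = np.abs(den) < 1e-12 * np.maximum(scale, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(parallel, np.nan, num_s / den)
        t = np.where(parallel, np.nan, num_t / den)
    # parallel segments whose projections pass very close are degenerate
    if np.any(parallel):
        for k in np.flatnonzero(parallel):
            if _segments_close_2d(xy[i[k]], xy[nxt[i[k]]],
                                  xy[j[k]], xy[nxt[j[k]]], tol=1e-7):
                raise DegenerateProjection("parallel overlapping segments")
    hit = (s > -tol) & (s < 1 + tol) & (t > -tol) & (t < 1 + tol)
    crossings: list[Crossing] = []
    margin = 1e-7
    for k in np.flatnonzero(hit):
        sk, tk = float(s[k]), float(t[k])
        if min(sk, tk, 1 - sk, 1 - tk) < margin:
            raise DegenerateProjection("crossing at a segment endpoint")
        zi = z[i[k]] + sk * (z[nxt[i[k]]] - z[i[k]])
        zj = z[j[k]] + tk * (z[nxt[j[k]]] - z[j[k]])
        if abs(zi - zj) < 1e-9:
            raise DegenerateProjection("equal depths at a crossing")
        pi, pj = i[k] + sk, j[k] + tk
        if zi > zj:
            crossings.append(Crossing(over_param=pi, under_param=pj))
        else:
            crossings.append(Crossing(over_param=pj, under_param=pi))
    return crossings


def _segments_close_2d(a0, a1, b0, b1, tol: float) -> bool:
    for p, q0, q1 in ((a0, b0, b1), (a1, b0, b1), (b0, a0, a1), (b1, a0, a1)):
        d = q1 - q0
        L2 = float(d @ d)
        u = 0.0 if L2 == 0 else float(np.clip((p - q0) @ d / L2, 0.0, 1.0))
        if np.linalg.norm(p - (q0 + u * d)) < tol:
            return True
    return False


def _bareiss_det(mat: list[list[int]]) -> int:
    """Fraction-free exact determinant of an integer matrix."""
    m = [row[:] for row in mat]
    n = len(m)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for k in range(n - 1):
        if m[k][k] == 0:
            swap = next((r for r in range(k + 1, n) if m[r][k] != 0), None)
            if swap is None:
                return 0
            m[k], m[swap] = m[swap], m[k]
            sign = -sign
        for r in range(k + 1, n):
            for c in range(k + 1, n):
                m[r][c] = (m[r][c] * m[k][k] - m[r][k] * m[k][c]) // prev
        prev = m[k][k]
    return sign * m[n - 1][n - 1]


def determinant_from_crossings(crossings: list[Crossing]) -> int:
    """Knot determinant from a regular diagram's crossing list."""
    nc = len(crossings)
    if nc == 0:
        return 1
    unders = sorted(c.under_param for c in crossings)
    # arc r runs from under-passage r to under-passage r+1 (cyclically)
    def arc_of(param: float) -> int:
        k = int(np.searchsorted(unders, param, side="right")) - 1
        return k % nc
    mat = [[0] * nc for _ in range(nc)]
    for row, c in enumerate(crossings):
        k = unders.index(c.under_param)
        mat[row][arc_of(c.over_param)] += 2
        mat[row][(k - 1) % nc] -= 1
        mat[row][k] -= 1
    minor = [row[:-1] for row in mat[:-1]]
    return abs(_bareiss_det(minor))


def knot_determinant(config: RingConfiguration | np.ndarray,
                     direction: np.ndarray | None = None,
                     seed: int | None = 0, max_retries: int = 50) -> int:
    """Knot determinant of a closed configuration from a generic projection.

    A fixed direction may be supplied; degenerate projections are retried
    with a small random jitter (documented behavior -- never silently
    skipped).  The result is independent of the direction for any regular
    diagram, which the test suite exercises.
    """
    pos = config.positions if isinstance(config, RingConfiguration) else np.asarray(config)
    if isinstance(config, RingConfiguration) and not config.closed:
        raise ValueError("knot determinant is defined for closed chains only")
    rng = np.random.default_rng(seed)
    d = np.asarray(direction, dtype=float) if direction is not None \
        else np.array([0.317, 0.539, 0.782])
    for _ in range(max_retries):
        try:
            return determinant_from_crossings(
                projected_crossings(pos, d, closed=True))
        except DegenerateProjection:
            d = d + 1e-5 * rng.standard_normal(3)
    raise DegenerateProjection("no regular projection found after jitter retries")
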