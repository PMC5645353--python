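"""Rational-tangle construction of twist-knot polygons.

The twist knots 4_1, 5_2, 6_1, 8_1 (determinants 5, 7, 9, 13) are the
two-bridge knots with fractions (2n+1)/n for n = 2, 3, 4, 6 half-twists.
They are built here as the closure of a rational tangle: starting from the
zero tangle (two parallel strands), ``n`` twists are applied to the east
pair of endpoints and two twists to the south pair, and the result is
closed with simple arcs.  Crossings are realized in 3D by routing the
over-strand at z = +h and the under-strand at z = -h; everything else lies
in the z = 0 plane, so the projection along z is the standard twist-knot
diagram.

The construction is certified by the knot determinant: the expected values
2n+1 are asserted by the test suite, and a wrong relative handedness of the
two twist regions would instead produce the (smaller) determinants 2n-1.
"""

from __future__ import annotations

import numpy as np

_H = 0.8  # z-offset of over/under passes


class _Tangle:
    """Two open strands with named endpoints NW, NE, SW, SE."""

    def __init__(self) -> None:
        self.strands: list[list[np.ndarray]] = [
            [np.array([0.0, 1.0, 0.0]), np.array([1.0, 1.0, 0.0])],
            [np.array([0.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0])],
        ]
        # port -> (strand index, end): end 0 is the head, -1 the tail
        self.ports = {"NW": (0, 0), "NE": (0, -1), "SW": (1, 0), "SE": (1, -1)}

    def _pos(self, port: str) -> np.ndarray:
        s, e = self.ports[port]
        return self.strands[s][e]

    def _append(self, port: str, point) -> None:
        s, e = self.ports[port]
        p = np.asarray(point, dtype=float)
        if e == 0:
            self.strands[s].insert(0, p)
        else:
            self.strands[s].append(p)

    def twist_east(self, sign: int = 1) -> None:
        """Cross the NE and SE endpoints once (one half-twist)."""
        p_ne, p_se = self._pos("NE"), self._pos("SE")
        x0 = max(p_ne[0], p_se[0]) + 0.5
        y_top, y_bot = p_ne[1], p_se[1]
        y_mid = 0.5 * (y_top + y_bot)
        self._append("NE", (x0, y_top, 0.0))
        self._append("SE", (x0, y_bot, 0.0))
        z = _H if sign > 0 else -_H
        self._append("NE", (x0 + 0.5, y_mid, z))
        self._append("NE", (x0 + 1.0, y_bot, 0.0))
        self._append("SE", (x0 + 0.5, y_mid, -z))
        self._append("SE", (x0 + 1.0, y_top, 0.0))
        self.ports["NE"], self.ports["SE"] = self.ports["SE"], self.ports["NE"]

    def twist_south(self, sign: int = 1) -> None:
        """Cross the SW and SE endpoints once (one half-twist)."""
        p_sw, p_se = self._pos("SW"), self._pos("SE")
        y0 = min(p_sw[1], p_se[1]) - 0.5
        x_w, x_e = p_sw[0], p_se[0]
        x_mid = 0.5 * (x_w + x_e)
        self._append("SW", (x_w, y0, 0.0))
        self._append("SE", (x_e, y0, 0.0))
        z = _H if sign > 0 else -_H
        self._append("SW", (x_mid, y0 - 0.5, z))
        self._append("SW", (x_e, y0 - 1.0, 0.0))
        self._append("SE", (x_mid, y0 - 0.5, -z))
        self._append("SE", (x_w, y0 - 1.0, 0.0))
        self.ports["SW"], self.ports["SE"] = self.ports["SE"], self.ports["SW"]

    def numerator_closure(self, mode: str = "numerator") -> np.ndarray:
        """Close the tangle with two crossing-free arcs and return one
        closed polygon.  ``numerator`` joins NW-NE above and SW-SE below;
        ``denominator`` joins NW-SW on the west and NE-SE on the east."""
        pts_all = np.concatenate([np.asarray(s) for s in self.strands])
        arcs = {}
        if mode == "numerator":
            y_hi = pts_all[:, 1].max() + 1.0
            y_lo = pts_all[:, 1].min() - 1.0
            pairs = (("NW", "NE", y_hi), ("SW", "SE", y_lo))
            for a, b, y in pairs:
                pa, pb = self._pos(a), self._pos(b)
                via = [np.array([pa[0], y, 0.0]), np.array([pb[0], y, 0.0])]
                arcs[a] = (b, via)
                arcs[b] = (a, [v for v in reversed(via)])
        else:
            x_lo = pts_all[:, 0].min() - 1.0
            x_hi = pts_all[:, 0].max() + 1.0
            for a, b, x in (("NW", "SW", x_lo), ("NE", "SE", x_hi)):
                pa, pb = self._pos(a), self._pos(b)
                via = [np.array([x, pa[1], 0.0]), np.array([x, pb[1], 0.0])]
                arcs[a] = (b, via)
                arcs[b] = (a, [v for v in reversed(via)])
        partner_end = {}  # port -> port at the other end of the same strand
        for p1 in self.ports:
            for p2 in self.ports:
                if p1 != p2 and self.ports[p1][0] == self.ports[p2][0]:
                    partner_end[p1] = p2
        loop: list[np.ndarray] = []
        start = "NW"
        port = start
        visited = set()
        while True:
            s, e = self.ports[port]
            if s in visited:
                raise ValueError("tangle closure produced a link, not a knot")
            visited.add(s)
            pts = self.strands[s] if e == 0 else list(reversed(self.strands[s]))
            loop.extend(pts)
            exit_port = partner_end[port]
            nxt, via = arcs[exit_port]
            loop.extend(via)
            port = nxt
            if port == start:
                break
        if len(visited) != len(self.strands):
            raise ValueError("tangle closure produced a link, not a knot")
        return np.asarray(loop)


def _densify(pts: np.ndarray, max_edge: float) -> np.ndarray:
    out = []
    n = len(pts)
    for i in range(n):
        a, b = pts[i], pts[(i + 1) % n]
        k = max(1, int(np.ceil(np.linalg.norm(b - a) / max_edge)))
        for j in range(k):
            out.append(a + (b - a) * (j / k))
    return np.asarray(out)


def _chaikin(pts: np.ndarray, rounds: int) -> np.ndarray:
    """Closed-curve corner-cutting subdivision.  Each round replaces every
    edge by its 1/4 and 3/4 points; displacements are bounded by a quarter
    of the local edge length, so after densification the curve moves far
    less than the tangle's self-clearance and the knot type is preserved
    (certified by the determinant in the callers' tests)."""
    p = np.asarray(pts, dtype=float)
    for _ in range(rounds):
        q = np.roll(p, -1, axis=0)
        new = np.empty((2 * len(p), 3))
        new[0::2] = 0.75 * p + 0.25 * q
        new[1::2] = 0.25 * p + 0.75 * q
        p = new
    return p


def twist_knot_polygon(n_half_twists: int) -> np.ndarray:
    """Closed polygon realizing the twist knot with ``n_half_twists`` twists
    plus a clasp (n=2 -> 4_1, 3 -> 5_2, 4 -> 6_1, 6 -> 8_1)."""
    if n_half_twists < 1:
        raise ValueError("need at least one half-twist")
    t = _Tangle()
    for _ in range(n_half_twists):
        t.twist_east(sign=1)
    for _ in range(2):
        t.twist_south(sign=1)
    raw = t.numerator_closure(mode="denominator")
    return _chaikin(_densify(raw, 0.3), rounds=3)
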