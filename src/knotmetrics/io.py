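"""XYZ trajectory I/O with JSON metadata in the comment line."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import RingConfiguration


def write_xyz(path, configs, metadata: dict | None = None) -> None:
    """Write configurations as multi-frame XYZ; the comment line carries a
    JSON object with knot_label, closed, and any extra metadata."""
    if isinstance(configs, RingConfiguration):
        configs = [configs]
    with open(path, "w") as fh:
        for cfg in configs:
            meta = {"knot_label": cfg.knot_label, "closed": cfg.closed}
            if metadata:
                meta.update(metadata)
            fh.write(f"{cfg.n_beads}\n{json.dumps(meta)}\n")
            for x, y, z in cfg.positions:
                fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> list[RingConfiguration]:
    """Read a (multi-frame) XYZ file written by :func:`write_xyz`; plain
    XYZ comment lines are tolerated (defaults: closed ring, unknot)."""
    out = []
    lines = Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].split()[0])
        try:
            meta = json.loads(lines[k + 1])
        except (json.JSONDecodeError, IndexError):
            meta = {}
        pos = np.array([[float(v) for v in lines[k + 2 + i].split()[1:4]]
                        for i in range(n)])
        out.append(RingConfiguration(pos, meta.get("closed", True),
                                     meta.get("knot_label", "0_1")))
        k += 2 + n
    return out
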