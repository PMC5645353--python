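"""Bead-spring force field in reduced Lennard-Jones units.

Interactions (all energies in epsilon, lengths in sigma):

* excluded volume: WCA, the purely repulsive LJ truncated at 2^(1/6) sigma
  and shifted up by epsilon so it vanishes continuously at the cutoff;
  optionally the full (attractive) LJ truncated and shifted at 2.5 sigma,
  used for poor-solvent temperature scans;
* connectivity: FENE springs, k = 30 eps/sigma^2, R0 = 1.5 sigma -- the
  Kremer-Grest combination that makes chain crossing energetically
  prohibitive and thereby conserves knot topology;
* stiffness: U_bend = k_bend (1 - cos theta), theta the deviation from
  collinearity of adjacent bonds (straight chain = minimum);
* optional bead charges: truncated Coulomb Z^2/r for r <= 4 sigma, used
  only for generating canonical (minimum Coulomb energy) knots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceField:
    epsilon: float = 1.0
    sigma: float = 1.0
    k_fene: float = 30.0
    r0: float = 1.5
    k_bend: float = 1.0
    z_charge: float = 0.0
    coulomb_cutoff: float = 4.0
    pair_style: str = "wca"      # "wca", "lj" (poor solvent), "none" (phantom)
    lj_cutoff: float = 2.5
    sigma_nm: float = 2.8

    def __post_init__(self) -> None:
        for name in ("epsilon", "sigma", "k_fene", "r0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_bend < 0 or self.z_charge < 0:
            raise ValueError("k_bend and z_charge must be non-negative")
        if self.coulomb_cutoff < WCA_CUTOFF * self.sigma:
            raise ValueError("coulomb_cutoff must be >= 2^(1/6) sigma")
        if self.pair_style not in ("wca", "lj", "none"):
            raise ValueError("pair_style must be 'wca', 'lj', or 'none'")

    def with_charge(self, z: float) -> "ForceField":
        return replace(self, z_charge=z)


def wca_pair_energy(r: float, epsilon: float = 1.0, sigma: float = 1.0) -> float:
    """Weeks-Chandler-Andersen pair energy: shifted LJ for r <= 2^(1/6)
    sigma, exactly zero beyond (continuous at the cutoff)."""
    if r <= 0:
        raise ValueError("overlapping beads: r must be positive")
    if r > WCA_CUTOFF * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6) + epsilon


def lj_pair_energy(r: float, epsilon: float = 1.0, sigma: float = 1.0,
                   cutoff: float = 2.5) -> float:
    """Truncated-and-shifted Lennard-Jones pair energy (attractive well)."""
    if r <= 0:
        raise ValueError("overlapping beads: r must be positive")
    if r > cutoff * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    src6 = (1.0 / cutoff) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6) - 4.0 * epsilon * (src6 * src6 - src6)


def fene_bond_energy(r: float, k: float = 30.0, r0: float = 1.5) -> float:
    """FENE spring energy -(k R0^2 / 2) ln(1 - (r/R0)^2); diverges at R0."""
    if r < 0:
        raise ValueError("r must be non-negative")
    if r >= r0:
        raise ValueError("bond overstretched: r >= R0")
    return -0.5 * k * r0 * r0 * math.log(1.0 - (r / r0) ** 2)


def bend_energy(theta: float, k_bend: float = 1.0) -> float:
    """Bending energy k_bend (1 - cos theta), theta in [0, pi] the deviation
    of adjacent bonds from collinearity (0 = straight chain)."""
    return k_bend * (1.0 - math.cos(theta))


def coulomb_pair_energy(r: float, z: float) -> float:
    """Truncated (unshifted) Coulomb repulsion Z^2/r for r <= 4 sigma."""
    if r <= 0:
        raise ValueError("overlapping beads: r must be positive")
    if r > 4.0:
        return 0.0
    return z * z / r
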