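# Methods

`knotmetrics` quantifies the complexity of knotted ring polymers — modeled
on knotted double-stranded DNA — through electrostatic energy functionals,
crossing statistics, and hydrodynamic size measures.  This note records the
models, the numerical choices, and what the synthetic ensembles do and do
not emulate.

## The polymer model

Rings and linear chains are Kremer–Grest bead–spring polymers in reduced
Lennard-Jones units (bead mass m = 1, energy ε = 1, length σ = 1, time
σ√(m/ε)).  The physical mapping is σ = 2.8 nm, the effective diameter of
dsDNA in ≈1 M NaCl, so an N-bead chain has contour length N × 2.8 nm
(e.g. 126 beads → 352.8 nm).

Interactions:

* **Excluded volume** — WCA (purely repulsive LJ, cut at 2^(1/6) σ and
  shifted by ε).  An attractive option (full LJ, truncated and shifted at
  2.5 σ) is provided for poor-solvent temperature scans, where collapse at
  low T is the phenomenon of interest; with a purely repulsive potential
  temperature only rescales the stiffness and no collapse occurs.
  A `none` style (phantom chain: excluded volume only between bonded
  neighbors, to keep bonds in their usual minimum) exists solely for
  validation against exactly solvable statistics.
* **Connectivity** — FENE springs, k = 30 ε/σ², R₀ = 1.5 σ.  Combined with
  WCA, bond extension beyond ~1.2 σ is energetically prohibitive, so chains
  cannot pass through themselves and knot topology is conserved; the
  integrator aborts if a bond ever reaches R₀.
* **Stiffness** — U_bend = k_bend (1 − cos θ) with θ the deviation of
  adjacent bonds from collinearity (the straight chain is the minimum;
  this is the convention under which persistence length grows with
  k_bend).  k_bend ∈ {1, 3, 5, 10, 20} ε spans l_p ≈ 5.8–50.2 nm for
  linear chains.
* **Charges** (canonical knots only) — truncated, unshifted Coulomb
  repulsion Z²/r for r ≤ 4 σ.  The small discontinuity at the cutoff is
  irrelevant for the quasi-static minimization it is used in.

## Sampling

Dynamics are BAOAB Langevin with friction γ = 1 and time step
δt = 0.006 σ√(m/ε).  Ensemble averages of configurational observables are
thermostat-independent, so Langevin is interchangeable with any other NVT
thermostat here.  With γ = 0 the scheme reduces exactly to velocity
Verlet; the test suite verifies energy conservation (drift < 10⁻³ relative
over 10⁴ steps), equipartition, the Boltzmann statistics of bond lengths
and bending angles against quadrature/closed-form oracles, and per-frame
topology conservation via the knot determinant.

Full-scale study conditions are ≥10⁷ steps and 4000 configurations per
state point.  Default pipeline runs are scaled down by `scale_factor`
(default 0.05: ≥2×10⁵ production steps, ≥200 frames), which resolves the
qualitative trends.  All stochastic quantities carry block-averaged
standard errors (10–12 blocks).

One observable needs special care: the end-to-end/first-bond projection
that defines l_p.  For the stiff chain (k_bend = 20, l_p ≈ L/7) it is
dominated by the chain's slowest bending mode, which at γ = 1 is heavily
overdamped and relaxes over ~γ/(κq₁⁴) ≈ 10⁷ steps — the scale of an
entire run, so single-trajectory error bars are unreliable there.  The
persistence-length measurements therefore run near critical damping of
that mode (γ = 0.01 for k_bend = 20, γ = 0.1 for k_bend = 1), which
decorrelates the projection roughly a hundredfold faster while leaving
every configurational average unchanged (verified by cross-seed agreement
and equipartition at the reduced friction).  Equilibration is ≥5×10⁵–10⁶
steps so no memory of the straight initial chain survives; production is
4×10⁶–1.2×10⁷ steps, giving ~4–5% standard errors on l_p.

## Knot generation and the topology certificate

Initial shapes: (2,q) torus curves for 3₁, 5₁, 7₁; a planar regular
polygon for the unknot; rational-tangle closures for the twist knots 4₁,
5₂, 6₁, 8₁ (n = 2, 3, 4, 6 half-twists plus a clasp, built as explicit 3-D
polygons with over/under passes at z = ±0.8).  All raw curves are
resampled to N beads with *equal chord lengths* (max/min bond ratio ≤
1.001) by a damped redistribution iteration with a least-squares fallback,
then scaled so the mean bond is 0.97 σ, near the FENE+WCA minimum.

Topology is certified by the knot determinant |Δ(−1)|: a generic
projection gives a regular diagram, the Fox-coloring relation matrix
(2·over − under_in − under_out per crossing) is assembled, and any maximal
minor is evaluated in exact integer arithmetic (Bareiss elimination).
Degenerate projections are jittered and retried, never skipped.  The
determinants of the supported family (1, 3, 5, 5, 7, 9, 7, 13) are
*computed*, not assumed, and they distinguish every pair in the family
except 3₁/5₁-style coincidences (5 for both 4₁ and 5₁, 7 for both 5₂ and
7₁); within this generator those pairs come from different constructions,
so the certificate remains conclusive for conservation checks.  The full
Alexander polynomial is out of scope.

## Average crossing number

⟨m⟩ of a configuration is its projected crossing count averaged over
uniformly distributed directions.  Three routes:

* `gauss_integral` (default for ensembles): for a polygon, the absolute
  Gauss double integral splits into non-adjacent segment-pair terms whose
  integrand has constant sign per pair, so each term equals the absolute
  solid angle of the pair's spherical quadrilateral — evaluated in closed
  form as two van Oosterom–Strackee triangle terms.  This is deterministic
  and exact (no quadrature error); the asin-based shortcut for the
  quadrilateral area was rejected because it mis-branches for near-parallel
  near-coplanar segment pairs.
* `uniform_mc`: crossing counts over random directions (64 by default),
  with standard errors; used to cross-validate the closed form.
* `orthogonal3`: the mean of the xy/xz/yz plane counts, reproducing the
  illustrative three-plane procedure; over a thermal ensemble molecular
  tumbling supplies the angular average.

Counting conventions: the polymer is the polygon through bead centers;
adjacent segments are excluded; each crossing pair counts once; degenerate
projections are retried with a 10⁻⁵-radian seeded jitter.

## Electrostatics and transport

The conductor is the union of spheres of radius σ/2 at the bead centers.
Units: Coulomb constant = total charge = 1, so a sphere's capacity is its
radius and E_C = 1/(2C).  R_h = C, f_t = 6πηC, μ = 1/f_t.

* `capacity_walk` — walk-on-spheres: walkers launched uniformly from a
  sphere of radius 1.5× the circumscribing radius; jumps use the exact
  distance to the union near the body (uniform-grid nearest-sphere query
  for dense bodies) and safe lower bounds far from it; ε-capture shell
  10⁻⁴ σ; outside the launch sphere the walker escapes with probability
  1 − R/ρ or re-enters with the exact Poisson-kernel distribution.
  C = R_launch × P(hit), binomial standard errors.  Calibration: unit
  sphere to 0.1% at 10⁶ walks; prolate-spheroid closed form reproduced.
* `capacity_mom` — deterministic discretization of the Kelvin variational
  principle: point charges at bead centers, self-term 1/a, off-diagonal
  1/r, solved at unit potential.  It is the cross-validation oracle for
  the walk.  Its point-charge bias is ~1–2% for bead chains (N ≥ 24) and
  up to ~6% for very small blobby bodies; the cross-validation bands in
  the tests add exactly that allowance to the 3σ MC band.  The pipeline
  uses the MoM route per frame (deterministic, milliseconds) — E_C enters
  the results only through the ratio ⟨E_C⟩/E₀ computed with the same
  discretization, which cancels most of the bias.
* **Energy averaging** — ⟨E_C⟩ is the ensemble mean of 1/(2C) computed per
  configuration, never 1/(2⟨C⟩): no configurational preaveraging.
* `polarizability_mom` — charge-plus-dipole interaction model: bead
  monopoles enforce equipotentiality (charge transfer, dominant for
  chains) and bead dipoles respond with the single-sphere polarizability
  a³, making the one-bead limit exact.  Only trace *ratios* are consumed
  (g_η), so the universal [η]∝α constant is never needed.  A stochastic
  path-integral polarizability was not implemented; the deterministic
  solve serves the same interface with zero variance.

## Shape descriptors and g-ratios

The gyration tensor is the second-moment tensor about the centroid;
eigenvalues are reported ascending.  R_g² is defined as the tensor trace
(mean squared distance from the centroid) — the convention consistent with
the solid-sphere benchmark C/R_g = √(5/3) ≈ 1.29; a trace/3 variant is
exposed as an option but not used.  Degenerate fixtures (planar rings,
rods) report Λ-ratios as flagged infinities; thermal ensembles never hit
them.  g_h, g_s, g_η are ratios of ensemble means between a knotted ring
and a linear chain of the same bead count, with first-order error
propagation; the topological-polydispersity average Σ g_i(m) P(i,m) is a
direct weighted mean with a 10⁻⁸ normalization guard.

## Canonical knots

The canonical (minimum-Coulomb-energy) form is produced by ramping the
bead charge through Z = 1, 2, 4, 7, 10 with an L-BFGS energy minimization
(analytic gradients; FENE continued quadratically beyond 0.99 R₀ so line
searches stay finite) after each step, until the relative change of
E_C = 1/(2C) between rounds falls below 10⁻⁴.  The canonical unknot — a
planar circle — supplies the normalizers E₀ and μ₀ at matched (N, k_bend).
Canonical energies order strictly with knot complexity (0₁ < 3₁ < 5₁ < 7₁
at fixed N), mirroring ideal knots obtained by tube inflation.

## What the synthetic ensembles do and do not show

The generator produces exactly the model the analysis assumes: a
homopolymer of uniform thickness with fully screened electrostatics (the
thermal ensembles are uncharged).  Passing tests therefore demonstrate the
internal consistency of the model-plus-estimators and reproduce the
*trends* (E_C vs ⟨m⟩ collapse, stiffness/length/temperature dependences,
g-ratios below one and decreasing with m).  They do not probe
sequence-dependent stiffness, unscreened polyelectrolyte effects,
hydrodynamic interactions during dynamics, or melt conditions; mobilities
are Stokes–Einstein dilute-solution values, not gel-electrophoresis
mobilities.  Scaled-down sampling widens error bars but does not bias
configurational averages; all trend assertions are rank-based with
magnitudes left free.

## Known limitations

* The knot determinant cannot distinguish every knot pair (by design it is
  a conservation certificate, not an identifier).
* The point-charge MoM bias (above) is visible when compared against the
  unbiased walk at high walk counts; ratios cancel most of it.
* `capacity_mom` is limited to N ≤ 3000 (dense solve); the walk estimator
  has no such limit.
* The approximate segment-distance guard in resampling is conservative
  but not a rigorous isotopy proof; the determinant check is the final
  arbiter.
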