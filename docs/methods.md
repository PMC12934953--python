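# Methods

## Mechanical model

The nuclear envelope (NE) is treated as a single hyperelastic shell that
lumps the double lipid bilayer with the underlying lamin A/C network. The
stress-free configuration is a spherical shell of outer radius R0 = 4.1 um
and thickness 0.2 um centred at (0, 0, znuc + R0) with znuc = 1.04 um above
the pillar-top plane (z = 0; the substrate floor sits at z = -h_NP, and a
flat substrate is the degenerate case h_NP = 0). Because the nucleus sits
centred over a pillar of the square array, mirror symmetry about x = 0 and
y = 0 reduces the problem to one quadrant with the normal displacement
component fixed on each symmetry plane.

The wall is an incompressible two-term Mooney-Rivlin solid,
W = Escale (E1 (I1 - 3) + E2 (I2 - 3)) - p (J - 1) with E1 = 5000 Pa,
E2 = 1000 Pa, solved in the mixed (perturbed-Lagrangian) weak form in which
the pressure test equation reads phi0 (J - 1) + p = 0 with
phi0 = 1e8 Pa. Two consequences worth knowing:

* the unloaded reference carries the hydrostatic baseline p* = 2 E1 + 4 E2,
  so the stress-free shell relaxes in volume by exactly p*/phi0 = 1.4e-4;
  loaded solves in this package stay below the 1e-4 relative NE-volume
  deviation target;
* at the published osmotic set-point Pmax = 820 Pa the shell inflates to an
  outer radius of 5.28 um and wall thickness 0.117 um. This is confirmed to
  0.004% by an independent one-dimensional thick-sphere quadrature
  (`fixtures.balloon_oracle`), and is consistent with the published initial
  nucleoplasm volume (~152 um^3 full-domain equivalent); the other published
  post-inflation figures (5.0 um radius, 0.13 um thickness, 107.5/118.4 um^2
  areas) correspond to a lower pressure (~760 Pa) and are mutually
  inconsistent with wall incompressibility, so this package reports the
  faithful solve of the stated constitutive law and loads.

Loads are follower loads integrated on the deformed surface: the osmotic
pressure acts on the inner sphere; the actin-cap stress
sigma_cap exp((Z - (znuc + 2 R0))/Z0) acts along -z on the outer sphere
with the saturating schedule sigma_max (1 - e^{-t/t0}); the nanopillar
steric repulsion sigma_c0 exp(-(z - d_steric)/d_steric) is weighted by a
super-Gaussian pillar indicator evaluated at the deformed in-plane
position. The repulsion direction is +z by default (`contact_mode="ez"`,
matching the printed weak form); a variant along the inward deformed
normal is available but deforms the pillar rim more aggressively on coarse
meshes. Floor contact is an active-set Dirichlet condition on u_z,
re-evaluated inside every Newton iteration (nodes are pinned when they
penetrate and released when their reaction becomes adhesive). The apex
"roof" patch is pinned to the stretch-weighted average u_z of the
surrounding annulus, applied only while cap stress acts (it is a
stabilization of the flattening apex; at zero cap load it acts as a
ratchet that slowly flattens a resting sphere). The pinned value is
refreshed within the pressure-equilibration fixed point rather than once
per time step — with the published once-per-step lag, large load
increments tent the apex and produce spurious local stretch on coarse
meshes. Between inflation and the cap schedule a settle stage lets the
shell rest on the substrate with neither gauge pin, so the transport
initialization sees a genuinely stationary geometry.

During inflation the rigid vertical mode of the free shell is gauged by
pinning u_z on the equator ring, which is exact for a spherically symmetric
state and leaves the centre in place; the inflated nucleus then rests
against the substrate through the floor/pillar contact, which carries the
vertical force during cap compression (the equator pin is dropped).

The nucleoplasm is not meshed for the mechanics; its volume follows from
the divergence theorem on the deformed inner surface, and the osmotic
pressure evolves as dP <- dP - phi_inner (V - V_prev)/V (phi_inner =
100 Pa), iterated with re-solves until the pressure changes by < 1%. For
transport, the displacement is extended into the nucleoplasm by minimizing
a compressible neo-Hookean energy E1n (I1 - 3 - 2 ln J) + phin (J - 1)^2
(E1n = 5000 Pa, phin = 1e5 Pa) with the shell displacement as Dirichlet
data. The -2 ln J term is required for the reference state to be the exact
minimizer (so that zero boundary data yields zero extension); the solver
warm-starts from the previous step and falls back to adaptive continuation
in the boundary-data fraction.

## Discretization

All kernels are implemented on numpy/scipy: a structured quarter-sphere
triangulation by recursive octahedron subdivision (vertices stay exactly on
the symmetry planes), radial prism extrusion of the shell split into
conforming tetrahedra, and graded concentric layers closing the nucleoplasm
with a central cone. Shell elements are curved (isoparametric P2 geometry
with mid-edge nodes snapped to the interpolated sphere), giving closed-form
shell volume to ~1e-5 at CI resolutions. Displacements are quadratic,
pressure linear (Taylor-Hood); volume quadrature is a collapsed
Gauss-Jacobi rule exact to degree 3 (degree 5 on loaded faces). Newton uses
analytic consistent tangents for the volume terms, per-face central-difference
tangents for the (cheap) follower loads, LU reuse while the residual
contracts by at least 3x per iteration, step backtracking only on element
inversion, and automatic load-increment halving. Linear solves use SuperLU
with COLAMD ordering.

Transport uses P1 elements on the deformed vertices: the outer surface
triangulation for NPCs, the concentric inner surface (same connectivity,
inner vertices) for lamin, and the full tetrahedral mesh (nucleoplasm + NE
wall) for the phospho-lamin and nuclear YAP/TAZ pools. Each step first
applies the multiplicative dilution by the ratio of lumped measure entries
(old/new), which conserves every total to round-off, then an implicit-Euler
diffusion-reaction solve on the frozen deformed domain. Relative to the
published order (diffuse, then dilute) this differs at the splitting-error
order O(dt) and makes discrete conservation exact. The NPC pair is solved
as one coupled linear system so activation conserves the pair sum exactly;
the lamin exchange flux is applied with the inner-surface measure on both
the surface and the volume side (the printed form uses the outer measure on
the volume side, which on a curved shell leaks ~10% of the exchanged
molecules; `literal_exchange_measure=True` restores it). Tiny negative
concentrations (< 1e-10 of scale) are clipped with a counter; larger ones
abort.

## Kinetics and initialization

All kinetic constants are the published set. Two values are not part of it
and are required configuration inputs with documented, non-authoritative
defaults: the active-myosin level [M]_A = 1.5 uM and the YAP/TAZ export
rate k_out = 1.0 (count um^-2 s^-1 uM^-1). Quantitative YAP/TAZ levels
(e.g. the absolute N/C ratio) depend on these; the package's assertions
about YAP/TAZ are therefore orderings, not magnitudes.

Initialization sets every species to its uniform well-mixed steady state
computed from the post-inflation measures. The default mode ("effective")
solves the true fixed point of the cycling kinetics with the
Hill-saturated dephosphorylation rate at the mean initial F-actin level, so
the initialized system is stationary; the "literal" mode evaluates the
published closed-form rows verbatim (bare maximal rate, printed
denominator structure), which reproduces the reference lamin density
[L]_ref = 2980 um^-2 for the published geometry but is not an exact fixed
point (it relaxes by ~5% on a minute timescale).

The lamin-stiffness normalization [L]_ref is, by default, each run's own
initial steady-state lamin density (`l_ref_mode="auto"`), so every run
starts at stiffness multiplier exactly 1 and the coupling acts on lamin
redistribution and dilution during the run. This mirrors how the published
reference value equals the wild-type density of the published initial
geometry — and it is also forced by the model itself: the shell's
pressure-radius curve saturates near 890 Pa, so a shell softened to 75%
(the lamin-depleted level under an absolute normalization) has no
equilibrium at the 820 Pa osmotic set-point at all. Lamin-depleted runs
still bear higher force per lamin subunit directly through F_L =
|sigma|/[L]. A fixed absolute reference can be forced with
`l_ref_mode="fixed"`.

The F-actin field follows the cylindrical plasma-membrane model around the
nearest pillar: [F] = F0 + F1 max(top, curvature-weighted side) with the
published radius-dependent baseline (140 uM flat, 100 uM at r = 0.2 um,
120 uM at 0.5 um). The piecewise PM distances are clamped at zero: the
printed branches go negative in the physically excluded sliver below the
pillar top inside its footprint, which would otherwise blow up the
exponential.

## Problem sizes and schedules

Default test/CI runs use the level-3 octahedron mesh (~0.8 um edges, 384
shell tetrahedra, ~3.2k displacement nodes) and shortened schedules
(t0 = 100 s, t_end = 300 s, cap-stress increments of sigma_max/10); the
acceptance script uses the level-4 mesh (~0.4 um edges, ~10.4k unknowns).
These resolutions were chosen as the package's CI-scale presets; the
published simulations used ~0.1-0.15 um meshes. Resolution mainly affects
the pillar-contact region: at ~0.8 um the 0.2 um pillar is supported by a
handful of quadrature points, which exaggerates local stretch and tension
at the indentation rim and blurs the dependence of lower-NE stretch on
pillar pitch; the pitch-sweep and peak-tension comparisons are therefore
the least converged outputs at CI scale, while inflation geometry, volume
loss, conservation and all orderings are robust.

## What the tests do and do not show

The synthetic scenarios (free inflation, flat-substrate compression,
prescribed dilations/squashes, pitch sweeps at CI resolution) exercise
every code path against closed forms, an independent 1-D inflation oracle,
symbolic differentiation of the strain energy, and exact conservation
identities. They do not emulate real nuclei beyond the model's idealized
geometry: no NE wrinkling, no chromatin mechanics, no explicit LINC
complex, quasi-static mechanics only, and a well-mixed cytosol. Passing
tests therefore validate the implementation of the stated model, not the
model's biological fidelity.
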