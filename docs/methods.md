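# Methods

This note documents the models and numerical choices behind
`bilayerkit`: what each observable computes, what the synthetic
generator does and does not emulate, and where genuinely open design
choices were resolved.

## Coordinate model

All lengths are nm and times ns internally (PDB Å converted on read;
100-ps frame intervals become 0.1 ns). Only orthorhombic boxes are
accepted: the systems of interest are rectangular slabs with the
bilayer normal along Z, and silently shearing a triclinic cell would
corrupt every area metric, so triclinic input raises instead.
Coordinates are never wrapped on read — wrapping policy belongs to each
metric (the triangulation wraps XY; profiles wrap Z; vector
construction uses the minimum image). Atom roles (phosphorus, choline
nitrogen, ordered acyl carbons, water oxygen) come from a
`NamingConvention` that is data, not code; the shipped default is the
generator's generic united-atom PC naming (`P`, `N`, `C1A…C16A`,
`C1B…C16B`, `OW`). Force-field-specific namings vary between published
topology files, so they are supplied by the user as a dict/YAML map
rather than guessed.

GRO is parsed and written in-package (the format is fixed-column and
the trajectory variant is a plain concatenation of frames, which the
underlying MDAnalysis readers treat as single-frame); PDB, XTC and TRR
go through MDAnalysis.

## Area per lipid

`projected_apl` is L<sub>X</sub>·L<sub>Y</sub>/N with N the lipids per
leaflet. `apl3d` triangulates the leaflet's phosphorus XY positions
(scipy Delaunay) and sums 3-D triangle areas. Periodicity is handled by
ghost tiling: points are wrapped into the primary cell, copies from the
eight neighbouring images within a 1.5 nm margin band are appended, and
a triangle is kept iff its XY centroid lies in the half-open primary
cell — each periodic triangle class is then counted exactly once, so a
flat leaflet returns the projected area to machine precision.
Two numerical details:

- Perfect lattices are cocircular-degenerate; Delaunay tie-breaking is
  then not consistent across periodic copies and the clipped tiling can
  gap or overlap. A deterministic micro-jitter (~10⁻⁷ of the box,
  applied before tiling so the configuration stays exactly periodic)
  puts points in general position at negligible area error.
- Triangulating in XY and lifting to 3-D assumes the surface is a
  height field; it breaks for overhangs, which do not occur before
  rupture.

## Density profiles, thickness, σ_Z

Profiles recentre Z on the lipid centre of mass per frame (drift-free),
wrap into one box height, accumulate mass into 0.1-nm bins (default;
resolves ~0.5-nm headgroup peaks without noise) and normalise by bin
volume (kg/m³). The binning is conservative: the profile integral
recovers the selected mass exactly up to floating point. Thickness is
the distance between the highest local maximum on each side of the
midplane, refined by a parabolic fit through the three surrounding
bins. σ_Z is the per-leaflet variance (nm²) of phosphorus Z,
leaflet-averaged then frame-averaged; the symbol σ is sometimes used
for a standard deviation, so `as_std=True` exposes the square root, and
scan outputs record which convention was used.

## Rupture detection

Rupture is operationally water percolation: bulk water density is
estimated from the region at least 1 nm beyond the headgroup peaks, and
rupture is flagged at the first frame of the first run of ≥ 5
consecutive frames whose core water density (|z| ≤ 0.5 nm) exceeds 10%
of bulk. These thresholds are configuration, not physics — the
underlying criterion in simulation studies is visual — so every report
embeds them. Because the detector averages laterally, a cylindrical
pore of radius r registers as ρ_bulk·πr²/(L_X·L_Y): a 1-nm pore is
detectable at the 10% threshold only in cells up to ≈ 31 nm². The test
systems therefore use 32 lipids per leaflet (≈ 19.5 nm² cell), where
the constructed pore exceeds the threshold with a safe margin; for
production boxes, either the threshold or a lateral region of interest
should be adapted to the expected pore size. The detector reports a
single onset (first frame of the persistent run); it does not separate
pore nucleation from full-column completion, which in practice differ
by a frame or two.

## Order metrics

Nematic order uses the standard Q-tensor, Q = ⟨(3uuᵀ − I)/2⟩ over the
head-to-terminal chain unit vectors of one leaflet; S is the largest
eigenvalue and the director its eigenvector (sign fixed so head→tail
points toward the midplane). This needs no bilayer-normal reference and
is invariant under u → −u. Window values average per-frame Q-tensors
before a single diagonalisation (a *global* order parameter); the
per-frame S series is also exposed. The director separation
arccos|d₁·d₂| is folded to [0°, 90°]: a tilt phase (chains parallel as
lines across leaflets) gives ≈ 0°, a cross-tilt phase gives twice the
tilt angle. At finite leaflet size the separation has a sampling noise
floor of a few degrees even for a true tilt phase; no noise-corrected
estimator is attempted.

Tilt angles are measured from the +Z axis, arccos|v_z|, folded to
[0°, 90°]. "Alternate carbon" segment vectors use a stride of 2
(C_i→C_{i+2}), exposed as a parameter for sensitivity checks.

S_CD reconstructs the two C–H directions of each interior united-atom
carbon from its neighbours with ideal tetrahedral geometry: the H's lie
in the plane through the C_{n−1}/C_{n+1} bisector, perpendicular to the
C_{n−1}→C_{n+1} axis, at half the 109.47° H–C–H angle. When the two
C–C bonds are exactly collinear (the generator's idealised extended
chains) the azimuth is undetermined and the closed-form average over
the perpendicular ring is used, ⟨cos²θ⟩ = (1 − u_z²)/2; this reproduces
−0.5 for a Z-aligned chain and +0.25 for an in-plane chain, the same
limits as the explicit tetrahedral construction.

## Orientational ACF

f(δt) is the rank-1 correlator ⟨n̂(t)·n̂(t+δt)⟩ over all segment vectors
and sliding time origins (default every frame); vectors are
re-normalised per frame. The rank-2 (P₂) variant sits behind a flag.
For free isotropic rotational diffusion f decays as exp(−2·D_r·δt);
`AcfSeries.decay_rate` fits −ln f through the origin over the lags with
f above 0.2 (the initial exponential regime). Lags run at the frame
spacing with no logarithmic thinning.

## Curvature

The leaflet surface is phosphorus Z binned onto a periodic n_x × n_y
grid (default 24 × 24, ≈ 0.35-nm cells for a 256-lipid box — resolves
box-wavelength undulations without overfitting single-lipid
protrusions); empty cells are filled by periodic inverse-distance
interpolation, and more than half-empty grids are rejected as too fine.
Periodic Gaussian smoothing is available but off by default: the
surface-fit accuracy target (error < A/50 at 16 cells per wavelength)
is unattainable with even 1-cell smoothing, whose attenuation of a
16-cell sinusoid is already ~7%; smoothing is for noisy production
data, enabled explicitly. Mean curvature uses the full
first-fundamental-form expression with periodic central differences
(post-transition slopes are O(1), so the small-slope Laplacian is not
adequate). Under this formula a crest bulging toward +Z has H < 0; the
three-class map therefore labels top-leaflet cells convex where
H ≤ −h₀, concave where H ≥ +h₀ and flat otherwise (mirrored for the
bottom leaflet), with h₀ = 0.05 nm⁻¹ by default and always recorded in
outputs.

## Pressure scans, transitions, hysteresis

Each scan point computes A_XY_PL (mean ± sd over its analysis window),
3D-APL, σ_Z, S, director separation and optionally the rupture report.
Equilibration windows are either fixed (drop the first N ns — typical
protocols discard 30–50 ns below the transition and ≥ 500 ns above) or
automatic (earliest start from which the reverse cumulative mean of a
metric varies less than a tolerance; a window must retain at least two
samples). Transition detection is deliberately parameter-light: the
adjacent-pressure interval with the largest absolute metric difference
is a transition iff it exceeds 5× the median of the other differences.
A single-jump outlier rule matches the phenomenology (one sharp drop on
an otherwise near-linear background) and has zero false positives on
exactly linear scans by construction. Hysteresis is the difference of
forward and reverse transition-interval midpoints; if either branch has
no transition the branches are compared pointwise and the maximum
deviation reported (the reversible, no-hysteresis case). Branch
direction is explicit in the configuration — the tool never infers it
from file order. Reports embed all thresholds and a config hash and are
byte-deterministic for fixed inputs and seeds.

## Synthetic generator

The generator emulates the study conditions of a fully hydrated
DPPC-like bilayer: 128 lipids per leaflet at 0.61 nm² projected APL,
3.8-nm headgroup separation, two 16-carbon chains per lipid, 30 waters
per lipid, frames every 0.1 ns. Headgroups sit on a jittered lattice at
±separation/2; undulation is a single sinusoid z += A·sin(2πx/λ)
applied to both leaflets in phase (a bending mode, X-only, keeping the
analytic oracles one-dimensional; λ must divide the box length).
Chains are extended rods along the tilt direction so the
head-to-terminal vector equals the imposed direction exactly;
orientational noise is an axial wrapped-Gaussian polar kick with
concentration κ (∞ aligned, 0 isotropic), seed-stable. Water is placed
on a bulk-density lattice (33.37 nm⁻³) in flat slabs with no
excluded-volume relaxation — the metrics under test need densities, not
packing realism. A pore is a central Z cylinder: the lipids inside are
deleted and the core filled with lattice water; the rupture trajectory
variant keeps a uniform atom set by parking the column water in the
bulk until the onset frame.

Rotational diffusion evolves each chain direction as a random walk on
the sphere with two independent transverse angular components of
variance 2·D_r·Δt per frame — the discretisation of isotropic
rotational diffusion, whose rank-1 correlation is exp(−2·D_r·δt). An
optional reflecting cone about each chain's initial direction produces
the confined-diffusion ACF plateau.

The pressure-scan builder imposes a linear structural response with a
sharp transition: projected APL 0.61 nm² at 1 bar falling at
1.5·10⁻³ nm²/bar, a 0.10 nm² drop at the transition (then
0.5·10⁻³ nm²/bar), σ_Z growing linearly with pressure (0.02 nm² at
0 bar, 5·10⁻⁵ nm²/bar), and amplitude 1 nm at full box wavelength once
undulated — magnitudes chosen to match the observed behaviour of a
256-DPPC slab between −200 and +150 bar in 10-bar steps.

What the generator does **not** emulate: thermal chain conformations
(gauche defects), capillary-wave spectra beyond the single sinusoid,
ripple-phase ordered/disordered domain mixtures, lipid flip-flop,
electrostatics or any force field. Passing tests therefore demonstrate
that the estimators recover known geometry and dynamics exactly; they
do not certify behaviour on thermally rough surfaces beyond what the
jittered and undulated constructions cover.

## Problem sizes in tests and acceptance

Oracle checks use the smallest systems with sampling error comfortably
inside each tolerance: 256–8192 lipids for area/σ_Z lattices (variance
estimates need ~10³–10⁴ headgroups for percent-level agreement), 10⁴
vectors × 500 frames for ACF recovery, 2·10⁵ segment samples for the
isotropic S_CD null, 100 randomized scans per detector calibration,
and 32 lipids per leaflet for pore detection (see the rupture section).
The full suite runs in a few minutes on one CPU.

## Known limitations

- Leaflet assignment assumes an intact or moderately undulated bilayer;
  it is not meaningful mid-rupture, and flip-flop is not tracked.
- The XY-projected triangulation and the height-field curvature grid
  both assume no overhangs.
- The transition detector assumes a uniform pressure grid and at most
  one jump per branch.
- The equilibration auto-rule is a stationarity heuristic on one
  metric, not a statistical equilibration test.
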