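# Methods

This note documents the physical model, the calibration of the default
mixture properties, the numerical choices, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Physical model

A cell of radius *a*, density ρ_p and compressibility κ_p in a liquid
(ρ₀, κ₀, η) inside a 1-D standing pressure wave experiences the
time-averaged radiation force

F(y) = 4π Φ k_y a³ E_ac sin(2 k_y y),
Φ = (1 − κ̃)/3 + (ρ̃ − 1)/(2ρ̃ + 1),

with y measured from the left wall and the pressure node at y = W/2
(k_y = π/W nominally; a fitted k_y can be supplied). Balancing against
Stokes drag gives the transverse velocity u(y) = u₀ + F/(6πηa), where u₀
is a constant bulk offset representing the fitted remnant of
boundary-driven streaming/drift. Streaming is otherwise not modeled: in the
stratified system the stabilizing acoustic force density dominates the
streaming stress by orders of magnitude, and for zero-contrast cells in
homogeneous media (where streaming *does* dominate) the synthetic generator
substitutes a toy vortex (sinusoidal oscillation), which is all the
stop-flow classifier needs.

The cell's **effective acoustic impedance** Z_cell is defined as the
impedance of the medium in which its contrast vanishes (the zero-contrast
definition). Because Z_med(c) is strictly increasing and Φ is strictly
decreasing in concentration for a fixed particle, Φ(c) has at most one
root: the iso-acoustic concentration, and through the gradient, the
iso-acoustic point. `CellModel.from_impedance` prescribes (Z_cell, ρ_p)
and solves κ_p from monopole/dipole cancellation at the root; Z_cell, not
the individual (ρ_p, κ_p), controls the equilibrium position. The
alternative definition √(ρ_p/κ_p) is available via
`ParticleProperties.acoustic_impedance`; the two differ at the percent
level for cell-like property mismatches.

## Default mixture model and its calibration

Concentration is the OptiPrep percentage scale (60 % iodixanol = undiluted
stock). Defaults, all overridable through `MixtureModel` /
`media_model` config:

- density and sound speed: quadratics in concentration pinned exactly at
  three points — diluent (DPBS + 2 % FBS: ρ = 1005 kg m⁻³, c₀ = 1500 m s⁻¹),
  stock (ρ = 1320 kg m⁻³, c₀ = 1620 m s⁻¹), and a calibrated 10 % point;
- viscosity: linear, η(0) = 1.0 mPa s, η(10 %) = 1.3 mPa s.

The 10 % point is fixed by two measured anchors simultaneously: the
polystyrene tracer bead (a = 2.23 µm, ρ = 1050 kg m⁻³,
κ = 1.65 × 10⁻¹⁰ Pa⁻¹) must have contrast factor Φ = 0.199, and
ρ₀c₀² must equal p_a²/(4E_ac) for the calibrated pair
(0.39 MPa, 16.27 J m⁻³). These two conditions jointly determine both
ρ₀(10 %) = 1068.3 kg m⁻³ and κ₀(10 %) = 4.279 × 10⁻¹⁰ Pa⁻¹, which is why
the mixing rule is quadratic rather than linear: a linear density rule
between the chosen endpoints cannot pass through the calibrated point. The
resulting Z(c) is strictly increasing over 0–60 % (verified on a 0.1 %
grid). The diluent/stock sound speeds are plausible bench values chosen
once; they set the curve far from the calibrated region and matter little
for the 10–36 % window the measurements use. Note the two printed
high-voltage field values (43 J m⁻³, 0.66 MPa) imply a slightly different
ρ₀c₀² than the calibrated pair; the model follows the calibrated pair, so
it reproduces 0.66 MPa only to ≈4 %.

The intensity→impedance conversion uses a degree-2 polynomial fitted to
the model's Z(c) over the gradient's span (RMS residual < 0.001 MPa s m⁻¹
over 10–36 %), mirroring the experimental calibration against standard
solutions.

## Gradient dynamics and stabilization

The cross-channel profile starts as a plug-flow top-hat (central band width
(Q_c/Q_tot)·W) and diffuses with no-flux walls. The solver expands the
profile in a cosine (DCT-II) basis on a 512-point cell-centered grid and
damps each mode by exp(−D k_n² t): unconditionally stable, mass-conserving
to round-off, and exactly semigroup. Because evolution is a modal damping,
c(y, t) during trajectory integration is evaluated exactly in time (no
operator-splitting error). The maximum principle holds up to spectral
truncation of the initial discontinuity, which is negligible once the
diffusion width exceeds the grid spacing (≈ milliseconds here).

Downstream position maps to diffusion time by plug flow, t = W·H·x/Q_tot,
neglecting the Poiseuille profile and depth dependence; this matches the
time-scale framing of the experiments (5.6 s at 12 µl min⁻¹, 52 s at
1.3 µl min⁻¹ to the 20 mm imaging region) but under-resolves axial
dispersion.

Gravitational stabilization is evaluated, not simulated: the margin
E_ac/(Δρ·g·H) uses the density span of the profile and the full channel
depth as the hydrostatic scale. Margin > 1 means stabilized; a collapsed
state is only flagged. For the 10 %/30 % lamination at 15 J m⁻³ the margin
is ≈ 90.

Diffusivities: iodixanol 2.5 × 10⁻¹⁰, 3 kDa dextran tracer
2.2 × 10⁻¹⁰ m² s⁻¹; the profiles differ by < 3 % of the step for all
times up to 60 s, which is what justifies the fluorescent tracer as a
proxy for the iodixanol field.

## Trajectories and populations

dy/dt = u(y, t) is integrated with an adaptive Runge–Kutta method
(rtol 10⁻⁷, atol 10⁻¹¹ m); whole populations integrate as one vectorized
system (the cells are independent, so a shared adaptive step is safe), with
a per-cell fallback if the batch solve fails. Walls stall the dynamics
(the force vanishes at the antinodes); cells within 2ε_y of a wall or the
centerline are reported censored ("wall"/"center"), with ε_y = W/200 by
default. Trajectories are 1-D in y: sedimentation and axial flow profiles
are out of scope. Time-to-IAP is the first time after which the track stays
within ε_y of its final position.

Converged populations read back slightly compressed: a cell tracks its
moving iso-acoustic contour with a lag that scales inversely with E_ac, so
the 5–95 % spread approaches the true population spread from below as the
energy grows. This is why, above the stabilization energy (≈11 J m⁻³
analogue), the spread is flat only within the method's accuracy scale
(≈0.005 MPa s m⁻¹) rather than strictly decreasing.

## Stop-flow classification

Rules in priority order on tracks of ≥ 20 frames: zero (starts away from
center and walls, and either the velocity reverses with the weaker
directional extreme > 20 % of the stronger, or the cell crosses the central
region without stopping), then positive (ends in the central band), then
negative (ends within the wall margin), else unknown. The qualitative
"central region" and "near a wall" are parameterized as the middle 20 % of
the width and 10 % wall margins. Velocities are central finite differences;
for the reversal test they pass through a 5-frame median filter and the
endpoint-contaminated samples (one-sided differences carry twice the noise,
and the filter smears them one half-width inward) are excluded — without
this, tracking noise on the wall plateau of slow negative-contrast tracks
masquerades as reversal. "Does not stop" means the exit speed from the
central band exceeds 10 % of the track's maximum speed.

## Image-based inference

r = (I − I_bg)/(I_max − I_bg) cancels global camera gain/offset; pixels
with reference−background below 10 % of the median are masked, r is clipped
to [0, 1] and a clip rate above 5 % raises a data-quality warning. The
column profile averages r along the flow direction. Cell detection
(the localization procedure is this package's own: Gaussian blur, Otsu
threshold, connected components, intensity-weighted centroids, minimum-area
and eccentricity filters) reaches sub-half-pixel accuracy at SNR ≈ 10;
regions much larger than a supplied typical single-cell area are flagged as
possible merges. Concentration is linear in r between the side (10 %) and
central (36 %) media; impedance comes from the calibration polynomial.
Cells within 5 % of the width of a wall or the centerline are censored —
their impedance lies outside the gradient's measurable span and the value
is only a bound.

## Synthetic data

Generators are pure functions of (spec, seed). Populations draw Z_cell and
radius from truncated normals (defaults: BA-F3-like 1.68 ± 0.014 MPa s m⁻¹,
a = 4 µm; MCF7-like 1.5× the radius with a lower impedance, 1.63 MPa s m⁻¹,
chosen within the measured ordering since no number is published) and start
uniformly in the two side-inlet bands. Stop-flow templates are simulated
trajectories in homogeneous 10 %/25 % media at 30 frames / 3 Hz; the
template field (43 J m⁻³) is chosen so every start position completes its
migration within the 30-frame window. Rendered images map the tracer ratio
affinely to intensity with additive Gaussian noise and Gaussian-spot cells
(≤ 6 per frame).

Not emulated: photon shot statistics and bleaching, optical aberrations and
flat-field structure, cell-shape variability, tracking errors beyond
additive position noise, axial dispersion, and cell–cell interactions.
Passing tests therefore demonstrate the correctness and internal
consistency of the analysis chain under the stated model, not robustness to
every artifact of real microscopy data.

## Problem sizes used in tests and the acceptance script

End-to-end round trips use 1450-cell populations (matching the reference
experiment's n) on the 512-point gradient grid; equilibrium-property sweeps
use 150-cell populations with common random numbers across conditions,
which isolates the physics from sampling noise; the PIV Monte-Carlo uses
100 replicates of 200 samples; classifier robustness uses 500 noisy
replicates of 20 templates. These sizes give stable statistics while
keeping every check fast.

## Known limitations

- The mixture polynomials extrapolate outside the calibrated 10 % point and
  the 10–36 % measurement window on plausibility, not measurement.
- The hydrostatic stability criterion is an order-of-magnitude inequality;
  collapse dynamics are not modeled.
- The effective-impedance description compresses a cell's interior
  heterogeneity into one scalar; deformation, lift and inter-cell
  hydrodynamics are ignored.
- The voltage→energy inversion assumes penetration is monotone in energy
  and the bead never saturates at the node; saturated observations are
  rejected rather than used.
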