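# Methods

This note documents the models, estimators and numerical choices behind
`ciliaflow`, in the order the pipeline runs them: video-derived beat
metrics, bead tracking, the envelope flow model, and the profile fit that
yields the shear-stress efficiency index.

## Coordinate and unit conventions

Image coordinates are micrometres with the origin at the top-left pixel
corner, x along columns and y along rows (downward); the centre of pixel
(row r, col c) is at ((c + 0.5)p, (r + 0.5)p) for pixel size p. The flow
model uses wall coordinates: x along the ciliated edge, y the distance
above it. Internally everything is μm–s–Pa·s; velocities are μm/s and
stresses are reported in mPa.

## Ciliary beat metrics

**CBF.** Two estimators operate on the grey level sampled (bilinearly)
along the operator's 5-point edge line. (1) FFT: the mean grey level of
the line per frame is detrended and the power-spectrum argmax inside a
physiological search band (default 0.5–30 Hz, below all Table-range beat
frequencies' harmonics and above drift) is returned; resolution is
frame_rate/n_frames (≈ 0.20 Hz at 1800 frames / 358 fps). A peak is only
accepted if it exceeds 10× the in-band median power, otherwise the movie
has "no dominant frequency". (2) Video-kymography: the line is resampled
at one-pixel curvilinear steps into a T×S image; each column's temporal
autocorrelation (FFT-based, zero-padded to 2T) is averaged across columns,
and the beating period is the base lag of the peak comb. The lag of the
highest-order visible peak divided by its order, with 3-point parabolic
interpolation, gives sub-frame precision (a single-peak readout is
quantized to ±0.5 frame, which at 14 Hz would already exceed one FFT bin).

**CBA.** From the clicked points P0 (cilium base) and P1/P2 (tip before
the effective and recovery strokes): CBA = |P1P2|. The cilium length is
taken as the mean of |P0P1| and |P0P2| (the two tip excursions are both
anchored at the base; no formula is canonical here). Coincident tips give
CBA = 0 with a warning rather than an error — a real degenerate beat.

**Metachronal wavelength.** 104 segments of 24 pixels, perpendicular to
the wall and centred on it, are spread uniformly along the polyline. Each
segment's mean grey level is Fourier-transformed and the phase at the CBF
bin extracted; phases are 1-D unwrapped along the curvilinear abscissa
before the least-squares line θ(x) = p·x + c, and λ = 2π/|p| (using |p|
makes the estimate invariant under reversal of the segment ordering).
The fit is rejected ("wavelength not measurable") when R² < 0.7 — an
uncoordinated edge — or when λ would exceed 10 edge lengths, the
practical in-phase limit.

**Cilia density.** ρc is the fraction of cilia-zone pixels of the
*time-averaged* movie strictly darker than the mean grey of a disjoint
background zone (each zone ≥ 100 px). Averaging over frames removes the
beat oscillation so the measure reflects coverage, not phase. For a
homogeneous cilia array of diameter e_c = 0.2 μm this is e_c/(e_c + d_c),
giving the inter-cilia distance d_c = e_c(1 − ρc)/ρc (undefined, NaN, at
ρc = 0) and the uncovered fraction f_c = 1 − ρc. The estimator is
invariant under any affine rescaling of the grey levels applied to both
zones.

## Bead tracking

Beads are darker than the background. Segmentation thresholds each frame
(fixed operator threshold, Otsu fallback), labels 8-connected components
and keeps those with area inside gates defaulting to 4–64 μm² (a 4.5 μm
bead covers ≈ 15.9 μm²). Components touching the image border are dropped:
a clipped disc biases its centroid inward. Centroids are darkness-weighted
(darkness relative to the frame median grey) over the component dilated by
one pixel, so the anti-aliased rim contributes; on rendered discs this is
accurate to ≈ 0.015 px where a binary centroid wanders by ≈ 0.07 px.

Linking is greedy gated nearest-neighbour: candidate (track, detection)
pairs in order of increasing distance, accepted while below the gate
(default 3 μm — beads move ≲ 0.7 μm/frame at 358 fps, so the gate makes
assignments essentially unambiguous). Ties break deterministically on the
lowest detection index after canonical (x, y) sorting, which also makes
linking invariant to detector output order. No gap closing: a missed
detection ends the track. Tracks shorter than 10 frames are dropped.

Kinematics: forward-difference velocities, decomposed along the tangent
and normal of the edge segment nearest each step midpoint; distances are
point-to-segment minima over the four segments. The reported mean speed
V_b is the norm of the mean velocity vector (equals net displacement over
elapsed time for uniformly sampled tracks; unlike the mean of |u| it does
not rectify centroid jitter into spurious speed). The per-bead distance
y0 is the time-mean distance. Selection filters mirror the physical
assumptions of the flow model: straightness — the fraction of positional
variance along the principal axis — at least 0.9 (1.0 is a perfect line,
0.5 an isotropic cloud), and |mean u_perp| ≤ 0.25 |mean u_par| (beads with
a larger wall-normal drift are not markers of the wall-parallel flow).

## Envelope flow model

Discrete cilia are replaced by an undulating material surface over the
cilia tips. The tip anchored at abscissa ξ follows the elliptic orbit
X = ξ − a·cos(ωt − σkξ), Y = βa·sin(ωt − σkξ), with CBA = 2a, β the
signed ellipse ratio (+: clockwise orbit; default 0.14, a typical
observed value), ω = 2π·CBF, k = 2π/λ, and σ = ±1 the metachronal travel
direction (default +1, wave towards +x; the lab-frame sign of the induced
transport is a convention, and effective velocities are reported as
crossing speeds |L_w/τ|).

The fluid obeys incompressible Stokes flow in a channel 0 ≤ y ≤ h with a
stagnant lid: u = 0 at y = h. The parameter h cannot be predicted from
wall quantities — it summarises the confinement by the surrounding medium
— and is measured as the x-intercept of the fitted profile. At the wall
the envelope velocity enters through a Navier slip condition
u − ϕ∂u/∂y = u_wall applied on the mean line y = 0, the classical
swimming-sheet linearization. The slip length ϕ models the partial
momentum transfer of a porous (non-continuous) cilia cover and is tied to
the density by ϕ = Λ(1 − ρc)²/ρc with Λ = 750 μm: full cover means
no-slip, sparse cilia approach free slip.

Beads are treated as massless tracers: for a 4.5 μm polystyrene bead in
water at ~10 Hz the Stokes number (2/9)R²ρ_bω/μ ≈ 10⁻⁴, so bead inertia
is negligible and trajectories integrate dX/dt = u(X, t).

**Solution structure.** The wall data is a single travelling harmonic, so
the oscillatory field is exact: a biharmonic stream-function mode
f(y)e^{i(ωt−σkx)} with (d²/dy² − k²)²f = 0, written in the scaled basis
(A + By/h)e^{−ky} + (C + Dy/h)e^{−k(h−y)} whose 4×4 boundary system stays
O(1) for kh ≫ 1 (the naive e^{±ky} basis overflows: kh ≈ 42 for λ = 13,
h = 87.5). This wave-locked part decays over λ/2π ≈ 2 μm and has zero
time average. The transport observed over many beat cycles is the
second-order steady streaming: time-averaging the Taylor expansion of the
envelope condition off the mean line yields an effective steady slip
velocity U_s = (aσk/2)·Im f′(0) + (βa/2)·Im f″(0). The steady mean flow
driven by U_s must carry zero velocity *and* zero shear into the stagnant
fluid at y = h; with the uniform pressure gradient of the closed
observation cell this forces the exact parabola ū(y) = U_w(1 − y/h)² with
U_w = U_s·h/(h + 2ϕ) — whose wall shear is 2μU_w/h, the factor 2 of the
efficiency index. Boundary residuals are measured against the full
imposed wall data (envelope velocity + U_s) and are at machine precision;
the field is divergence-free by construction. A steady solve for uniform
wall velocity (`solve_steady_uniform`, finite differences) exists as an
independently checkable limit.

Tracer advection uses adaptive explicit Runge–Kutta (RK45, rtol 10⁻⁸,
atol 10⁻¹⁰) from (0, y₀) until |x| = L_w (default 81.92 μm, the recorded
field of view), with events for wall/lid exit and a time cap (default
2000 s) that flags stalled tracers. V_eff(y₀) = L_w/τ(y₀) then contains
both the steady parabola and the near-wall Stokes drift of the
oscillatory part, and its parabolic fit recovers the configured h to a
few per cent.

**Known limitation.** With the boundary data linearized on the mean line,
the transport is second order in the orbit amplitude, and its absolute
scale (a few μm/s for typical parameters) sits well below measured bead
velocities (tens to hundreds of μm/s); a quantitative velocity match
requires the full envelope treatment, which is out of scope here. The
model's contracted observables are the profile *shape* (parabolic,
x-intercept at h), the boundary/divergence residuals, and the sensitivity
signs of V_eff (+CBF, +CBA, +ρc, −λ, −y₀), all of which hold.

## Profile fit and statistics

`ParabolicProfile.fit()` minimizes Σw(V − U_w(1 − y/h)²)² with analytic
Jacobian (bounds U_w ≥ 0, h > 0; initial h from the line fit of √V vs y,
which is exact below the intercept). Standard errors come from the
Gauss–Newton covariance with residual variance on n − 2 dof. An all-zero
profile is flagged degenerate: U_w = 0 with h indeterminate (NaN) rather
than an arbitrary intercept. τw = 2μU_w/h is returned in mPa and, by
construction, scales linearly with a global rescaling of the velocities.
Per-patient summaries use the sample (n − 1) standard deviation — the
convention validated against the bundled table, where the population SD
visibly disagrees (patient 1: 3.6 vs the printed 4.1) — and omit the SD
for single-edge patients.

The bead-velocity regression is OLS with intercept on the five
exploratory variables (CBF, ρc as fraction, CBA, y₀, λ) via statsmodels;
the design must be full rank and n ≥ 10. The near/far comparison splits
beads at the median distance and applies a two-sided Mann–Whitney U:
exact null for combined n ≤ 20 without ties, normal approximation with
tie correction (and no continuity correction, so identical groups give
p = 1) otherwise. Bland–Altman reports the pairwise bias and
mean ± 1.96·SD limits of agreement. The per-cilium force is the plain
quotient of τw by an areal cilia density (e.g. 5 cilia/μm² → pN); it is
returned with an explicit caveat because a steady wall stress divided by
a count is not comparable to oscillatory single-cilium force
measurements, and published per-cilium figures are not recovered by this
division.

## Synthetic data: what it does and does not emulate

The generator renders the three features the estimators rely on, with
exact ground truth: (1) a cilia band extending one cilium length (6 μm)
from the wall polyline on the fluid side, in which a seeded, exact
fraction ρc of pixels ("cilia") oscillate sinusoidally at the CBF with
spatial phase 2πx/λ and time-averaged grey below background; (2) beads as
anti-aliased discs (area-coverage rendering, 6×6 subsampling) advected
parallel to the edge at U_w(1 − y₀/h)²; (3) i.i.d. Gaussian pixel noise
clipped to 8-bit. Defaults mirror the reference acquisition: 358 fps,
1800 frames, 256×192 px, 0.32 μm/px, background grey 180.

It does *not* render resolved cilia, optical point-spread, mucus,
Brownian bead motion, or non-sinusoidal beat waveforms; passing recovery
tests therefore demonstrates correctness of the estimators under the
model's own assumptions, not robustness to every optical artefact of real
recordings. Analyses of synthetic movies sample the grey level on a line
offset 3 μm into the band (`EdgePolyline.offset`), as an operator clicks
on the visibly beating cilia rather than the band's outer boundary.
Profile-sample generation accepts per-altitude noise SDs because measured
per-bead velocity scatter grows with the velocity itself; recovery
studies use SD = 10% of the local velocity on altitude grids that mirror
the observed near-wall-heavy bead distance distribution (0.3–70.9 μm,
mean ≈ 13 μm).

## Problem sizes in the test suite

Unit tests run on compact movies (512 frames, 160×96 px) where one FFT
bin is 0.70 Hz; the end-to-end recovery test uses the full reference
geometry (1800 frames, 256×192 px, bin 0.199 Hz). The Monte-Carlo fit
study uses 1000 profiles of 10 altitudes; the simulator sensitivity sweep
is a 2-level factorial over (CBF, CBA, ρc, λ) × two altitudes with a
12 μm observation window — V_eff is window-independent for the
steady-dominated flow, while crossing times (hence runtime) scale with
L_w.
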