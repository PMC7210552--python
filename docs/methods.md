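# Methods

This note documents the models, numerics and design choices behind the
pipeline, and what the synthetic data does and does not establish.

## Synthetic inputs

**Velocity waveforms.** The common-carotid Doppler trace is modelled as a
non-negative baseline plus periodized Gaussian bumps: a systolic peak
(default 0.8 m/s above a 0.2 m/s baseline at 0.12 T, σ = 0.045 T) and,
for the during-counterpulsation state, a diastolic augmentation bump
(default 0.35 m/s at 0.56 T, σ = 0.06 T). The diastolic centre 0.56 T is
the midpoint of the two diastolic report instants used in the comparison
(0.54 T rest, 0.58 T during), where the diastolic velocity peaks. Bumps
were chosen over splines because their cycle integral is closed-form
(amp·σ·√(2π) per period), so generator correctness is analytically
checkable. The waveform is exposed as an abstract "velocity"; whether it
stands for a Doppler peak velocity or a cross-section mean is decided by
the perfusion module's `profile_factor` (1.0 default = mean velocity;
0.5 documented for peak velocity under a parabolic profile).

**Geometry.** The bifurcation is the implicit union of three slab-capped
tubes (CCA trunk r = 3.1 mm along +z, ICA r = 2.4 mm and ECA r = 1.9 mm
splayed 50° in the x–z plane; typical adult dimensions), triangulated by
marching cubes at 0.25 mm pitch — watertight and genus-0 by
construction, with flat, labelled inlet/outlet discs. The plaque is an
axisymmetric Gaussian narrowing of the ICA radius with relative depth
`plaque_depth_frac` ≤ 0.2 (the emulated subject class has diameter
stenosis below 20%). An axisymmetric narrowing was chosen over a
one-sided indentation so that *diameter stenosis measured from any
cross-section equals the spec value exactly*, making the
stenosis-recovery check well-posed; the one-sided appearance of a real
plaque is cosmetic for every quantity this pipeline measures. The grid
origin is offset by 0.37 voxels so the flat end planes never coincide
with grid planes (which would create degenerate marching-cubes
crossings).

**MR-like slices.** Slices orthogonal to the vessel axis through the
trunk: bright lumen (200) on dark background (40) with a one-pixel
linear intensity ramp across the boundary (sub-pixel realism),
non-overlapping bright clutter blobs, and additive Gaussian noise.
Gaussian was preferred to Rician magnitude noise for analytic
tractability; at the contrast-to-noise ratios generated (σ = 10% of
contrast) the difference is immaterial to Otsu thresholding. Ground
truth contours come from the analytic implicit field (sub-pixel
accurate), which is why the generator takes the geometry *spec* rather
than the triangulated mesh — slicing the mesh would only add
tessellation error to the truth. Not emulated: k-space artefacts, bias
fields, partial-volume anisotropy, Doppler spectral broadening. Passing
the segmentation tests therefore shows robustness to additive noise and
clutter, not to MR physics.

## Segmentation

Denoising is opening-by-reconstruction followed by
closing-by-reconstruction with a disc structuring element (default
radius 4 px): clutter smaller than the disc is removed without eroding
the lumen shape. Binarization is Otsu's threshold. The edge map is the
two-pixel boundary band (dilation minus erosion of the foreground)
blurred with σ = 2 px and rescaled to [0, 1]; the band straddles the
region boundary so the blurred ridge is centred on the true sub-pixel
edge — using only the inner boundary layer biases contours inward by
half a pixel. Image-border pixels are excluded from the edge set.

The snake discretizes the energy ∮ α|c′|² + β|c″|² + γ(1−E) ds with N =
100 vertices resampled to uniform arclength every iteration. Internal
terms use the periodic pentadiagonal (circulant) operator solved
semi-implicitly; the external force is the gradient vector flow (GVF)
diffusion of ∇E (μ = 0.2, 250 iterations), which extends the ridge's
pull across homogeneous regions — a plain ∇E force with σ = 2 px decays
within ~3 px and cannot recover a 6 px initialization error — while
agreeing with ∇E on the ridge, so the converged position is unchanged.
Defaults α = 0.01, β = 0.1, γ = 1, step 1.0, tolerance 0.05 px, 500
iterations. Each iteration is accepted only if the discrete energy does
not increase (step backtracking, up to 10 halvings); evolution stops at
convergence, iteration cap, or when no decreasing step exists. Multiple
foreground components are disambiguated by overlap with the previous
contour's interior (largest component on slice 1). A contour failing a
self-intersection screen (isoperimetric-ratio bound) is flagged and the
previous contour is carried forward. The first slice's contour is
supplied externally (file or ground truth), standing in for a manual
trace.

## Reconstruction

Lofting resamples adjacent contours to 128 uniform-arclength vertices,
aligns them rotationally by minimizing summed squared distance over
cyclic shifts, and stitches triangle strips. With 128 vertices the
polygonal lateral area of a cylinder is within 0.01% of 2πrh.

The Y-junction uses a pants triangulation rather than a projected 2D
Delaunay (no projection plane is well-defined at a bifurcation): the
trunk's distal ring is split at the two saddle vertices where it crosses
the inter-branch direction, each arc is closed by a straight 3-point
seam between the saddles (bowed 30% toward the junction midpoint), and
each closed loop is zippered to one branch ring by greedy
shortest-diagonal stitching. The seam is shared by both halves, so the
result is watertight by construction, and the side assignment is
symmetric in the branch arguments. Winding is made globally consistent
afterwards and flipped outward if the capped volume is negative. The
construction assumes the two branch proximal rings are spatially
disjoint; the pipeline starts branch tubes two trunk radii past the
branch origin to guarantee this.

The inlet extension extrudes the inlet ring along its mean (Newell)
normal by 5·r̄, where r̄ is the mean vertex distance to the ring centroid (the
"averaged radius" rule needs a concrete definition and this one is
exact for circles and well-behaved for ellipses). Extrusion
preserves the cross-section exactly; re-extending replaces the previous
extension via the stored pre-extension base mesh.

Flattening is a deliberately simplified surface-of-revolution chart:
θ = azimuth about the per-ring centroid in a fixed global frame (so
rotating the mesh shifts θ by the same angle), u = cumulative centreline
arclength, plus a radius channel. It is bijective per ring for
star-shaped sections; texture-faithful flattening is out of scope.

## Flow

Two solvers, split by what each geometry actually requires:

- **Axisymmetric tube (the workhorse).** In a rigid straight tube the
  developed solution is exact: velocity is axial and z-independent, the
  convective term vanishes identically, and momentum reduces to unsteady
  radial diffusion forced by the axial pressure gradient. The gradient
  is the Lagrange multiplier enforcing the prescribed cross-section mean
  velocity at each step (solved in closed form since the update is
  affine in G). Crank–Nicolson in time (200 steps/cycle), finite-volume
  radial operator on 64 nodes geometrically clustered toward the wall
  (ratio 1.04) — the structured analogue of near-wall inflation layers.
  Wall shear uses a second-order one-sided derivative. The run starts on
  the Poiseuille profile of the initial mean velocity, integrates four
  cycles and retains the last; the retained-vs-previous cycle RMS
  difference is reported (≈10⁻⁸ in practice, comfortably under the 1%
  periodicity criterion). The discrete momentum residual is monitored
  and required below 10⁻⁵ (it is ~10⁻¹⁵, machine level, because the
  update is a direct solve); continuity is satisfied identically.
  Validation: steady WSS within 0.01% of 8μU/D; oscillatory WSS within
  0.05% RMS of the Womersley solution at α = 4.6; <1% change between
  the two finest default grids.

- **2D planar channel (full equations).** MAC staggered grid, explicit
  fractional-step projection with a prefactorized sparse Poisson solve;
  plug inlet, no-slip walls, opening outlet implemented as zero normal
  velocity gradient with zero reference pressure (one concrete reading
  of an "opening" boundary). Used to exercise the nonlinear equations
  (steady plane Poiseuille within 0.4%; WSS-amplitude linearity under
  inlet doubling holds at low Reynolds number and degrades as convection
  grows). A stenosed 2D domain was not implemented; stenosed-wall
  metrics are exercised on the 3D surface via the mapping below.

**Quasi-1D wall-shear map.** The 3D wall field is the solver's reference
shear rescaled per cross-section: τ(ring, t) = τ_ref(t) · q · (R_ref /
r_ring)³, with the bifurcation flow split by Murray's law (q ∝ r³), and
the vector aligned with the local centreline direction; seam vertices
inherit nearest-ring values. This reproduces the leading spatial
structure (elevated shear over the stenosis, branch-level differences)
while inheriting the solver's exact time dynamics. It is an estimate,
not a 3D solve: secondary flows, bulb recirculation and the
high-OSI pockets of a real bifurcation are absent, which is why the
synthetic OSI is small and nearly state-independent. Directional
conclusions (shear level up, perfusion up, OSI barely moved) are
meaningful; absolute index values are not patient-comparable.

## Indices

Time quadrature is the composite trapezoid with periodic closure, which
on uniform samples equals the sample mean — exact for the closed-form
fixtures to quadrature order. The WSSG derivatives act on the *scalar*
magnitude |τ⃗_w| (the printed component form is ambiguous without a
frame convention; the scalar reading recovers it exactly on flat walls):
per-triangle P1 gradients via the metric tensor (frame-free, exact for
linear fields), area-averaged onto vertices; central differences on
structured wall polylines. OSI of an identically zero series is defined
as 0 with a data-quality flag; RRT singularities (OSI → ½ or AWSS → 0)
are flagged +inf, never NaN, and excluded from summary statistics.
Summary means are unweighted point means by default with an
area-weighted option (the reference tables do not state their
weighting). Percent changes are rounded half-up to one decimal, matching
the reference reporting style.

## Study conditions and problem sizes

Defaults are the study conditions: 10 slices of 96×96 px at 0.15 mm/px,
noise σ = 10% of contrast with 3 clutter blobs for the scored fixture;
solver 64 radial nodes × 200 steps × 4 cycles; grid study at 16/24/32/48
nodes; metrics on the ~6.6k-face combined wall. These sizes put the full
study at a few seconds on one core while every validation criterion is
met with wide margin; the same code scales to finer settings through the
config dataclasses.

## Known limitations

- No 3D Navier–Stokes solve: bulb recirculation, secondary flows and
  realistic OSI/RRT spatial patterns are not produced.
- The subject's absolute values (pressures, Table-style index
  magnitudes, the published 12.6% perfusion elevation) depend on
  unpublished waveforms/geometry and are reproduced only as arithmetic
  on the published summary tables, never as field recomputations.
- Rigid walls (as in the reference workflow); the diameter waveform
  feeds perfusion only.
- The snake's parameters are tuned for bright-lumen slices; vessel-wall
  (outer boundary) extraction and inter-slice registration are out of
  scope.
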