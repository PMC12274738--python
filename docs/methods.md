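# Methods

## Scanning model and trajectory construction

A frame is a continuous curve sampled at the laser pulse repetition rate
(PRF), so consecutive samples are separated by a constant angular increment
within each pass.  The frame splits its `n_points` pulses equally between an
outward pass (centre → rim) and an inward pass (rim → centre); `n_points`
must therefore be even, and the four-pass compound variant needs a multiple
of four.  Radial laws: Archimedes `r = aθ` with `a = R/(2π·n_turns)`, Fermat
`r = a√θ` with `a = R/√(2π·n_turns)`.  The outward pass includes both
endpoints (`r = 0` and `r = R` exactly); the inward pass starts one angular
step past the apex so the rim sample is not duplicated, and descends to
`r = 0`.

**Return-pass geometry.**  The inward pass mirrors the radial law while the
rotation keeps advancing at the same constant rate.  This makes the apex
junction an ordinary sampling step (no flyback, no first-difference
discontinuity beyond ~2× the median step) and automatically staggers the
return turns relative to the outward turns over most of the field.  We
deliberately did not implement interleaving as a rigid angular offset of the
return pass: rotating the whole pass by `π/n_turns` would displace its first
sample by `R·π/n_turns` (~0.2 mm at defaults), i.e. a flyback-sized jump a
resonant scanner cannot execute.  A `pass_phase_offset` parameter (default
0) exists for studying that variant.

**Compound composition.**  The default A-FS frame is one AS outward pass
joined at `r = R` (matched position, continuing rotation) to one FS inward
pass — a single out-and-back double spiral, which preserves resonant
continuity.  A four-pass variant (`as_roundtrip_fs_roundtrip`) concatenates
complete AS and FS round trips, joining at the centre.

**Defaults.**  `fov_diameter = 2 mm`, `prf = 200 kHz`, `n_points = 33332`
(the nearest even pulse count giving a 6 Hz frame rate at that PRF), and
`n_turns = 16` per pass.  The turn count is not critical for any radial
statistic: with uniform angular sampling the cumulative point fraction
inside radius ρ depends only on the radial law (`ρ/R` for AS, `(ρ/R)²` for
FS, their mean for A-FS), so the central-pulse-fraction figures are
identical across `n_turns ∈ {8, 16, 32}` to better than 0.01 pp; 16 turns
is chosen as a realistic balance between inter-turn spacing (~62 µm) and
the ~9 µm optical resolution of such systems.

## Sampling analysis

Pulse positions are binned into half-open pixel cells (image row 0 at top,
x → column, y → row, FOV-centred mm coordinates; points landing exactly on
the outer edge belong to the last pixel, so the closed FOV disk bins
without loss).  The energy factor is `log10(counts+1)` normalised by its
maximum over the grid — the normaliser is a design choice; the definition
fixes only the logarithmic compression.  Central disks of area fraction `f`
have radius `R√f`.  The grid default is 512×512 with pixel size
`fov_diameter/512`.  Radial fill profiles use equal-width annuli over
`[0, R]` and ignore pixels outside the FOV circle.

## Phantom generator

The phantom emulates planar vascular scenes on a dark background: smooth
spline centrelines (jittered control points), constant-diameter tubes
rasterised as uniform disks (optional Gaussian feathering), per-vessel sO₂
and relative C_HbT, and dual-wavelength absorption computed through the
packaged extinction table — so the optical forward model is consistent with
the unmixing module by construction.  Styles: `parallel` (dense
longitudinal vessels), `grid` (sparse reticular pattern), `loops`
(capillary hairpins), `random_tree` (bifurcating trees; the only style with
ground-truth branch points — crossings in `grid` are overlaps, not
bifurcations, and are deliberately not counted as truth NBP).

Defaults, chosen once as physiologically plausible for a 2 mm FOV at 512 px
(3.9 µm pixels): diameters 3–8 px (12–31 µm, capillary-to-venule scale),
arterial sO₂ 0.95–0.98, venous 0.60–0.75, relative C_HbT 0.9–1.1 per vessel
(total hemoglobin varies modestly between vessels; the system measures it
only up to a scale).  One bifurcating tree per unit `vessel_density`, depth
3, child length ×0.66 and diameter ×0.7 per generation, branching
half-angles 0.5–0.8 rad — chosen so sibling subtrees do not cross and tube
unions stay resolvable, which is what makes the analytic truth
(arc/chord/diameter per segment) a meaningful oracle.  Scenes covering
>90% of pixels are rejected.

What the phantom does *not* model: optical scattering and depth-dependent
fluence, acoustic propagation and transducer bandwidth, speckle, motion,
layered (3-D) vasculature.  Recovery results on it therefore certify the
*analysis chain* (gridding, segmentation, skeleton metrics, unmixing
algebra), not performance on real tissue.

## Acquisition and reconstruction

Amplitude = bilinear sample of `mu_a(λ)` at the pulse position, plus
Gaussian noise, clipped at zero.  Dual-wavelength mode fires both lines at
the same position (co-located pairs, zero lag); an optional `lag_pulses`
mode samples the second wavelength one or more pulses later to study
interleaving misregistration.  `bin_mean` reconstruction averages samples
per pixel and leaves unsampled pixels at zero with a false fill flag — the
"raw" image of a sparse scan.  Gap filling is classical scattered
interpolation (`nearest`/`linear` via Delaunay triangulation), flagged as
interpolated; no learned restoration is included.

Stitching uses least-squares rigid registration of landmark pairs
(orthogonal Procrustes with the determinant constrained to +1, no scale),
and mosaics tiles into the union bounding box with either overwrite or
distance-feathered averaging.

## Unmixing

The per-pixel 2×2 system is solved analytically; the shared proportionality
constant (Grüneisen × fluence) is absorbed into relative units and assumed
wavelength-independent — no fluence correction is applied, a documented
limitation shared by the two-wavelength method itself.  sO₂ is reported
only where both wavelengths were sampled and the 532 nm amplitude exceeds a
threshold (default 5× a robust background-noise estimate: 1.4826×MAD of
filled pixels adjacent to sampling gaps).  Negative component estimates are
clamped to zero and counted.  The packaged ε values (532 nm:
ε_HbO2 ≈ 44480, ε_Hb ≈ 40584 cm⁻¹/M; 558 nm: ≈ 33512 / 52912) come from the
standard compiled hemoglobin spectra, with the 558 nm row interpolated; the
near-isosbestic property at 532 nm (|Δε|/ε ≈ 9%) is what lets the 532 nm
amplitude stand in for relative C_HbT.  All quantitative tests rely on
forward–inverse self-consistency rather than on the specific ε values.

The noise-recovery experiment (2%-of-peak amplitude noise, 10 noise seeds)
reconstructs on a 128×128 grid: a 33k-pulse frame then delivers ≥2 samples
to most in-FOV pixels, so bin-mean averaging is actually exercised; at
512×512 the same frame leaves most pixels with 0–1 samples and the
experiment would measure interpolation, not unmixing.  Error is evaluated
on pixels whose ground truth is unambiguous (all contributing sub-pixels
inside one vessel), since sO₂ truth is undefined for partial-volume
mixtures of vessel and empty background.

## Morphometry

Segmentation default: Otsu threshold on a white-top-hat-filtered image
(radius 20 px), removal of objects <20 px, filling of holes ≤64 px.  The
hole-fill cap matters: enclosed regions larger than that (grid cells, loop
interiors) are genuine background.  The threshold step is a stand-in
validated only against synthetic truth.

Skeletons come from topology-preserving thinning.  The 8-connected pixel
graph is cleaned of redundant diagonal edges (a diagonal whose two pixels
share a 4-connected skeleton neighbour) before degrees are computed;
touching branch pixels merge into one branchpoint node, and terminal spurs
shorter than 5 px — thinning artefacts at junctions — are pruned and the
trace repeated.  Per-point diameter is 2× the Euclidean distance transform
at interior chain points; junction and end pixels are excluded because the
normal-line diameter is ill-posed there.  This distance-transform diameter
equals the normal-line definition for locally straight tubes and is far
more robust at junctions.

Arc length is measured on a moving-average-smoothed chain (window 5,
endpoints pinned).  Rationale: the raw 8-connected chain overestimates the
length of oblique or curved paths by up to ~8% (staircase excess), which
would alone exceed the VL and VT recovery tolerances; the smoothing is
exact on collinear chains, so a straight segment still yields VT = 1
exactly, and a rasterised semicircular tube recovers VT = π/2 to ~0.01%.
VT averages per-segment arc/chord ratios, unweighted by default
(length-weighted optional), skipping closed loops (zero chord) and chains
shorter than 5 px whose ratio is discretisation noise.

FD uses multi-scale box counting: boxes anchored at the image origin,
default sides the powers of 2 from 2 px to image_size/4, FD = least-squares
slope of `log N(r)` vs `log(1/r)`.  A single-scale reading of that formula
is ill-defined (it depends on the unit of r); the regression is the
standard estimator.  `box_sizes` is an explicit argument, so structured
fixtures can use matched scales — e.g. triadic sizes {1, 3, 9, 27} on a
3-iteration Sierpinski carpet give the slope log 8/log 3 exactly.

## Numerical conventions and degenerate inputs

One grid convention everywhere (`_grid.py`): FOV-centred mm, x right / y up,
row 0 at top, half-open cells closed at the outer edge; bilinear sampling
places integer indices at pixel centres, so a pixel-centre scan reproduces
the raster exactly and dense noiseless acquisition + bin-mean is bit-exact.
Empty masks, empty record sets, all-zero images, <2 landmark pairs,
coincident landmarks, <2 distinct box sizes, odd pulse budgets and
out-of-extent pulses all raise `ValueError` naming the problem (and the
offending pulse index where applicable).  A single isolated skeleton pixel
yields one node and no segments.  All randomness flows through
`numpy.random.default_rng(seed)`; the pipeline derives per-stage seeds as
`SeedSequence([global_seed, stage_index])`, so a config plus seed
reproduces every artefact byte-for-byte.

## Problem sizes

The test suite and acceptance script run at the nominal operating point
(33k-pulse frames; 512 px phantoms for morphometry recovery, 256 px scenes
for reconstruction comparisons, 128 px grids for the unmixing Monte-Carlo
with 10 noise seeds) — sizes at which every statistic above is stable to
well within its stated tolerance.

## Known limitations

- No electromechanical MEMS dynamics: trajectories are kinematic ideals;
  real resonant amplitude ramps and mirror inertia will deform `r(θ)`.
- Wavelength-independent fluence in unmixing; no absolute C_HbT.
- The segmentation stand-in (Otsu + top-hat) is validated on synthetic
  scenes only; real endoscopic images need a tuned segmenter.
- Truth NBP is defined only for the tree style; crossings in other styles
  produce skeleton branchpoints by construction of the union mask.
- FD of a finite raster is scale-window dependent; reported FD values are
  comparable only at matched box-size ranges.
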