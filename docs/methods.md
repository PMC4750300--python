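# Methods

## Geometry and conventions

A cilium is modelled as a straight 3D segment of length `L` (µm) at
elevation θ (angle to the imaging x–y plane; 0° lying flat, 90°
perpendicular) and an in-plane azimuth. Straightness (a continuous slope
along the whole length) is the assumption under which the Pythagorean
estimate is exact; curved or kinked cilia are out of scope for all three
automated methods and are better served by manual path tracing.

Voxels are indexed `(z, y, x)` with isotropic in-plane pixel size `dxy`
(µm/px) and axial step `dz` (µm/slice). `(x, y)` coordinates are continuous,
0-based, measured at pixel centers; z indices are integers. Slice `k`
represents the axial slab `[(k−½)·dz, (k+½)·dz)`, so a segment's slice span
is obtained by nearest-integer rounding of its endpoints' axial coordinates;
a flat segment lying on a slice plane spans exactly one slice. Spans are
inclusive (`span = z_last − z_first + 1`). Calibration is never guessed:
explicit arguments beat OME metadata, and a stack without either fails to
load.

## The three measurement methods

**MIP.** The annotated polyline on the maximum intensity projection,
`Σ‖Δp‖·dxy`. The projection discards axial extent, so the expected value for
an ideal straight cilium is `L·cos θ`: flat cilia are measured faithfully,
angled cilia are systematically foreshortened.

**PyT.** `c = √(a² + b²)` with `a` the projected polyline length and
`b = (z_last − z_first)·dz`. The interval count (not the slice count) is
used for `b` so that a single-slice cilium gets `b = 0`, making PyT collapse
to MIP exactly in that case; counting slices instead would add one `dz`
systematically. Because `b` is quantised to multiples of `dz`, PyT carries a
worst-case axial error of about `dz/2` per endpoint. This is a real
limitation for short, steep cilia: a 2 µm cilium at 70° has a true axial
extent of 7.52·dz at dz = 0.25 µm, so the best achievable `b` is off by
≈ 0.12 µm and the length error is ≈ 5.7% *whatever* the stack placement.
The validation grid documents this: that one cell exceeds the 5% recovery
tolerance; every other cell (L ∈ 2–5 µm, θ ≤ 70°) is within it.

**DAAS.** A side-view plane is resliced along the vector between the
operator's two projection picks. The plane contains the z-axis, so sample
z-coordinates coincide with slice positions and each sample needs only
bilinear interpolation of the four neighbouring pixels within its own slice;
columns are spaced at the native `dxy` and the plane extends a configurable
margin (default 1 µm) beyond the picks. Lengths on the plane use the
anisotropic calibration `√((Δs·ds)² + (Δz·dz)²)`.

## The automated operator

The interactive step of the original workflows — a human clicking endpoints —
is replaced by `auto_endpoints` so the pipeline is reproducible and
high-throughput; manual annotations are still measured verbatim when given.
The detector thresholds the image inside the measurement grayscale window
(default 55–255 on the 8-bit scale), keeps the largest connected component,
and initialises with the component's two most mutually distant pixels under
the physical metric (deterministic lexicographic tie-break). Two refinements
then remove blur-induced bias:

1. **Axis estimation by ridge tracking.** The intensity-weighted principal
   axis of a short streak is rotated toward the more-blurred axial direction
   (the PSF adds `diag(σz², σxy²)` to the second-moment matrix, and
   σz > σxy). The centerline is immune to this: perpendicular blur is
   symmetric about the core, so background-subtracted perpendicular
   centroids at stations along the middle 60% of the streak lie on the true
   axis. A straight-line fit through those ridge points (two iterations)
   gives the working axis.
2. **Tip localisation at the half-maximum crossing.** For a uniform line
   blurred by a symmetric PSF the intensity at the true tip is exactly
   halfway between the line's plateau and the background, so each tip is
   taken as the outermost crossing of that level along the fitted axis
   (linear sub-sample interpolation). A plain intensity-weighted centroid
   refinement was tried first and rejected: it leaves a residual
   ~`2σ·√(2·ln(plateau/threshold))` length inflation that grows for short
   cilia.

With this operator, noise-free recovery over the validation grid is within
+4% for DAAS everywhere (worst cell L = 2 µm, θ = 60°), with a small
positive bias from linear interpolation across the coarse axial sampling of
the plane.

The slice span feeding PyT and the flat/angled classifier is, in the
pipeline's default operator mode, *judged from the image*: a slice shows the
cilium when the 3×3-mean-filtered intensity within 0.5 µm of the annotated
polyline reaches the threshold (the smoothing keeps single noise voxels from
extending the span). This mirrors how spans are read in practice — the
observer sees the blurred image, not the geometric truth — and it is what
produces the characteristic mild PyT inflation of flat cilia. The analytic
span is available as an alternative mode.

## Synthetic data

The generator deposits a uniform linear intensity density along the segment
(sub-voxel trilinear splatting at ¼-voxel steps), convolves with a separable
anisotropic Gaussian PSF, scales the result so the post-blur peak equals the
cilium's amplitude, then adds constant background, Gaussian noise (Poisson
optional), clips to [0, 255] and quantises to 8-bit. Annotations returned by
the generator are analytic — exact projected endpoints and the slice span of
the un-blurred segment — so ground truth is independent of any detection
step.

Default conditions, chosen once: `dxy = 0.1 µm`, `dz = 0.25 µm` (the
established acquisition step for this application), PSF σxy = 0.1 µm,
σz = 0.3 µm (a standard confocal anisotropy of 3×), background 10, noise
SD 5, amplitude 100. The amplitude is deliberately moderate: it is
calibrated so that an in-plane cilium's above-threshold signal spans ≤ 4
slices at dz = 0.25 µm under the default PSF — i.e. so that flat cilia *by
appearance* exist at all, matching how such populations present in real
monolayers. A much brighter amplitude would let the axial PSF skirt alone
cross the 55 threshold over ≥ 5 slices and every cilium would classify as
angled.

Cohorts draw true lengths from N(3.0, 0.7²) µm truncated to [1.5, 6] µm for
*both* populations; flat cilia get elevations in [0°, 5°], angled in
[45°, 70°]; azimuths are uniform. Replicate measurements perturb the clicked
endpoints with Gaussian jitter of 0.05 µm per coordinate, emulating operator
click variability; three replicates are averaged per cilium and method, and
the replicate range is reported as a technical-error QC statistic. Note the
automated DAAS picks can respond discretely to click jitter, so occasional
replicate ranges exceed what a careful human operator would produce.

What the generator does *not* emulate: curved or beaded cilia, non-uniform
staining, saturation, depth-dependent PSF broadening, refractive-index
mismatch, cross-talk from neighbouring structures, or detector-specific
noise. Passing tests therefore demonstrate correctness of the measurement
geometry and statistics under the stated optical model, not robustness to
every property of real immunofluorescence data.

## Agreement statistics

The ICC is the two-way, single-measure, absolute-agreement variant ICC(A,1),
computed from the mean squares of the n×2 layout:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),  k = 2.

Absolute agreement is the only variant that penalises a systematic
between-method bias, which is the phenomenon of interest here; the
consistency variant would forgive MIP's foreshortening entirely. A layout
with zero total variance is defined as ICC = 1 (with a warning). Landis–Koch
bands are applied with exclusive lower bounds, so boundary values (0.2, 0.4,
0.6, 0.8) fall in the lower band. Bland–Altman limits use the n−1 SD of the
differences and a 1.96 multiplier (configurable). Population comparisons use
the pooled-variance two-sided Student's t-test, with Welch available behind
a flag.

## Problem sizes and numerical choices

The validation suite renders each grid cell (4 lengths × 6 elevations) in a
tight per-cilium volume (≈ 30 × 20 × 70 voxels), the cohort study uses
31 + 31 cilia, and the step-size scan renders one cilium at dz = 0.04 µm and
re-acquires it at 16 steps × 3 grid phases; the whole suite completes in a
few seconds on one core. The step-size scan draws a uniform axial grid phase
per re-acquisition because a single fixed phase makes the result an artefact
of where the cilium happens to sit relative to the slice grid; averaging
three phase-randomised acquisitions mirrors the average-of-three measurement
protocol and yields a stable largest-consistent-step (0.45–0.75 µm across
seeds, comfortably above the 0.40 µm reliability boundary, with visibly
growing replicate spread beyond it). Degenerate inputs are handled
explicitly: single-pixel components yield zero-length endpoint pairs,
perpendicular cilia project to a point and receive an ε-offset second
annotation point, and resampling is downsampling-only with nearest-integer
8-bit re-quantisation.
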