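# Methods

## Scope and data model

The package processes two-channel 3D fluorescence stacks of developing
zebrafish vasculature: channel 1 labels endothelial cells (vessel
walls), channel 2 labels circulating red blood cells (vessel interiors).
Volumes are `(z, y, x)` arrays with anisotropic voxel spacing in µm;
offsets and coordinates are 0-based integer voxel indices, and a tile's
position is the displacement of its origin in the global frame.

## Mosaic planning

A camera field of view of 1.097 mm (960 px at 10×) covers only part of
an embryo that reaches 3.5–4 mm, so acquisition volumes are tiled along
the sample axis with step `(1 − overlap) · FOV` and overlap 30% by
default — enough shared structure for reliable stitching. The tile
count is the smallest whose coverage `FOV + (n−1)·step` reaches the
expected sample length (ceil semantics; a 1e-9 slack guards the
exact-coverage case against float noise). Data-rate arithmetic
multiplies volumes × channels × planes × frame pixels × bytes/pixel ×
timepoints/day; with 75 dual-colour 16-bit volumes of 200 planes every
20 min this gives 3.98×10¹² bytes/day (TB = 10¹² bytes; a flag switches
to TiB).

## Stitching

Registration is translation-only and integer-voxel: the stages are
repeatable to ~0.5 µm (half a pixel), sub-voxel refinement would force
resampling of binary masks, and the residual error is below the
segmentation noise. The normalized cross-power spectrum of each
overlapping tile pair is inverted to a correlation surface; its top
local maxima are candidate offsets, each expanded over its wraparound
ambiguity, restricted to a search radius (default 20 px) around the
stage-predicted offset, and ranked by real-space zero-normalized
cross-correlation of the implied overlap. Pairs whose best correlation
falls below 0.3 are declared unreliable and fall back to the nominal
displacement with weight 1e-3 in the global solve; reliable pairs enter
with their correlation as weight. Global positions minimize the
weighted squared deviation from the pairwise offsets with tile 0 pinned
at the origin (one linear least-squares per axis; a disconnected
adjacency graph is an error naming the components). Fusion uses
Fiji-style linear blending: each tile contributes with a weight ramp
equal to its distance to the nearest tile border, normalized across
contributors; voxels covered by exactly one tile are copied bit-exact.
For 3D stacks, registration runs on y/x maximum-intensity projections
and the recovered in-plane offsets are applied to the stacks, with z
offsets taken from the stage positions — the projections carry the same
lateral texture at far better signal-to-noise, and axial stage error is
negligible. Per-timepoint registration is the default; a saved offset
set can be re-applied to lock a series to one solution.

## Self-supervised segmentation

Red blood cells circulate only inside perfused vessels, so the RBC
channel is an intrinsic luminal marker. The pipeline:

1. **Luminal proxy.** Gaussian smoothing (σ = 2 px) consolidates the
   speckled RBC signal; Otsu's threshold separates it from background.
   A flat channel yields an empty mask with a warning rather than an
   arbitrary cut.
2. **Training set.** Candidate voxels are the union of the endothelial
   channel's Otsu foreground and the luminal proxy, dilated by 2 voxels
   (6-connected). This keeps negatives *near* vessels — wall voxels and
   the immediate perivascular shell — rather than trivial far
   background, which is what makes a linear model learn contrast along
   the wall/lumen axis instead of a bare brightness cut. Candidates are
   shuffled once under the seed and the first N = 5000 of each class
   (inside/outside the proxy) are taken without replacement; a class
   shortfall is flagged, never padded by duplication.
3. **Features.** Six per-voxel features of the endothelial channel: raw
   intensity; central-difference gradients along x, y, z (voxel units,
   replicate-edge boundaries); the Euclidean gradient magnitude; and the
   inverse-gradient-weighted image `I/(1+‖∇I‖)`, which is large exactly
   where signal is strong *and* locally flat — filled vessel interiors —
   and small on steep wall edges and empty background. Features are
   z-scored over the whole volume; the statistics are stored on the
   model so a saved model scores new stacks with its training
   standardization. Gradients deliberately ignore the µm anisotropy:
   the per-feature standardization absorbs the scale, and mixing axes
   before standardization would let the coarse z axis dominate.
4. **Weight solve.** The design matrix (6 standardized features + a
   constant bias column; without the bias, zero-feature voxels would be
   forced to score 0) against 0/1 labels is solved by SVD
   pseudo-inverse — the minimum-norm least-squares solution, exact and
   deterministic, robust to collinear features (the gradient magnitude
   is a function of the three gradients). The fit residual ‖Xw − y‖² is
   recorded.
5. **Threshold.** Scores are histogrammed into 256 bins over their
   range and cut with the Triangle algorithm: a line from the histogram
   peak to the far end of the longer tail; the threshold is the bin
   maximizing the distance between histogram and line (vertical
   distance — the ranking is identical to perpendicular distance for a
   fixed line); a left-side long tail is handled by mirroring. The
   foreground is everything above the right edge of the threshold bin.
6. **Cleanup.** One erosion followed by one dilation (morphological
   opening) with a 3×3×3 6-connected cross — the smallest element that
   removes single-voxel fragments while sparing thin vessels.

Per-stack refitting is the default (each stack carries its own
intensity statistics); passing a saved model skips the supervision
stages.

## ROI tracking

Regions are annotated once, at the last timepoint where anatomy is
clearest, and propagated backward. Per boundary point and per step
t → t−1: a 70×70 px template around the point at t is matched by
zero-normalized cross-correlation (illumination-robust) at every valid
placement inside a 140×140 px concentric window at t−1; border-clipped
windows shrink accordingly. Ties break toward the smallest displacement,
then row-major; a zero-variance template contributes no shift. The raw
per-point shifts are regularized by a componentwise median over a
centred, circular window of 7 boundary points (the point itself plus
three per side; shorter boundaries use the global median), then points
landing on the same or an 8-adjacent pixel are merged (collapse below 3
points is an error carrying the timepoint). The median window including
the centre point is one of two defensible readings of a 7-point
neighbourhood; it is the default because it never moves a point that
agrees with its neighbours. Merging only removes points, so the
boundary point count is non-increasing backward in time; no points are
re-inserted where the boundary stretches.

## Quantification

Masks are resampled to isotropic voxels at the finest existing spacing
by nearest-neighbour index mapping — exact replication for integer
ratios, no interpolation, binarity preserved — then counted;
volume = count × (iso spacing)³. Region volumes intersect the mask with
a rasterized label image; labels plus the unlabeled remainder partition
the mask exactly. The two ±60° viewing angles of one fish are averaged
pointwise (unmatched timepoints dropped with a warning), and each fish's
time base is shifted by a supplied per-fish offset; the anatomical
reference (the left/right primordial hindbrain channel anastomosis) is
identified manually upstream, so the shift is an input, not a detection
problem.

## Growth models

Six cumulative laws share the asymptote parameterization
`A` (lower asymptote, volume already formed at observation start) and
`V_L` (added volume, upper asymptote `A + V_L`):

| model | V(t) | shape parameters |
|---|---|---|
| log-logistic | `A + V_L/(1+(t/α)^(−β))` | scale α > 0, shape β > 0 |
| log-normal | `A + V_L·Φ((ln t − µ)/σ)` | log-time mean µ, sd σ > 0 |
| Gompertz | `A + V_L·exp(−exp(−k(t−t_i)))` | rate k > 0, inflection t_i |
| logistic | `A + V_L/(1+exp(−k(t−t_i)))` | rate k > 0, inflection t_i |
| Weibull | `A + V_L(1−exp(−(t/λ)^k))` | scale λ > 0, shape k > 0 |
| Richards | `A + V_L(1+ν·exp(−k(t−t_i)))^(−1/ν)` | k > 0, t_i, asymmetry ν > 0 |

The comparison models are standard four-parameter forms chosen so every
model reads on the same A/V_L semantics. Rates dV/dt are analytic; peak
growth times use closed forms — log-logistic
`t* = α((β−1)/(β+1))^(1/β)` (only for β > 1; at β ≤ 1 the rate is
monotone decreasing and `None` is returned), log-normal
`t* = exp(µ − σ²)`, Gompertz/logistic `t* = t_i` — and a log-grid +
bounded-refinement argmax for Weibull and Richards.

Fitting minimizes the RSS with Levenberg–Marquardt. Positive parameters
are log-transformed so the solver stays unconstrained; initialization is
data-driven (A₀ = min V; V_L₀ = range; time scales from the interpolated
half-rise; shapes from the interquartile rise span, e.g.
β₀ = ln 9 / ln(t₇₅/t₂₅); ν₀ = 1) with 10 multiplicatively jittered
restarts under a fixed seed, keeping the lowest RSS. Non-convergence
returns the best attempt flagged, never an exception; a fitted `V_L`
collapsing toward zero (constant data) is flagged `V_L_boundary`.
Model comparison fits each candidate and sorts by RSS — the criterion
used throughout, with residual vectors retained for inspection.

Identifiability: with observations starting at 17 hpf, the offset `A`
is an extrapolation of the lower asymptote to t → 0 and is the least
determined parameter — at 2% noise its median relative error (~17%) is
several times that of `V_L`, α, β (2–3%). This is a property of the
data window, not of the optimizer.

## Synthetic data

The phantom generator emulates the study's imaging regime at voxel
spacing (1, 1, 1) µm (the study's z step is 4 µm; isotropic test
phantoms exercise the same geometry at manageable size):

- **Vessels** are bounded-curvature random-walk tubes (radius 4–7 µm,
  capillary-to-medium calibre) reflected off the volume margins. The
  wall truth is the shell `|d − r| ≤ w/2` of the distance-to-centerline
  field (w = 1 µm, a thin embryonic endothelium); the lumen is
  `d < r − w/2`; where tubes overlap, lumen wins.
- **Endothelial channel**: a Gaussian shell profile (σ = w/2) centred
  at the radius, per-vessel base intensity drawn from 120–255,
  multiplied by nucleus blobs (σ = 2 µm, Poisson-placed at 0.15/µm of
  centerline) for wall heterogeneity, plus a weak luminal fill at 0.35
  of the base intensity, all blurred by an isotropic σ = 1.5 µm PSF.
  The luminal fill and PSF reproduce a property of real light-sheet
  data the self-supervision depends on: vessel interiors carry signal
  above extravascular background (cytosolic EGFP lining, point-spread
  fill of capillary-scale lumina, scattered out-of-focus light).
  Without it, luminal training positives are indistinguishable from
  background in every first-order feature, no linear scorer can
  separate them, and the Triangle threshold degenerates — the method
  itself, not just the phantom, requires partially filled lumina.
- **RBC channel**: ellipsoidal Gaussian speckles (σ = 1.2×1.0×1.0 µm,
  the scale of embryonic erythrocytes) whose centres are Poisson-placed
  (0.04/µm³) strictly inside the lumen with ≥ 1.5 µm clearance from the
  inner wall face — circulating cells ride the axial stream and keep a
  cell-free layer at the wall. The clearance is what keeps the smoothed,
  thresholded proxy ≥ 95% inside the true lumen.
- **Noise** is additive Gaussian, the simplest model that exercises the
  thresholding stages; channels are clipped at 0.

Tile sets cut a volume along one axis with width
`w = L / (1 + (n−1)(1−overlap))`, nominal offsets `i·(1−overlap)·w`,
and integer jitter within ±jitter_px on the true cutting positions
(tile 0 anchors the frame), so reassembly at the true offsets
reproduces the source exactly. Growth series evaluate a named model on
an even time grid (defaults 17–90 hpf, n = 100 — the study's
observation window) plus Gaussian noise. Each generator call draws all
randomness from one integer seed.

**What the phantoms do not model:** branching vessels, pulsatile or
directional RBC motion, photobleaching, sample drift, Poisson photon
statistics, multi-view fusion artifacts, and anisotropic PSFs. Passing
tests on phantoms therefore demonstrate correctness of the algorithms
under the stated geometry and noise model, not performance on raw
microscope data.

## Verification problem sizes

The acceptance script and test suite run, per invocation: one 128³
four-vessel phantom for segmentation quality (Dice vs ground truth,
luminal coverage, SVD-vs-pseudo-inverse agreement at N = 5000 + 5000);
10 seeded tile sets (3 tiles, ±5 px jitter) for exact offset recovery
plus a 3-cycle oracle solve; 50 random background-peak histograms
against the scikit-image Triangle reference; noise-free round trips of
all six growth laws (60 points), 20-seed noisy recovery (n = 100, σ =
2% of V_L) and 20-seed log-logistic-vs-Gompertz RSS ordering (σ = 1% of
V_L, the low-noise condition for model discrimination); and a 10-frame
rigid-translation tracking fixture (3 px/frame, 16 boundary points).

## Known limitations

- The segmentation is a linear scorer; vessels in regimes the training
  set does not represent (e.g. unperfused sprouts with no RBC signal
  nearby) are segmented only insofar as their features resemble the
  luminal class.
- Triangle thresholding assumes a dominant background mode with the
  informative tail on one side; score maps violating that (e.g. from a
  degenerate fit) can flip the threshold to the wrong tail.
- Stitching is translation-only; rotation or scale drift between tiles
  is out of scope, as is illumination correction across tile seams.
- The log-normal and log-logistic laws are near-indistinguishable on
  cumulative data over a finite window; RSS ranking between the two is
  not meaningful evidence for either, and only their joint advantage
  over non-log-time models is asserted.
- ROI tracking assumes small inter-frame motion (≲ 35 px, half the
  search margin) and textured projections; it only removes boundary
  points, so a strongly expanding region becomes sparsely sampled
  forward in time.
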