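# Methods

## Problem and model assumptions

The pipeline segments two abdominal fat compartments in transverse rodent
MR slices: subcutaneous adipose tissue (SAT), the ring between the skin
and the abdominal muscle wall, and visceral adipose tissue (VAT), the fat
surrounding the organs inside the wall. It assumes fast-spin-echo-like
contrast: fat hyper-intense, the muscle wall iso-intense, organs hypo- to
iso-intense, background dark. The muscle wall is the only anatomical
boundary the method must find explicitly; everything else is handled by
intensity clustering. Slices are processed in 2-D (the in-plane resolution,
~0.2 mm, is roughly eight times finer than the slice spacing, so 3-D
filtering would mix anatomy across slices); quantification then sums over
slices.

## Stage-by-stage description

### Preprocessing

* **Normalization** maps each slice to [0, 1] by min–max after clipping at
  the 0.5th/99.5th percentiles. The clipping makes the map robust to hot
  pixels and reconstruction spikes, which would otherwise compress the body
  into a sliver of the intensity range. The map is monotone, so downstream
  thresholds are well defined.
* **Background removal** zeroes pixels below 5 % of the normalized range —
  air and coil noise, which would otherwise contribute spurious gradients.
* **Anisotropic diffusion** (Perona–Malik, 4-neighbour explicit scheme,
  zero-flux boundaries) denoises while preserving edges. Defaults: 15
  iterations, conductance scale κ = 0.1 (normalized intensity units — noise
  gradients ≲ 0.05 are smoothed, tissue edges ≳ 0.3 are kept), time step
  0.2 (the 2-D explicit bound is 0.25), exponential conductance. The
  antisymmetric flux form conserves the slice mean exactly and never
  increases total variation.
* **Edge enhancement** is unsharp masking, `I + a(I − G₁∗I)` with gain
  a = 1, clipped to [0, 1]. It sharpens the wall/fat interfaces the curve
  evolution must detect; the clustering stage instead reads the diffused
  (unsharpened) image, whose intensities are not distorted near edges.

### Body mask and initial contour

Otsu's threshold over the nonzero pixels separates the bright subcutaneous
shell from darker tissue; the largest bright connected component is kept
(discarding disjoint artifacts) and hole-filled so organs enclosed by the
shell become foreground. The boundary of this mask is traced with Moore
neighbour tracing into a closed 8-connected chain.

The initial contour is this chain scaled about its centroid and placed at
the slice centre, then rasterized and embedded as a signed Euclidean
distance field (negative inside). The scale factor lives in [0.75, 0.85];
by default it is derived per slice from the size of the binary mask: the
shell thickness is estimated as (bright ring area)/(body perimeter), and
the scale is chosen so the shrunken contour clears the shell plus a wall
allowance (`wall_clearance`, default 4.5 px ≈ wall thickness + blur
margin) along the most constrained direction, clamped to the interval.
Thin animals land at 0.85, obese ones at 0.75. A fixed scale (default
0.80) is available via `init.adaptive_scale = false`. The geometric reason
for adapting: a fixed 0.80 leaves the initial curve less than half a pixel
from the wall once the fat shell approaches 20 % of the minor body axis,
and a curve initialized inside the blurred wall gradient cannot read clean
local statistics. Chain perimeters are estimated with the
Vossepoel–Smeulders corner-corrected chain-code formula
(0.980·n_axis + 1.406·n_diag − 0.091·n_corners), accurate to ~1 % on
smooth convex shapes where the naive √2-weighted chain length is ~5 %
biased.

### Hybrid geodesic / local-region evolution

The curve `{φ = 0}` expands with outward normal speed

    F(x) = g(x)·[β + R(x)] − ω·g(x)·κ(x),
    R(x) = ((I−v_x)² − (I−u_x)²) / ((u_x−v_x)² + ε),

with `g = 1/(1+(|∇(G_σ∗I)|/s)²)` (σ = 1.5 px, s = 1), balloon β, curvature
weight ω = 0.2, and `u_x`, `v_x` the mean intensities of the interior and
exterior parts of the radius-*r* disc around x. R is positive where the
pixel resembles the local interior (push outward past it) and −1 where it
resembles the exterior; the (u−v)² normalizer keeps speeds O(1) at any
local contrast, so *every* coherent interface can hold the curve and the
balloon decides which interfaces are crossed.

Two couplings matter and set the defaults:

* **Local radius r = 3 px.** The radius must not exceed the muscle-wall
  thickness (~0.5 mm ≈ 2.5 px at 0.2 mm pixels). A larger ball mixes the
  wall with the bright subcutaneous fat behind it in the exterior mean, the
  wall pixels then read as "interior", and the curve tunnels through the
  wall.
* **Balloon β = 0.1.** The balloon must stay below the region force that a
  weak, diffusion-blurred edge can produce (the organ/wall contrast is
  ~0.1 after smoothing). With β much above ~0.15 the curve creeps through
  the inner wall edge pixel by pixel and comes to rest on the strong
  wall/SAT edge instead — leaving the wall inside the curve, which breaks
  the subsequent skin/wall stripping geometry.

Numerics: Osher–Sethian upwind differencing for the advective part,
central differences for curvature (κ clamped to ±1), time step 0.35
(CFL-safe for |F| ≤ 1.1), updates restricted to the |φ| < 10 px narrowband,
signed-distance reinitialization every 20 iterations via the binary
Euclidean distance transform with a half-pixel interface offset. The
enclosed area is tracked with sub-pixel coverage, Σ clip(0.5 − φ, 0, 1):
a plain pixel count is quantized at whole pixels and would make slow
expansions look stationary between checks. Expansion stops when the area
changes by less than `area_tol` = 10 px between checks (every 5
iterations), with a hard cap of 500 iterations; a vanished contour or
border contact is an error, not a silent clamp.

The EDT-based reinitialization preserves the interior sign pattern exactly
(zero-crossing displacement < 0.5 px) and restores |∇φ| ≈ 1, but has
staircase outliers near diagonal interfaces: |∇φ| ∈ [0.9, 1.1] holds for
≳90 % of band pixels (median ≈ 1.00), not pointwise. This is adequate for
the flow, which renormalizes speeds by |∇φ| each step.

### Clustering, merging, stripping

The converged contour splits the body into a subcutaneous side (outside)
and a visceral side (inside). Each side is clustered with fuzzy C-means on
intensity — 3 classes for the SAT side (skin, fat, wall/partial volume),
5 for the more heterogeneous visceral side — with fuzzifier m = 2,
tolerance 1e-5 on centroid movement, centroids initialized at evenly
spaced intensity quantiles (deterministic; a seed adds jitter only on
request). Voxels are pooled across slices by default so class structure is
shared; per-slice clustering is a config option. Hardening is by maximum
membership, ties toward the brighter centroid.

Fat-like classes are merged into one mask: any class whose mean lies
within `intensity_gap` = 0.15 of the brightest class's mean *and* whose
region touches the brightest class's region. The gap excludes muscle and
organs; the adjacency condition excludes bright but anatomically detached
structures.

Skin and the abdominal wall are then stripped from the subcutaneous mask:
a 2 px band inside the body outline (skin is fat-bright and would
otherwise be counted as SAT) and a 1 px band around the converged contour
(|φ| < 1). The wall itself is iso-intense and already excluded by the
merge rule; the contour band only needs to cover the ~1 px partial-volume
shell, and a wider band was found to remove genuine subcutaneous voxels
wherever the wall is locally thin. Depth inside the body mask is measured
as EDT − 0.5 px, consistent with the half-pixel interface convention of
the distance embedding.

### Quantification

volume(ml) = voxel count × row spacing × col spacing × slice thickness
/ 1000; mass(g) = 0.9 g/ml × volume (adipose tissue density, configurable).
Percent change between scans is 100·(post − pre)/pre per depot, computed
per subject. Dice overlap 2|A∩B|/(|A|+|B|) (empty vs empty defined as 1)
is the evaluation metric against phantom ground truth.

## The synthetic phantom

Each slice is a nested-ellipse construction: body outline (semi-axes
85×68 px in a 224² grid, 3 slices, 3 % end-slice taper), a 2 px fat-bright
skin line (mean 0.8), a 7 px SAT ring (0.9), a 2.5 px iso-intense wall
(0.45), and an organ interior (0.35, with two darker organ blobs at 0.30)
holding five VAT discs (0.85, radii 8–13 px) lining the inside of the wall
— where perirenal and retroperitoneal fat sits in real rodents, and what
allows an expanding contour to cross fat and stop at the wall. A
multiplicative low-frequency bias field (amplitude 0.1) and Rician noise
(σ = 0.03, the high-SNR magnitude-MR model; Gaussian available) corrupt
the intensities; labels are the noise-free assignments. Voxel geometry
defaults to 0.2×0.2×1.6 mm, matching typical rodent FSE protocols. Three
slices rather than a full L1–L5 stack keep end-to-end test batches fast;
quantification is additive over slices, so nothing scientific depends on
the count. Rings are nested ellipses rather than constant-thickness EDT
bands because the continuous implicit function gives near-continuous
rasterized counts — which the paired-series calibration exploits,
bisecting the post-scan SAT thickness and VAT blob radius scale until the
ground-truth counts hit the programmed fractional changes (achieved to
~0.1 %).

What the phantom does **not** emulate: partial-volume mixing at tissue
interfaces (labels are crisp), chemical-shift and motion artifacts,
disconnected or folded wall anatomy (available only as the deliberate
`skin_fold` failure mode, where a wall sector takes the fat intensity and
the contour correctly cannot hold there), organ texture, and inter-animal
shape variability beyond axis scaling. Passing the phantom batch therefore
demonstrates the machinery is correct under the stated contrast
assumptions, not that the defaults transfer to any scanner; on real data
the diffusion κ, intensity gap and strip depths are the knobs to revisit.

## Design choices where the design was open

* The exact hybrid energy is specified here as the geodesic factor
  multiplying balloon-plus-local-region force with g-weighted curvature;
  the local means follow the localized region-based active-contour idea of
  modelling interior/exterior by neighbourhood mean intensities.
* Signed-distance construction uses the exact Euclidean distance transform
  of the rasterized interior (half-pixel offset) rather than fast
  marching or PDE reinitialization — exact for the binary interface,
  deterministic, and fast at these image sizes.
* "Centre of the slice" means the geometric centre of the grid; a
  mask-centroid mode exists for off-centre animals.
* Clustering pools voxels across slices by default, since class counts are
  meant to reflect intensity variation across the whole stack.
* Scaling before placement is about the contour centroid, not the image
  centre.
* Per-slice failures ("contour collapsed", "containment lost") abort that
  slice with a logged message; the CLI exits nonzero if any slice failed.

## Known limitations

* The wall must be a closed, intensity-separated ring on every slice;
  skin folding or abdominal compression that erases the separation defeats
  the curve evolution (by design it is an error, not a silent guess).
* Evolution is 2-D per slice; no inter-slice consistency is enforced.
* The stopping rule compares areas, so a curve pinned early on a closed
  spurious interface stops "converged"; the trace (areas, iterations,
  stop reason) is exported so such slices can be audited.
* No bias-field correction is performed; the local-region force and
  per-side clustering tolerate the smooth ±10 % fields in the phantom, but
  stronger coil profiles would need external correction first.
* Cross-scan slice matching (pre vs post) is the user's responsibility.
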