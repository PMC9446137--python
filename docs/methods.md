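# Methods

## The labeling model

`woundlabel` treats semantic annotation of a wound photograph as a
two-stage process. Stage one produces *proposals*: partitions of the
working image (or of a zoomed sub-rectangle) computed by four segmentation
algorithms with user-controlled hyperparameters. Stage two composes the
label mask: whole proposal segments are assigned to tissue classes, with
later assignments overwriting earlier ones, and two manual operators — a
circular brush and a seed-referenced flood fill — correct edges the
automatic partitions miss. The mask is a per-pixel class map with 0
reserved for "unlabeled"; a finished session exports the image/mask pair
(the mask as a paletted PNG whose palette index equals the class id, so
the file round-trips bit-exactly).

All interaction is expressed as a JSON session script. Replay on the same
image is deterministic by construction: the segmenters contain no hidden
randomness (k-means is seeded explicitly), and every tie-break below is
fixed.

"Zoom" is modeled as crop-plus-resegmentation: proposals are computed on
the active sub-rectangle at native resolution and selections are offset
back into full-image coordinates. Display magnification is irrelevant to a
headless tool. Gamma correction (`v → v^γ`) applied through a script
mutates the working image, so subsequent proposals see the corrected
pixels; the proposal cache is invalidated at that point.

## Image model and color

Pixels are continuous RGB in [0, 1]; 8-bit quantization happens only at
file I/O (bytes are written as `round(255·v)` half-up). This avoids double
quantization in gamma and color conversion. CIELAB conversion uses the
exact piecewise sRGB transfer function and the D65 white point — not the
2.2-power approximation — and is cross-checked in the tests against
scikit-image's converter. Gaussian pre-smoothing uses reflective boundary
handling with kernel radius `int(4σ + 0.5)`.

## Proposal generators

**Felzenszwalb graph merging** runs on Gaussian-smoothed RGB (σ default
0.8) over the 4-connected grid graph; edge weight is Euclidean color
distance. Edges are sorted by `(weight, first endpoint index, second
endpoint index)` — the positional tie-break makes runs reproducible on
8-bit images, where equal weights are common. Components merge when the
edge weight is at most `min_i(Int(C_i) + k/|C_i|)`. Afterwards, components
below `min_size` (default 20 px) are folded in one at a time: the smallest
undersized component (ties: lowest pixel index) merges across its
minimum-weight outgoing edge. Because this fold-in stage breaks size ties
positionally, exact mirror equivariance on tie-free inputs is guaranteed
only for `min_size = 1`; the core predicate itself is equivariant.
4-neighborhood was chosen over 8 for oracle simplicity.

**SLIC** clusters in `(L, a, b, y, x)`. Seeds sit at the centers of an
`ny × nx` grid chosen to make `ny·nx` closest to the requested count with
the squarest cells, then move to the lowest-gradient pixel in their 3×3
neighborhood (ties keep the unperturbed position, so constant images
retain the regular grid). Assignment searches each center's 2S×2S window
with `D² = d_lab² + (m/S)² d_xy²` (compactness m default 10 on the Lab
scale); pixels covered by no window fall back to the globally nearest
center, and every pixel's current center always remains a candidate. The
tracked per-iteration objective is the total *squared* assignment cost
ΣD², which the alternating minimization (nearest-center assignment, then
mean-labxy center update) provably never increases; the unsquared sum is
not monotone under mean updates and is not used. Iteration stops at
`max_iter` (default 10) or when no assignment changes. Connectivity
enforcement relabels 4-connected fragments; a fragment smaller than S²/4
that is not its cluster's largest is reassigned to the adjacent component
with the greatest boundary contact (ties: lowest component id), smallest
fragments first. Segment count may therefore exceed `n_segments` slightly.

**Quickshift** works on `(ratio·Lab, y, x)` (ratio default 0.5). The
Parzen density uses a Gaussian kernel of bandwidth `kernel_size`, summed
over a *square* spatial window of half-width `ceil(3·kernel_size)` — the
truncation shape is a package choice, declared here and mirrored by the
brute-force test oracle. Each pixel links to the spatially nearest pixel
of strictly higher density within `max_dist` (candidate offsets ordered by
squared distance, then (dy, dx)); pixels with no such neighbor are roots.
"Strictly higher" means exact plateaus (e.g. constant images) produce
one root per pixel — a documented degenerate behavior. Segment count is
non-increasing in `max_dist` since growing the search radius can only
remove roots.

**K-means** clusters raw RGB vectors with k-means++ seeding from a
`numpy` Generator keyed by `(seed, restart)`, `n_init` restarts (default
3) keeping the lowest SSE. An empty cluster is re-seeded at the point
farthest from its assigned centroid, preserving the requested cluster
count whenever feasible. Clusters are *not* spatially connected; the
labeling layer treats each connected component as independently
selectable. Cluster ids are renumbered by first row-major occurrence, so
fixed seeds give bit-identical maps.

All four emit contiguous ids ordered by first pixel occurrence.

## Manual operators

The brush writes all pixels within Euclidean distance ≤ radius of the
center, clipped to the image. The magic wand admits a pixel iff its
Euclidean RGB distance *to the seed pixel* (not a running region mean) is
≤ tolerance, and selects the 4-connected component of admissible pixels
containing the seed — implemented as connected-component labeling of the
admissibility mask, which is equivalent to breadth-first flood fill and is
verified against a BFS reference in the tests. The tolerance is on the
[0, 1] scale (0.1 ≈ 26 8-bit steps of combined channel difference).

## Evaluation protocol

The confusion matrix counts pixel pairs over the palette classes; with
`ignore_unlabeled` (default) pixels unlabeled in either map are excluded
and reported separately. Precision, recall and `F = 2PR/(P+R)` follow the
usual definitions, with zero denominators yielding 0 and a warning.
Reports always contain both **pooled** metrics (sum confusion matrices,
then compute) and **macro** metrics (per-image metrics averaged over
images whose truth contains the class): published agreement tables rarely
state which rule they used, and the two can differ materially when class
prevalence varies across images, so neither is privileged. CSV output is
rounded to 4 decimals; full precision is retained in memory. The
difference image is simply `1{a ≠ b}`, written as a black/white PNG.

## Synthetic scenes

The generator emulates the geometry of a wound photograph, not its
photometry: a background plane, a skin ellipse covering ≥ 40% of the
frame (semi-axes 0.40H × 0.44W, slightly jittered), and a wound bed whose
boundary is `r(θ) = R·(1 + Σ_{h=2..5} a_h sin(hθ + φ_h))` with seeded
amplitudes summing to the `irregularity` parameter (radial factor clipped
at 0.2 to keep the curve closed). The bed is granulation with slough and
necrotic blobs drawn as unions of seeded discs; drawing order
(granulation, slough, necrotic) resolves overlaps, and a small fallback
patch guarantees every enabled class occupies at least one pixel. Pixel
color is the class mean plus i.i.d. Gaussian noise (sd 0.03 ≈ 8 8-bit
steps, a realistic sensor/texture scale) clipped to [0, 1], optionally
shaded by a linear illumination gradient (default amplitude 0.10) along a
seeded direction. Default means mimic clinical hues: blue-gray backdrop,
tan skin, red granulation, yellow slough, near-black eschar.

What the scenes do **not** model: specular highlights, depth and limb
curvature, camera blur, spatially correlated texture, gradual tissue
transitions, and annotator disagreement. Passing tests therefore
demonstrate the correctness and composability of the machinery and the
*achievable* accuracy of segment-selection labeling on well-separated
tissue colors — not clinical-grade performance.

Six pinned-seed study scenes (seeds 101–106: defaults, no necrotic, noise
sd 0.01 and 0.06, irregularity 0.05 and 0.30; all 128×128) are the fixture
set used across the test suite. 128×128 at 400 SLIC superpixels puts
roughly 40 pixels in a segment — the same segment-to-image ratio a
practitioner would use on larger photographs, while keeping the whole
suite fast.

`oracle_select` assigns each proposal segment its majority truth class
(ties: smallest class id), which maximizes pooled pixel accuracy among all
constant-per-segment assignments; `achievable_metrics` chains proposal →
oracle selection → per-class metrics and thus measures how much labeling
accuracy the superpixel quantization itself forfeits.

## Numerical and degenerate-input choices

* Half-open, 0-based rectangles everywhere; empty rectangles are domain
  errors.
* SLIC cost monotonicity is asserted to 1e-9 absolute slack (float
  accumulation order), k-means SSE to 1e-12.
* Palettes must have consecutive ids 1..C with unique names and colors;
  the default follows the labeled-output legend (background blue, intact
  skin green, granulation red, slough yellow) plus necrotic black; an
  `editor_preset` variant (intact skin blue, background gray) mirrors the
  palette conventions of pixel-editor workflows. Unlabeled (index 0)
  renders magenta in label PNGs, a color outside both presets.
* Scripts abort on the first invalid action, reporting its zero-based
  index; actions on disjoint pixel sets commute.

## Known limitations

* The superpixel implementations favor clarity and testability over
  speed; they are vectorized numpy, comfortable at a few hundred thousand
  pixels but not real-time at camera resolution.
* Quickshift's square density window and positional tie-breaks are
  package-specific conventions; other implementations will produce
  slightly different (equally valid) forests.
* No undo stack, GUI, EXIF or color management beyond sRGB.
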