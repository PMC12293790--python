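# Methods

## Scope and model

`spotcall` annotates fixed-diameter (55 µm) multicellular capture spots on
an RGB immunofluorescence scan as positive/negative for a nuclear marker,
and quantifies agreement between annotation sets.  The analysis unit is the
spot, not the cell: every measurement is computed inside a disk mask of
radius `round_half_up(diameter / 2·scale)` pixels centered on the spot's
pixel coordinates.  Pixels outside the disk — and, for spots at the image
border, outside the image — count as black.  A nucleus belongs to the spot
whose mask it was segmented in; because segmentation runs on the masked
tile, nuclei straddling the rim are truncated at the rim rather than
assigned by an overlap rule.

The method assumes: (i) an 8-bit RGB raster in which one channel is a
nuclear counterstain (DAPI, blue) and one is the marker fluorophore's
dominant channel (Texas Red, red); (ii) spot coordinates already registered
to that raster (no alignment is performed); (iii) nuclear staining that is
center-bright and edge-dim, the premise of the segmentation; and (iv) a
nuclear marker — cytoplasmic or membrane staining is out of scope because
segmentation is driven solely by the nuclear stain.  16-bit input rasters
are accepted and linearly rescaled to 8-bit (integer division by 257); all
thresholds live on the 0–255 scale.

## Iterative threshold peeling

The working image is the masked nuclear channel.  At threshold *T* every
pixel `< T` is set to 0 ("above the threshold" keeps ties).  8-connected
components of the survivors are examined in raster-scan order of their
first pixel; a component is accepted as one nucleus iff

- `area ≥ min_area_px` (noise floor), and
- `boundary ≤ perimeter_max`, where boundary is the count of member pixels
  with at least one 4-neighbour outside the component (image edges count
  as outside).

Accepted components are recorded (pixel set, centroid, boundary, the
accepting threshold) and erased; everything else survives to the next
iteration at `T + range_increment`.  Iteration stops when the threshold
exceeds `dapi_upper_limit` or the image is black, after at most
`ceil((upper − start)/range) + 1` steps.  The 8-connectivity /
4-boundary pairing avoids checkerboard pathologies; the explicit raster
ordering makes the output reproducible down to list order, and a naive
flood-fill re-implementation in the test suite reproduces it exactly.

A nucleus's pixel set is recorded at its acceptance threshold, i.e. the
bright core, which is smaller than the first-iteration footprint.  Marker
statistics therefore run over core pixels.  `dilate_px` optionally grows
each core back (morphological dilation restricted to pixels above the
start threshold and unclaimed by other nuclei, earlier acceptances taking
priority); it is off by default because the core-pixel behaviour is the
conservative reading and the fixtures place marker foci near nucleus
centers, where the two readings agree.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `dapi_start_threshold` | 40 | first DAPI threshold (0–255) |
| `range_increment` | 10 | per-iteration threshold increase |
| `dapi_upper_limit` | 255 | stop once the threshold passes this |
| `perimeter_max` | 120 | max boundary pixels for one nucleus |
| `min_area_px` | 20 | smallest region accepted |
| `dilate_px` | 0 | optional core re-growth steps |

The defaults are this implementation's own; `perimeter_max` in particular
must be tuned to the tissue's nucleus size in pixels — it should sit above
the boundary count of one nucleus core and below that of two fused cores.
`SceneSpec.suggested_segmentation_params()` encodes that rule
(`≈ 6.7 × nucleus radius in px`) for the synthetic scale.

Note a non-obvious interaction: a *finer* `range_increment` is not always
at least as good at splitting overlaps.  A fine sweep can land on an
intermediate threshold where a fused cluster's boundary momentarily fits
`perimeter_max` and is accepted as one region; a coarse sweep that jumps
past that window can end up resolving more nuclei.  Counts across
increments stay close, and on geometries whose fused boundary never fits
the limit the final count is increment-independent, but exact equality
should not be expected on heavy overlaps.

## Marker quantification

A pixel is marker-positive iff every channel value lies in the closed range
`[rgb_min[c], rgb_max[c]]` and the pixel is inside the spot disk.  A cell
is positive iff the positive fraction of its nucleus pixels reaches
`cell_positive_pixel_fraction` (default 0.10, boundary inclusive); a
fraction is the default because it is invariant to nucleus size, with an
absolute-count mode (`min_positive_pixels`) as the alternative.  Spot
intensity is the arithmetic mean of the main-channel value over pixels
that are both marker-positive and inside some nucleus, 0.0 when that set
is empty.  Restricting intensity to nuclei is what discriminates true
nuclear marker signal from red-blood-cell autofluorescence, which is
bright in red but lies over no nuclear stain; the looser whole-disk
average is available as `intensity_scope="spot"` for comparison.

## Call rule

`excluded` iff the spot holds fewer than `min_cells` (default 10) nuclei —
such spots stay in the results CSV for auditability but are omitted from
the Loupe category export.  Otherwise `positive` iff the selected criteria
pass: `intensity_only`, `percent_only`, or `both` (default), with
thresholds defaulting to intensity 60 and percent 10.  The comparison is
strict `>` by default; the inclusive `>=` reading ("10 % or more") is one
config key away (`comparator="ge"`), since both conventions appear in
practice and they differ exactly on boundary-valued spots.

## Agreement statistics

Pairwise percent agreement is `100 · #identical / N`; the average is the
mean over all R(R−1)/2 pairs.  Fleiss' kappa uses the standard
formulation (per-subject agreement from category counts, chance agreement
from pooled prevalences).  For exactly three raters and binary labels the
mean per-subject agreement equals the mean pairwise agreement, so kappa is
recomputable from summary statistics alone
(`fleiss_kappa_binary_from_summaries`); the algebraic identity between the
two routes is property-tested on random matrices.  With R = 2 the pooled
formulation reduces to Cohen's kappa computed with pooled marginals, which
is the cross-check used in tests.  Reconstructing kappa from *rounded*
published summaries is sensitive to the rounding: proportions printed to
one decimal can shift the third decimal of kappa, so only the
reconstruction whose inputs are self-consistent at the printed precision
is asserted exactly.  Ratings files are inner-joined on spot id; subjects
missing from any rater are dropped with a logged count.  Kappa is reported
to 3 decimals and agreements to 2.  No confidence intervals are computed.

## Synthetic slides

The generator renders what the analysis needs and nothing more:

- **Nuclei**: clipped isotropic 2-D Gaussians on the blue channel, peak
  `U{180..240}`, σ = radius/1.85 so intensity at the nominal radius falls
  near/below the default start threshold — the minimal center-bright
  profile.  Default radius 3 µm at 0.5 µm/px (6 px), a compromise that
  keeps tens of separable nuclei inside a 55 px spot radius.
- **Counts**: per-spot nucleus counts from `N(42.1, 15)` clipped to
  [11, 60], calibrated to reported per-spot cell statistics for dense
  tumour tissue; the upper clip is set by the placement constraint (min
  center separation 1.4 radii, rejection sampling; an infeasible spec
  raises rather than silently under-placing), not by observed tissue.
- **Marker**: positive nuclei get 4 red foci (radius 2 px, value 200)
  within 1 px of the nucleus center — punctate, and confined to the
  recorded core so the 10 % rule is met by construction.
- **Confounders**: per spot, red disks (value 180) with zero blue,
  placed ≥ 2.6 σ + blob radius from every nucleus center.
- **Noise**: i.i.d. Gaussian (σ = 2 by default) added to all channels,
  clipped to [0, 255].

All randomness flows from the single scene seed.  What the fixtures do
*not* emulate: anisotropic or lobed nuclei, intensity gradients and
vignetting, chromatic cross-talk, tissue autofluorescence texture, focus
blur.  Passing the recovery tests therefore demonstrates correctness of
the algorithmic chain under the method's own assumptions, not performance
on real scans — on real data the segmentation parameters must be tuned per
tissue, which is why they are all exposed.

Ratings generation (`make_ratings`) assigns each rater exactly
`round(p_r · N)` positives: nested sets for maximal agreement,
independent random sets for chance agreement, or — given a target mean
pairwise agreement — nested sets degraded by marginal-preserving swaps
(one rater at a time, each swap moving a positive from a unanimous-positive
subject to a unanimous-negative one) until the target is reached to within
one swap's granularity, `400/(3N)` percentage points for three raters.

## Numerical conventions

- Spot radius: round-half-up; centers rounded to the nearest pixel for
  mask construction; disk inclusion `dx² + dy² ≤ r²` on the integer
  lattice.
- Percentages serialized to 1 decimal, intensities to 2, kappa to 3.
- Ties: threshold keeps `= T` pixels; cell positivity inclusive at the
  fraction boundary; call thresholds strict by default (see above).
- Empty cases: blank tile → 0 cells, 0 % positive, intensity 0; empty
  marker-positive set → intensity 0; unanimous single-category ratings →
  kappa 1.
- Determinism: no randomness anywhere in the analysis path; component
  ordering fixed by raster scan; two runs on identical inputs produce
  byte-identical CSVs.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run entirely on generated
data: 20-spot slides (~600×480 px) for end-to-end recovery, single-spot
tiles for segmentation properties, 200 random ≤ 32×32 tiles for exact
equivalence against a brute-force flood-fill reference, 10⁴-subject
ratings matrices for the chance-agreement checks.  The full suite runs in
well under a minute on one CPU.

## Known limitations

- Nuclear markers only; segmentation is DAPI-driven by design.
- Circular spots only; no hexagonal-neighbour or sub-pixel geometry.
- No image registration, flat-field correction, background subtraction or
  spectral unmixing; inputs are assumed pre-registered 3-channel rasters.
- The perimeter criterion is a boundary-pixel count; strongly non-convex
  nuclei can exceed it and be deferred to a threshold where they shrink
  below the area floor, i.e. be missed.  The criterion is isolated in one
  predicate so an alternative (e.g. area-based) is a local change.
- Fleiss' kappa is reported without uncertainty; with very unbalanced
  prevalences small absolute disagreements move kappa substantially.
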