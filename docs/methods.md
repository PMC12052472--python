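# Methods

This note documents the models, conventions and numerical choices behind
`eggscore`, and what the synthetic test surfaces do and do not establish
about real scan data.

## Surface standardization

Meshes are plain indexed triangle sets in millimeters. Derived quantities
(face normals/areas, angle-weighted vertex normals) are cached and
invalidated whenever geometry is replaced, so metrics never see stale
normals.

**Alignment.** Real sections are cut from curved egg surfaces in arbitrary
poses. `align_to_xy` fits a least-squares plane (smallest principal
direction of the vertex covariance), rotates its normal to +Z (sign chosen
so the area-weighted mean face normal points up), translates the centroid
to the origin, and maps the in-plane projection of a supplied long-axis
direction to +Y. The long-axis direction must be supplied as metadata: a
disc of shell carries no intrinsic record of which way the egg's poles
lie. Alignment is idempotent to 1e-9.

**Section extraction.** Membership is by face-centroid distance from the
center measured in the local tangent plane (fitted to vertices within one
diameter). For shell-like, low-relief surfaces this agrees with a true
cylinder Boolean to well below the mesh resolution and stays robust on
open meshes; it is *not* appropriate for high-curvature closed surfaces
where a cylinder would intersect the far side.

**Decimation.** Sections are standardized to exactly 5000 faces by
Garland–Heckbert quadric edge collapse: area-weighted plane quadrics per
vertex, boundary-constraint quadrics (perpendicular planes through open
edges, weight 10³·len²) so the rim keeps its shape, a link condition to
preserve manifoldness, and a normal-flip guard. Collapses positioned at
the quadric optimum, falling back to midpoint/endpoints when the 3×3
system is near-singular or extrapolates wildly. A tiny edge-length term
(1e-9·len²) is added to every collapse cost: on exactly flat regions all
quadric costs are zero, and without the regularizer index-order
tie-breaking concentrates collapses and degrades both runtime and mesh
quality. Interior collapses remove two faces and boundary collapses one,
which is how the loop lands exactly on the target count. On smooth test
surfaces total area is preserved to ~0.1%, well inside the 2% contract.

## Metrics

**Complexity (DNE).** e = tr(G⁻¹H) per face from vertex normals, summed as
Σ e·A. Conventions, all configurable and echoed in CSV headers:

* vertex normals by angle-weighted averaging of incident face normals;
* boundary faces discarded by the *vertex* rule (any face touching a
  boundary vertex) — the stricter of the common discard rules; an edge
  rule and `none` are available;
* the top 0.1% of faces by contribution e·A dropped as outliers
  (`dne_outlier_fraction=0.001`), which suppresses solitary spikes from
  scan noise;
* faces with singular G (relative determinant below 1e-12) are skipped
  and recorded, never fatal; tiny negative densities from round-off are
  clamped to zero.

Checks: a flat plane scores 0 (constant normal field); a unit icosphere
with ≥ 5000 faces scores 8π within 0.1% (e = 2/r², ∫e dA = 8π for any
radius), and scaling any closed mesh leaves DNE unchanged (e ∼ s⁻²,
A ∼ s²).

**Relief (slope).** θ = arccos|n_z| per face, so overhanging faces fold
into [0°, 90°] instead of exceeding 90° (real shell sections have
essentially no overhangs; the fold protects against stray inverted
faces). The default mean is unweighted over retained faces; area weighting
is an option. The area-weighted mean over a fine hemisphere is 1 radian
(∫θ sinθ dθ / ∫ sinθ dθ over [0, π/2]), reproduced within 1%.

**Orientation.** Face-normal azimuths φ = atan2(n_y, n_x), rotated so the
configured long axis sits at 90°, are binned into eight 45° bins with
bin 1 = [0°, 45°). Faces whose normal's X-Y projection is below 1e-9 are
directionless and accumulate into an excluded-area bucket (bins + excluded
always equal retained area to 1e-6 relative). With the long axis on +Y,
ridges running pole-to-pole have flank normals near azimuth 0°/180°, i.e.
bins {1,4,5,8} — the along-axis set. The published score scale is
−100…+100 derived from the along/across area ratio; the transform used
here is the normalized difference

    Ω = 100·(SA_along − SA_across)/(SA_along + SA_across),

equivalently 100·(R−1)/(R+1) for the ratio R — the unique smooth, bounded,
sign-correct map of a ratio onto that scale. It is isolated in
`orientation_from_bins` so an alternative transform can be swapped in one
place. Rotating a mesh 90° about Z negates Ω (up to the excluded-area
bookkeeping), and V-groove surfaces built along/across the long axis
saturate at exactly ±100.

Per-bin *areas* are used, not patch counts: contiguous same-bin patches
are never enumerated, so patch-count-style minimum-patch filtering does
not arise here.

## Statistics

* **Shapiro–Wilk** is a screening report (3 ≤ n ≤ 5000); nothing switches
  methods silently on its outcome.
* **IQR outlier removal** is a single pass per egg per metric with
  quartiles by linear interpolation (the convention matters: it changes
  which points are outliers, so it is pinned and configurable). Fences are
  asymmetric — 1.5×IQR below, 3.0×IQR above — because the metric
  distributions are right-skewed; the multipliers are not dictated by the
  method and are configurable, with the defaults echoed in outputs.
  Per-egg (not per-taxon) pooling is the default; a pooled mode exists.
* **Bootstrap CIs** are percentile intervals of mean(a)−mean(b) over
  independent resampling of both samples, 1000 iterations, seed mandatory.
  Percentile intervals are first-order accurate: coverage of the 95%
  interval is ~94% at n = 50 per group and degrades for much smaller
  samples (~91% at n = 30).
* **Exact two-sample KS**: D = sup|ECDF_a − ECDF_b|; the p-value is the
  exact permutation-null tail probability (network algorithm, via
  scipy's exact mode) for n·m ≤ 10,000, with the asymptotic distribution
  above that guard, and the mode used recorded on the result. The exact
  null is discrete: at n = m = 10 the attainable p-values near the usual
  threshold are 0.0525 (D = 0.6) and 0.0123 (D = 0.7), so a test at
  α = 0.05 has true size 0.0123 there — the test is conservative at small
  samples, which is inherent to exactness, not a defect. Ties make the
  permutation null conservative as well (same caveat as R's `ks.test`).
* **Harmonic-mean combination**: p̊ = k/Σ(1/pᵢ), permutation-invariant and
  bounded by the min and max of its inputs; chosen over Fisher's method
  because the three metrics are computed from the same surface and are far
  from independent. The raw harmonic mean is the default decision
  statistic against α; the asymptotically calibrated variant (1/p̊ is
  asymptotically Landau with location ln k + 0.874 and scale π/2) is
  available via `calibrated=True`.

`pairwise_compare` builds symmetric per-metric and combined matrices over
all egg pairs (unit diagonal), excludes eggs with fewer than two retained
sections with a warning, and reports the fraction of significant pairs at
α = 0.05. Under a simulated null (both eggs drawn from one distribution)
the significance rate of the combined p at α = 0.05 measures ≈ 0.05.

## Synthetic surfaces

`make_section` builds z(x, y) = Σ Gaussian nodes + Σ Gaussian-profile
ridges extruded along a chosen azimuth + band-limited noise (six random
sinusoids, wavelengths 1.5–3 mm) on a grid-triangulated 10 mm disc,
deterministic given the seed. Defaults: 8 vertices/mm (~10,000 faces,
decimating to the 5000 standard), 25 nodes of 0.15 mm amplitude and
0.4 mm σ, 4 ridges of 0.15 mm amplitude along the long axis, 0.01 mm
noise — a moderately ornamented shell at the scan resolution the section
size implies. `make_vgroove` is the deterministic extreme case: a
triangle-wave ridge field with crests on grid lines (no horizontal faces)
and, for 90°-multiple azimuths, exact permutation-matrix rotation, so the
orientation score is exactly ±100 by construction. `make_egg` emits five
zones (zone 1 = acute pole; half-open position intervals with 1.0 closed
into zone 5) × 6 sections by default — 30 per egg, the study-design
minimum — with per-zone parameter overrides for gradients along the egg.

What the generator does *not* emulate: global egg curvature within a
section (sections are flat discs), scanner noise spectra, taphonomic
cracks, pores, or texture. Passing tests therefore validate the geometry
and statistics pipeline, not scan acquisition; on real scans the DNE
outlier fraction and boundary rule matter more than they do here.

## Problem sizes in tests

Mesh-heavy tests use 6 vertices/mm sections (~5,650 faces, still above the
5000 standard) and 5-section eggs; the decimation contract is additionally
exercised once from ~20,000 faces. Statistical calibration uses 2,000 null
KS simulations, 500 bootstrap coverage pairs (n = 50, δ = 2) and 100 null
pairwise replicates. These sizes are the package's own regression-test
choices; all scale up linearly.

## Known limitations

* Decimation is plain Python; standardizing very large meshes (≫10⁵
  faces) to 5000 faces takes minutes, not seconds.
* `extract_section`'s tangent-plane membership assumes locally low relief;
  do not use it on strongly curved closed surfaces.
* The exact KS p-value inherits scipy's tie handling; heavily tied metric
  samples (possible after aggressive rounding) get a conservative p.
* The orientation score transform reproduces the published scale's
  behavior (bounded, signed, ratio-symmetric) but the original scripts may
  implement a different bounded map of the same ratio; the transform is
  isolated so it can be swapped without touching the binning.
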