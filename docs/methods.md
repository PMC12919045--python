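# Methods

`memkymo` converts a time-lapse fluorescence movie of a single cell, plus a
binary mask of that cell from any segmentation tool, into space-time
kymographs of membrane-proximal intensity. This note documents the model
behind each stage, the parameters that matter, the numerical conventions,
and what the synthetic-data tests do and do not establish.

## Coordinate and angle conventions

Pixels are addressed as (row = y, col = x), 0-based, with pixel centers at
integer coordinates. Polar angles about a boundary's centroid are computed
as `atan2(-(y - cy), x - cx)` mapped to [0, 360): 0° is image-right, 90°
image-up, 180° image-left. Boundary point lists run counter-clockwise in
this screen convention. These conventions matter because the user-facing
default of "anchor the first frame at 180°" is only meaningful once the
angle zero and handedness are fixed; both are asserted in tests.

## Boundary extraction

Each mask frame is padded by one background pixel on all sides (so cells
touching the border still close), traced with marching squares at iso-level
0.5 on the {0,1} field, and the closed contour enclosing the largest
shoelace polygon area is kept — one cell per mask is assumed; smaller
components are imaging artifacts. The contour is resampled to uniform arc
length with shape-preserving piecewise-cubic Hermite (PCHIP) interpolation
of y(s) and x(s); the closed curve is handled by duplicating a few knots
across the seam before fitting and cropping afterwards. PCHIP is used
because it cannot overshoot between knots, so a pixelated outline never
acquires spurious lobes. Finally a circular (wrap-around) moving average
smooths the coordinates.

Defaults: resampling spacing 0.5 px (two boundary points per pixel of
perimeter — matches the sampling grid below); smoothing window
`max(5, round(N/50))` forced odd, i.e. about 2% of the perimeter, so the
smoothing scale is proportional to cell size rather than absolute. Neither
value is critical; both are configurable. Smoothing follows interpolation
so the window is defined on an evenly spaced curve.

## Inter-frame alignment

Row identity over time is established by circular re-indexing only — no
elastic matching. Frame 0 is rotated so the point nearest the requested
start angle (default 180°) becomes index 0. Every later frame is aligned to
its predecessor by evaluating the mean Euclidean distance between
index-matched points for *all* N candidate circular shifts and keeping the
minimizer (ties: smallest shift, preferring temporal continuity). When
point counts differ, the longer boundary is decimated by a random subset
drawn once per frame pair from a seeded generator and reused for every
candidate shift, so the objective is deterministic and the reported
minimum is exactly reproducible; per-frame seeds are `rng_seed +
frame_index`. Distances are measured in raw image coordinates, so
translation is penalized uniformly across shifts; the alternative
(centroid-centered distances) would make alignment translation-invariant
but also blind to genuine drift, and is not offered.

A consequence worth knowing: the objective tracks lab-frame proximity. For
a nearly circular cell undergoing pure rigid rotation *with* independent
shape fluctuation, the minimum-distance shift tends to stay in the lab
frame rather than follow material rotation (the re-pairing cost ~r·Δθ
exceeds the shape-mismatch cost). For deforming, translating cells — the
intended regime — the minimization tracks the deforming outline well, as
the end-to-end synthetic tests show.

## Perpendicular sampling

At each boundary point the local normal comes from an algebraic
least-squares circle fit (Kåsa: minimize Σ(x² + y² + Dx + Ey + F)², a 3×3
linear system) to the 2·`fit_neighborhood`+1 surrounding points (default 5
per side). The normal is the unit vector from the fitted center to the
point; if the neighborhood is collinear (condition number > 1e12) the
fallback is the perpendicular of the secant through the two immediate
neighbors. The sign is normalized outward via the dot product with
(point − centroid) — the raw center-to-point vector flips at concavities.
Because the sampled segment spans both sides of the boundary
symmetrically, the membrane value is in fact invariant to this sign.

Intensities are sampled at `point + s·normal` for s from −`l_perp` to
+`l_perp` (default ±8 px) in steps of `spacing` (default 0.5 px; 33 samples
at defaults), by biquadratic (order-2) spline interpolation, which is exact
on linear intensity fields. Samples falling outside the image read from a
zero-padded field — conservative, since zeros can never enter the top-k.
The profile is reduced to the mean of its `top_k` (default 5) largest
values: robust to single-pixel noise and to where exactly the outline
crosses the fluorescent band. Per-point work is pure, so thread-parallel
execution (joblib) is bit-identical to serial.

## Kymograph assembly, smoothing, normalization

Per-frame profiles have varying length (the perimeter changes), so each is
resampled to a fixed row count by periodic linear interpolation on
normalized circular position u ∈ [0,1); the default row count is frame 0's
point count. This harmonization step is the one piece of pure plumbing in
the pipeline with no single canonical choice; periodic linear interpolation
was chosen as the least-structured option.

Each column (frame) is then smoothed along the spatial dimension with
LOWESS, bandwidth fraction 0.1 of the rows (statsmodels implementation,
default robustifying iterations). Columns are treated as linear sequences
by default, matching standard LOWESS; a `circular=True` option pads with
wrapped rows so the membrane seam is treated like any interior position
(the membrane is closed, but plain LOWESS only bias the few rows at the
seam, which is why non-circular remains the default).

Normalization anchors are the 2nd/98th percentiles (linear interpolation
between order statistics — stated explicitly because percentile
conventions differ) of the *raw*, pre-smoothing intensities pooled over
all frames of a channel. The smoothed matrix is rescaled to [0,1] on those
anchors and clipped. Anchoring on raw pooled percentiles keeps the display
range outlier-resistant and identical across smoothing choices; a
degenerate range (hi − lo < 1e-12) produces an all-zero matrix plus a
warning rather than dividing by zero.

## Correlation analysis

Two same-shape kymographs are compared column-by-column with Pearson r and
Spearman rho (Pearson on average-ranked data), with two-sided p-values from
the t-approximation on n−2 degrees of freedom (scipy implementations).
With zero-exclusion enabled, a pair of positions is dropped when *either*
channel reads exactly 0 — a zero in one channel alone already marks
background or genuinely absent signal. Frames with fewer than 3 retained
pairs or a constant retained vector are reported as NaN, never silently
as 0. Correlations default to the normalized matrices, but any matrix pair
is accepted.

## Rendering

Kymographs render with x = time (frames, or seconds if an acquisition
interval is supplied), y = membrane position, values mapped through
`clip((v − vmin)/(vmax − vmin), 0, 1)` and a colormap. The default
"parula" is a bundled 256-entry CSV lookup table built by interpolating
the widely reproduced 64-anchor parula values; any matplotlib colormap
name also resolves. Figures export as PNG (300 DPI), SVG, and/or PDF.
Stored matrices are never mutated by rendering, so display settings can be
adjusted and re-rendered from the saved `.npy` files alone.

## Synthetic movie generator

The generator emulates the input contract with full ground truth. The cell
is a star-shaped Fourier contour `r(φ,t) = R₀(1 + Σ aₘ(t)cos(mφ + φₘ))`
with seeded smoothly oscillating mode amplitudes (modes 2..4 by default,
total amplitude capped at 0.3·R₀ so the outline stays simple), optional
drift (px/frame along x) and rigid rotation (deg/frame). The mask is the
exact interior (ρ ≤ r); fluorescence is a band of width `band_width`
(default 3 px) straddling the outline, modulated by an angular pattern —
uniform, crescent (smooth-shouldered arc), traveling wave, or step
stimulus — over a constant background, plus Gaussian noise clipped at 0.

Defaults were chosen once to look like a typical confocal single-cell
recording: background 10, signal 100, noise σ 2 (SNR ≈ 45 on the band),
deformation amplitude 0.15, base radius ≈ ¼ of the image side. The
ground-truth "ideal kymograph" is parameterized by arc-length fraction
from the 180° anchor — the same coordinate an ideally aligned pipeline
produces — not by polar angle, which would disagree with arc-length row
spacing on deformed outlines.

What the generator does *not* model: point-spread-function blur, camera
shot/read noise, photobleaching, intensity gradients, segmentation errors
(the mask is exact), multiple cells, or topology changes. Passing the
end-to-end tests therefore demonstrates correctness of the geometry,
alignment, sampling, and normalization machinery under realistic motion —
not robustness to segmentation failure or optical artifacts.

## Problem sizes in the test suite

The shipped tests and the acceptance script regenerate everything at run
time: 50 random shapes of 100–500 points for shift recovery, 20
unequal-length pairs against the brute-force oracle, a 64-frame 256×256
traveling-wave movie (~800 boundary points/frame) for ground-truth
recovery, a 12-frame noiseless complementary pair, and a 16-frame step
stimulus. These sizes were chosen to exercise every code path at realistic
boundary lengths while keeping a full run in the tens of seconds.

## Known limitations

- One cell per mask; inner contours (holes) are ignored.
- Circular-shift alignment cannot express local slippage of membrane
  material along the outline, and under-tracks rigid rotation of
  near-circular cells (see above).
- Row harmonization assumes membrane material is distributed in proportion
  to arc length between frames.
- p-values are per-frame t-approximations with no multiple-testing
  correction across frames.
- No background subtraction, bleach correction, or deconvolution.
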