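# Methods

This note documents the models and numerical choices behind each
analysis stage, the assumptions of the synthetic-data generators, and
what the validation suite does and does not demonstrate about real
microscopy data.

## Coordinate and unit conventions

Image convention throughout: `x` rightward, `y` downward, `z` into the
stack; pixel indices are 0-based and a pixel's position is its center.
All geometry leaving the I/O layer is in µm. Parameters that the
measurement protocols specify in pixels — the 40-px reference box, the
6-px nuclear and 4-px cytoplasmic circles — are stored in pixels and
converted through the attached `PixelCalibration` at the point of use,
so the same configuration reproduces the protocol on any magnification.

## Clone dispersal

The statistic is the clone-mean of per-cell mean absolute separations,
decomposed on a time-varying extension axis after projecting along z.
Averaging per-cell means over cells equals averaging over unordered
pairs, so the two readings of "mean distance of each cell to all clone
cells" coincide; the implementation is vectorized and is checked
against an independent double-loop oracle in the tests.

*Axis model.* Tip anchors are linearly interpolated in time and held
constant beyond the anchored range; the axis direction is the planar
unit vector from the stable back anchor to the interpolated tip.
Linearity is the minimal assumption for anchors placed every ten
frames.

*Normalization.* "Relative to the initial time point" is implemented as
a ratio (the fold-change convention); a difference mode exists behind a
flag for sensitivity analysis. If a series is exactly zero at t0 (all
cells collinear along the other direction) the normalized series is NaN
with a warning rather than an error.

*Track hygiene.* Tracks must cover the whole analysis window;
single-frame gaps are filled by linear interpolation, longer gaps or
late starts exclude the track.

*Flow fixture.* The generator advects a compact clone by a
time-interpolated affine flow: offsets from the clone center are scaled
by `s_par**(k/(K-1))` axially and `s_perp**(k/(K-1))` perpendicularly —
the simplest flow consistent with reported endpoint fold changes, which
the dispersal statistic then recovers exactly in the noise-free case.
Defaults: 40 cells, 27 frames at 10 min (a 260 min window), wild-type
preset `s_par=2.02, s_perp=0.88`. The initial clone footprint radius is
50 µm: 40 labeled cells of ~12 µm diameter mixed loosely with unlabeled
neighbors occupy on the order of 100 µm, consistent with explant
dimensions (~300 µm across). Positional noise is Gaussian per
coordinate per frame.

*Tip-distance correlation.* The R² of normalized tip distances between
onset and end is exactly 1 only when the map between the two distance
sets is affine — e.g. for cells on the axis. For planar clones under
anisotropic flow the Euclidean tip distance mixes the two scale
factors, so even noise-free fixtures give R² slightly below 1 (≈0.996
for the wild-type preset).

## Signaling-gradient profiles

Order of operations: cytoplasmic background (mean of spot means) is
subtracted from raw channel means, the corrected value is divided by
the raw DAPI mean, distances to the reference contour (minimum over
reference points after z-projection; distance to the interpolated
polyline is available as an option) are normalized to the sample
maximum, and ratios are binned.

*Binning.* Half-open bins `[k·w, (k+1)·w)` with the last bin closed;
bin 0 anchored at the reference (high-intensity) side. Edge exclusion
removes the outer 4% of the axis at both ends: one bin per edge at
w=0.04 (explants), two at w=0.02 (embryos). Counts are retained for
excluded and empty bins, so counts always sum to the post-QC nucleus
count. Plotting from the low side is a presentation option; the stored
orientation is fixed.

*Control referencing.* The reference value is the control group's
high-side (bin 0) mean ratio, computed per replicate and averaged,
matching a design in which equal numbers of control and treated samples
are processed per replicate. Single-sample runs self-reference with a
logged notice.

*Depth attenuation.* Any multiplicative field applied equally to signal
and DAPI cancels in the ratio once the additive background has been
removed. This is exact in the noise-free model and is asserted to 1e-6;
on real data the cancellation is only as good as the assumption that
both channels attenuate identically.

*Top-decile position.* k = ceil(0.10·n) highest DAPI-normalized
intensities, ties at the k-th rank included (deterministic and logged).
Note a structural property: with exactly zero intensity noise the
ratio is a strictly decreasing function of distance for every decay
length, so the top decile is always the k nearest nuclei and the
statistic cannot distinguish decay lengths; discrimination requires
noise. Validation therefore runs this statistic at 10% intensity CV,
where the expected monotone increase with decay length holds (paired
common-random-number replicates).

*Decay estimation.* For exponential profiles the bin mean over
`[a, a+w)` is proportional to `exp(-a/λ)`, so ordinary least squares of
log bin mean on the bin's left edge has slope exactly `-1/λ`. Bins
below 5% of the profile maximum are excluded from the fit: clamping
corrected intensities at zero leaves a positive noise floor in far bins
that otherwise biases λ upward (severely so for short decays).

*Domain extent.* Nuclei are projected on the back→tip line; positivity
is `ratio > mean + 2·sd` of the far-quarter (low-signal) ratios unless
an explicit threshold or mask is supplied; the extent is the farthest
positive position (back-anchored pSmad5 domains) or the first positive
position (tip-anchored reporter domains), normalized by the line
length. Caveat: with unbounded Gaussian background noise, ~2.3% of
background nuclei exceed a mean+2sd threshold by construction, and the
"farthest position" reading is sensitive to such single outliers;
with real data, prefer an explicit threshold, a generous `n_sd`, or the
mask route when the background is heavy-tailed.

*Graded vs radial.* A profile is called graded when the first-three to
last-three reported-bin ratio is ≥ 2.0 and the Spearman trend is
negative with |ρ| ≥ 0.5; otherwise radial. Both statistics and both
thresholds are returned with every call, since the underlying visual
criterion has no canonical cutoff.

*QC.* Flagged nuclei (enveloping layer, yolk syncytial layer,
inhomogeneous DAPI, dividing) are input columns — these exclusions are
judgment calls made at the microscope, represented as data rather than
re-derived. Depth windows: ≤180 µm (explants), 60–120 µm (embryos).

*Detection.* The minimal difference-of-Gaussian detector exists so the
raster generators can be exercised end to end; it is not a replacement
for a production spot detector. Nuclei closer than the nuclear scale
merge into one detection (logged).

## Morphometrics

*Circularity.* 4πA/P² on the marching-squares boundary polygon after
Gaussian smoothing along the arc (σ = 2 px). Raw marching-squares
contours overestimate a disk's perimeter by ~5% (staircase facets);
smoothing brings the disk to C = 0.998 and a 400×100 rectangle to
C = 0.508 (exact: 0.5027). Values are clipped at 1.0.

*Extension detection.* The visual "clear indentation" criterion is
operationalized: concave pockets of the silhouette (convex hull minus
shape) qualify when their depth ≥ 15 µm and boundary turning angle ≥
40°; a silhouette is extended when two qualifying pockets flank a neck,
and the indentation point is the midpoint of their deepest points. A
manually supplied indentation point overrides detection and is logged.
Near-threshold pockets produce a "borderline" log entry.

*Extension length.* The midline is the skeleton-based principal path
between the extremal points of the silhouette along its principal axis
(extended straight to the true extrema); the normalized extension
length is the tip-to-indentation arc over the full arc.

*Geodesic shape profile.* Within-mask geodesic distances from the
central reference-box pixels, using 8-connected steps weighted 1 and
√2 (`skimage.graph.MCP_Geometric` on a uniform cost grid, which is
exactly that chamfer metric; tests verify exact agreement with an
independent Dijkstra oracle). Per axial station (default 1 px) the
maximum distance on the requested side is reported — the reconstructed
half-width. Side and station spacing are configuration, defaulting to
the left side and 1 px.

## Cell alignment

Orientation comes from the polygon's second-order area moments
(Green's-theorem closed forms), i.e. the moment-equivalent "best fit
ellipse" of standard raster toolchains; for a w×h rectangle the moment
aspect ratio is exactly w/h. Angles live in [-90°, 90°); deviations
from the tissue axis are folded into [0°, 90°] (orientations are
180°-periodic axial data). Aspect ratios below 1.05 are flagged
near-isotropic — the angle of an almost-circular cell is numerically
meaningless — and can be excluded by configuration.

The orientation generator draws axial angles by halving a von Mises
draw on the doubled angle, which makes concentration 0 exactly uniform
on [-90°, 90°) (mean deviation 45°) and large concentrations collapse
onto the mean angle.

Nuclear intensities are read in a 6-px-diameter circle at the nucleus
center, background in 4-px-diameter circles at five cytoplasmic
positions (inside the outline, outside the nuclear circle), drawn with
the run seed when not supplied and always recorded in the output.
Depth gates: 45–60 µm from the explant top, ≤37.5 µm from the
mesendoderm top in embryos.

## Statistical harness

Per-group normality uses D'Agostino–Pearson; groups with n < 8 fall
back to Shapiro–Wilk (the omnibus test needs a usable kurtosis
estimate). All groups normal → t-test (two groups) or one-way ANOVA;
otherwise Mann–Whitney or Kruskal–Wallis; paired designs use the paired
t-test or Wilcoxon signed-rank. Omnibus comparisons are followed by
pairwise post-hocs with Holm correction — chosen as the default because
it controls FWER uniformly more powerfully than Bonferroni with no
distributional assumptions; the correction is configurable. The
end-to-end select-then-test procedure holds its nominal size under the
Gaussian null (type-I error within [0.035, 0.065] at α = 0.05 over
2000 replicates in the validation suite). Test computations delegate to
`scipy.stats`; this module's contribution is the gating logic and
reporting.

## What the synthetic generators do and do not emulate

They reproduce the *statistical structure the measurements assume*:
affine clone advection with known endpoint anisotropy, monotone
gradients with shared-channel depth attenuation and additive
background, wrapped orientation distributions with known concentration,
Gaussian-blob nuclei with Poisson-Gaussian pixel noise. They do not
simulate cell intercalation mechanics, signaling dynamics, segmentation
errors, anisotropic PSFs, or tracking failures. Passing recovery tests
therefore demonstrates the correctness and noise behavior of the
estimators — not that any particular biological dataset meets the
estimators' assumptions.

## Problem sizes in the validation suite

Oracle checks use 200 random clones (≤12 cells) and masks up to 64×64;
recovery runs use 204 flow simulations (40 cells, 14 frames, 2 µm
noise), 300 gradient simulations (800 nuclei, 10% CV), replicate n=500
orientation fixtures, and 2000 null replicates for the type-I
calibration. These sizes put Monte-Carlo standard errors well inside
the asserted bands while keeping a full run in tens of seconds.
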