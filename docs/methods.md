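# Methods

This note documents the models, conventions and numerical choices behind
`retquant`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Particle segmentation and size statistics

**Moment-preserving threshold.** For a 256-bin intensity histogram with
normalized moments m₁, m₂, m₃, the bilevel image that preserves all three
moments has representative levels z₀ < z₁ (the roots of
z² + c₁z + c₀ = 0 with c₀ = (m₁m₃ − m₂²)/(m₂ − m₁²),
c₁ = (m₁m₂ − m₃)/(m₂ − m₁²)) and below-fraction
p₀ = (z₁ − m₁)/(z₁ − z₀). The returned threshold is the gray level whose
cumulative histogram is closest to p₀; when a run of levels ties (a flat
stretch of the cumulative distribution, e.g. between two well-separated
modes), the middle level of the run is returned so the threshold falls
between the modes rather than at one of them. A histogram with all its
mass in one bin has no bilevel split and raises a degenerate-histogram
error. Binarization is global over the whole stack (volumes are
thresholded once, not per slice); foreground is strictly greater than the
threshold, which makes the foreground voxel count non-increasing in the
threshold.

**Connectivity.** Components are labeled with 26-connectivity by default
(6 and 18 available): clusters are diffraction-blurred blobs, so diagonal
voxel contact is physical contact.

**Major diameter.** The diameter of a cluster is the maximum Euclidean
distance between member-voxel centers (3D max Feret) plus one quarter of
the mean voxel pitch, floored at one pitch for single-voxel clusters. The
additive term is a quantization correction: the endpoint voxel centers of
the maximal chord sit inside the true object surface, but because the
maximum is taken over many near-antipodal pairs the expected shortfall is
much smaller than a full per-endpoint voxel extent. Calibration on
noiseless voxelized spheres two to four voxels across (the regime of
sub-micron clusters at 0.283 µm/px) puts the shortfall near a quarter
pitch; a full-pitch term overshoots by most of a pitch and displaces the
250-nm size histogram by a whole bin, while no correction undershoots by
the same margin. Diameters recovered from noiseless synthetic spheres are
accurate to within one in-plane voxel diagonal (the quantization step of
the discrete chord).

**Minimum cluster size.** The full pipeline (`quantify_particles`) drops
components smaller than `min_voxels` (default 4). This is the standard
particle-analysis size gate: on a sparse bright-object histogram the
moment-preserving split necessarily lands in the tail of the background
noise (around 2.5–3 σ), so isolated supra-threshold noise voxels — and,
more rarely, 26-connected pairs and triples — would otherwise be counted
as clusters. Four-voxel noise components are already rare enough
(≲1 per 3·10⁶ voxels at the default noise level) not to bias counts. On
noiseless data there is nothing to reject and the gate can be set to 1;
the recovery tests do exactly that.

**Nearest-neighbor distances** use a k-d tree and are exact; an optional
periodic box turns on toroidal edge correction for spatial statistics
(used for the Poisson-process calibration: mean NND → 0.5/√λ).

**Coverage.** The spread of the particle carpet is the area of a boundary
polygon enclosing all foreground of the binarized Z-max projection,
divided by the ROI area. The boundary is an alpha shape parameterized by a
shrink factor in [0, 1]: Delaunay triangles are discarded from the largest
circumradius down to the (1 − shrink) circumradius quantile, but never so
far that a foreground point loses all its triangles, so the boundary
always encloses every point. Shrink 0 keeps every triangle (convex hull);
the default 0.5 tolerates concave carpets. The boundary polygon is
intersected with the ROI before the ratio, keeping coverage in [0, 100].

**Internalization** assigns a cluster to a compartment iff its centroid
voxel lies in the compartment mask. Centroid membership makes the counts
partition-exact: in- and out-percentages always sum to 100. Whether the
original analyses counted by centroid or by any-voxel overlap is not
derivable from their description; overlap counting would only differ for
clusters straddling the compartment boundary.

**Manders coefficients** default to area mode (binary overlap fractions),
matching the "area colocalizing" reading; intensity-weighted split
coefficients are available for parity with the common colocalization
plugins.

Coordinates are 0-based voxel indices; the physical position of index i is
(i + 0.5) × spacing; intervals are half-open.

## Sholl analysis and shape descriptors

The cell mask is skeletonized and dilated by one pixel (fixed radius), so
processes become 3-px-wide countable centerlines; intersections at radius
r are the maximal contiguous foreground arcs crossed by the circle of
radius r about the soma center, sampled at a 0.1-px arc step (a dilated
centerline cannot slip between samples at that density). Radii advance in
1-µm steps from the soma minor diameter. The profile is fitted by
least squares with N(r) = A·exp(−(ln r − µ)²/2σ²) (scipy curve_fit,
initialized at the empirical peak, σ₀ = 0.4, bounds A ≥ 0,
σ ∈ [10⁻⁴, 10]); at least 4 nonzero radii are required, and a
non-convergent or all-zero fit returns a failed-fit record with spans
undefined. The maximal branching span is the distal point where the fitted
curve reaches half its peak, exp(µ + σ√(2 ln 2)); the proximal crossing
and the full width are also reported because "half-width" is ambiguous
between the three readings, and the distal extent is the one that measures
a span. The radius step is interpreted as a radius (not circle-diameter)
increment; a flag (`step_um`) changes it.

**Circularity** is 4π·area/perimeter². Analytic polygons are measured
exactly from their vertices. Binary masks are polygonized by marching
squares at level 0.5 and simplified with Douglas–Peucker at a 0.8-px
tolerance before measuring: raw marching-squares contours overestimate the
perimeter of smooth shapes by ~5 % (staircase bias, which would push a
disk's circularity down to ~0.91), while the simplification leaves true
corners intact, so rasterized disks and rectangles both measure within
about 1 %. Circularity is never clipped in code.

**RPE mosaics.** Neighbors are cells sharing at least one pixel edge
(4-connected contact; diagonal-only contact does not count). Cells whose
region touches the field border — and their immediate neighbors, whose
counts are deflated by truncation — are flagged and excluded from neighbor
statistics and density (interior cells per field area). Per-cell area and
perimeter come from the simplified outer contour polygon; ellipse axes
from the second image moments.

## Electrophysiology

All filters are zero-phase (forward–backward Butterworth of order 4, plus
an IIR notch at Q = 30 for line rejection), so detected latencies carry no
group delay. Averages are pointwise means across sweeps after aligning
stimulus onsets by whole-sample shifts.

**VEP detection.** The response is the extremum of largest absolute
deviation from the pre-stimulus baseline mean in a 75–150 ms post-onset
search window (both polarities are searched: cortical VEPs invert across
depth); amplitude is peak-to-baseline, and a response is detected iff
amplitude exceeds k = 2 times the noise SD. The noise SD is estimated from
the single-sweep baselines before averaging (each trial's 100-ms
pre-stimulus segment, mean-centered per trial, pooled). This choice is
deliberate: thresholding the extremum of a ~75-sample search window at 2×
the SD of the *averaged* trace's own baseline fires on pure noise most of
the time (an extreme-value effect, ~80 % on the generator's 1/f noise),
whereas against the single-sweep noise scale an n-sweep average has √n
headroom — the null false-positive rate is below 10 % (measured ≈ 0) while
an evoked component comparable to the raw noise is detected reliably. The
averaged-trace baseline SD remains the fallback when no sweep information
exists, and both windows are configurable. Undetected responses report
amplitude and latency as absent (non-responders have no finite latency).

**Acuity** is the X-intercept, 10^(−intercept/slope), of an ordinary
least-squares fit of pattern-VEP amplitude against log10 spatial
frequency, using only frequencies with detected responses (undetected
frequencies are dropped, not entered as zeros); a non-negative slope
raises a no-decay error rather than extrapolating.

**Spectral Z.** Short-time power spectral density with a 60-ms Hann window
hopped every 5 ms (the spectral estimator's parameters are exposed; only
the 5-ms bin and the −0.1–0.4 s peristimulus window are fixed by the
procedure). Per frequency row, Z(t) = (P(t) − mean P₀)/SD P₀ with the
pre-stimulus interval as baseline (≥ 10 baseline bins required); rows with
zero baseline variance are NaN and flagged rather than infinite.

**Spiking.** PSTHs are spike counts in 10-ms bins averaged across trials
and converted to Hz. Firing-rate Z-scores smooth the rate with a centered
50-ms boxcar whose window shrinks at the edges (no padding), subtract the
baseline-window mean and divide by the baseline SD; the summary statistic
is the maximum Z in the 150–500 ms post-stimulus window. Units with mean
rate < 0.2 Hz are excluded; the boundary (exactly 0.2 Hz) is retained
because the exclusion is strict.

## Behavior

The OMR score is total concordant tracking time divided by total
discordant time at one spatial frequency; untracked ("neither") time
enters neither numerator nor denominator, since the ratio is defined over
movements. Zero discordant time makes the ratio undefined and is reported
as censored-high rather than infinite. Repeats of a frequency (at least 4)
are aggregated as the arithmetic mean of per-repeat scores; pooling
durations first is available behind a flag. Freezing is expressed as a
percentage of the session duration; the conditioning summary covers seven
CS–US pairings (learning curve), the cue test's 2-min dark and 3-min CS
sub-periods with their paired difference, and the 5-min context test, and
names any missing phase in its error.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the measurements
assume, with exact bookkeeping:

- **Particle stacks**: solid spheres with log-normal diameters
  (mode 0.85 µm, log-SD 0.25 — placing the modal 250-nm bin at
  0.75–1.0 µm), centers non-overlapping (separation ≥ sum of radii plus a
  1-µm margin) in a thin subretinal band, a rounded fraction (default
  30 % of 100 clusters) in the RPE band; center-sampled rasterization
  (voxel in sphere iff its center is within the radius) before an
  isotropic Gaussian PSF of σ = 0.05 µm; Gaussian noise (SD 2 % of the
  rendering amplitude) added after the blur. The field is 64 × 64 µm at
  0.283 µm/px with a 0.3-µm z-step — lateral sampling matches the source
  acquisitions; the PSF emulates deconvolved super-resolution confocal
  (~120 nm lateral FWHM), and the axial step is near-Nyquist for it.
  Noise statistics of real acquisitions are not published, so the noise
  defaults are plausible rather than calibrated. Not emulated: realistic
  (anisotropic, Airy) optics, pigment autofluorescence, tissue background,
  or section-to-section variability.
- **Microglia**: ramified cells as random binary trees of 1-px processes
  from a soma disk, true span = the maximum root-to-tip distance actually
  rasterized; ameboid cells as low-order-harmonic perturbed disks whose
  true circularity is computed analytically from the generating polygon.
- **RPE mosaics**: Voronoi tessellation of a jittered hexagonal lattice,
  rasterized by nearest-seed assignment; ground-truth neighbor counts are
  the Delaunay adjacencies. The requested cell count is rounded up to a
  full lattice.
- **Evoked recordings**: per-trial 1/f-amplitude background noise
  (spectrally shaped white noise, flat below 1 Hz) plus a stereotyped
  negative Gaussian deflection (default 100 µV — a typical flash-VEP
  scale — at 100 ms latency, 10-ms width); pattern-series amplitudes
  A(f) = −slope·(log₁₀ f − log₁₀ acuity) + noise, clipped at zero, so
  A(acuity) = 0 by construction.
- **Spikes**: piecewise-homogeneous Poisson (baseline rate outside the
  response window, baseline × gain inside).
- **Behavior**: state sequences realized as whole sample counts at 0.1-s
  resolution and randomly interleaved, so summed state durations equal the
  request exactly.

All draws come from one `numpy.random.default_rng(seed)` per call;
identical arguments give bit-identical outputs. Consequently, passing
tests demonstrate correctness of the *measurement procedures* under the
generator's assumptions — they do not validate segmentation against real
tissue appearance, detection against real cortical noise, or scoring
against real tracker output.

## Problem sizes and orchestration

The validation suite runs at desk scale, chosen to keep the statistical
margins decisive: 100-cluster stacks (~3·10⁶ voxels) for recovery; 50
seeded random instances per brute-force oracle (masks ≤ 8×14×14, clusters
≤ 200 voxels, Sholl at 0.1-px arc sampling); 10⁴ points for the
Poisson-NND limit; ≥ 500 Voronoi cells for the mean-neighbor limit;
100–300 seeds for acuity, span and null-rate calibrations.

The CLI (`retquant <stage>`) is a thin layer over the library: JSON config
with flag overrides, one recorded seed, and a manifest (parameters
materialized, input SHA-256 checksums, package version, timestamp) per
run; deterministic stages reproduce byte-identical CSVs from identical
config + seed. The `report` stage aggregates per-subject metrics into
group mean ± sem tables with individual values and computes no inferential
statistics.

## Known limitations

- The moment-preserving threshold assumes a genuinely bimodal gray-level
  mixture; on sparse bright objects it lands in the background-noise tail,
  which is why the size gate exists. Extremely dim clusters near the noise
  floor are not recoverable.
- The quarter-pitch diameter correction is calibrated for blob-like
  clusters a few voxels across; for filamentous or very large objects the
  max-Feret convention itself is the dominant approximation.
- Sholl counting requires a binary mask with the soma on foreground;
  automatic microglia segmentation from raw fluorescence is out of scope,
  as are CD68/Iba-1 classification, spike sorting, deconvolution,
  registration and video tracking.
- The acuity extrapolation is only defined for amplitude series that
  decay with spatial frequency; series censored below the noise floor at
  all but two frequencies give an exact two-point line with no redundancy.
- Alpha-shape coverage depends on the shrink parameter, whose value in the
  original boundary routine is unreported; shrink 0 (convex hull) is the
  reproducible reference point.
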