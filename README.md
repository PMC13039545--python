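# retquant

Quantification pipeline for experiments that restore vision in blind
retinas with subretinally injected photovoltaic nanoparticles. After such
an injection, the questions a lab needs answered quantitatively are: how
far did the particles spread and how are they sized and spaced; how many
were phagocytosed by the retinal pigment epithelium (RPE) or by microglia;
did the epithelium and the microglia change shape in response; and did
visual function return — in cortical evoked potentials, in single-unit
spiking, and in behavior. `retquant` implements the measurement procedures
for all of these, plus a synthetic-data generator that produces every
input class with exact ground truth, so the whole pipeline is testable
without any acquired data.

## What it computes

**Particle distribution** (`retquant.imaging`). Fluorescent nanoparticle
clusters are segmented from confocal Z-stacks by moment-preserving
("Moments") auto-thresholding — the threshold *t* preserves the first
three gray-level moments of the image when the histogram is split into a
below/above two-level mix — followed by 26-connected component labeling.
Per cluster: the major diameter (3D max Feret over voxel centers with a
quarter-pitch quantization correction), binned into 250-nm frequency
histograms; nearest-neighbor distances between centroids (mean NND is the
granularity of the carpet); percent of the retinal area covered, from the
boundary polygon (alpha shape; shrink 0 = convex hull) of the binarized
Z-max projection; percent of clusters internalized by a compartment
(centroid-in-mask); Manders split colocalization coefficients
M1 = |A∩B|/|A|, M2 = |A∩B|/|B|; and integrated fluorescence density over
ROIs on a sum projection.

**Cell morphometry** (`retquant.morphometry`). Sholl profiles (process
crossings of concentric circles at 1-µm radius steps, starting at the soma
minor diameter, counted on the skeletonized and dilated mask), fitted with
a log-normal curve N(r) = A·exp(−(ln r − µ)²/2σ²); the maximal branching
span is the distal half-maximum crossing, exp(µ + σ√(2 ln 2)). The
circularity index 4π·area/perimeter² (1 for a circle) classifies microglia
as ramified vs ameboid. RPE mosaics from labeled images: per-cell area,
perimeter, ellipse axes, circularity, 4-connected neighbor counts (border
ring excluded), and cell density.

**Electrophysiology** (`retquant.ephys`). Zero-phase Butterworth filtering
(0.1–100 Hz band-pass for pipette VEPs; 300-Hz low-pass + 50-Hz notch for
probe LFPs; 300 Hz–5 kHz for spike band); sweep averaging aligned on
stimulus onset; evoked-potential detection as the peak-to-baseline
extremum in a 75–150 ms post-onset window against 2× the single-sweep
noise SD, with onset-to-peak latency; visual acuity as the X-axis
intercept of the linear regression of pattern-VEP amplitude on log10
spatial frequency; spectral Z-score maps ((P(t) − P̄₀)/SD(P₀), 5-ms bins,
pre-stimulus baseline) over the −0.1–0.4 s peristimulus window; 10-ms
PSTHs over 50 trials; and the maximum Z of the 50-ms-smoothed firing rate
in the 150–500 ms response window, with units below 0.2 Hz mean rate
excluded.

**Behavior** (`retquant.behavior`). The optomotor response (OMR) score =
concordant / discordant tracking time (1.0 = indifference threshold), and
conditioned-freezing percentages per CS–US pairing, per cue sub-period
(2-min dark vs 3-min light CS) and for the 5-min context test.

**Synthetic data** (`retquant.synthetic`). Deterministic, seeded
generators for every input: clustered sub-micron puncta in a thin
subretinal layer (log-normal diameters, mode 0.85 µm; a chosen fraction
placed in the RPE band), ramified/ameboid microglia, hexagonal RPE
mosaics, evoked sweeps on 1/f noise, amplitude-vs-frequency series with a
known acuity cutoff, inhomogeneous Poisson spike trains, and state traces
with exact durations. Every generated object has one ground-truth row.

## Worked example

```python
import numpy as np
from retquant import synthetic, imaging

spec = synthetic.StackSpec(seed=1)                 # 64x64x18 um field, 100 clusters
stack, masks, truth = synthetic.generate_np_stack(spec)
report = imaging.quantify_particles(stack, "np", compartment_mask=masks["rpe"])

print(f"clusters detected:   {len(report.clusters)} (generated: {spec.n_clusters})")
print(f"modal diameter bin:  {report.histogram.modal_bin_um} um")
print(f"clusters < 2 um:     {100 * report.histogram.fraction_below(2.0):.1f} %")
print(f"mean NND:            {report.mean_nnd_um:.2f} um")
print(f"RPE internalization: {report.internalized_pct:.1f} % (generated: 30.0 %)")
```

prints

```
clusters detected:   100 (generated: 100)
modal diameter bin:  (0.75, 1.0) um
clusters < 2 um:     100.0 %
mean NND:            5.00 um
RPE internalization: 30.0 % (generated: 30.0 %)
```

The stack was generated with 100 clusters whose diameters have their mode
at 0.85 µm and with 30 % of the cluster centers inside the RPE band; the
pipeline recovers the count, the modal 250-nm diameter bin, the sub-2-µm
fraction and the internalized percentage, and reports the mean
nearest-neighbor spacing of the carpet.

The same stages are scriptable from the shell:

```
retquant simulate --out sim/ --seed 1
retquant particles --stack sim/stack.tif --rpe-mask sim/rpe_mask.tif --out run/
retquant vep --rec rec.h5 --out vep/
retquant behavior --omr traces.csv --out beh/
retquant report run1/ run2/ --metric internalized_pct --out summary/
```

Each run writes its outputs as CSV plus a JSON manifest (all parameters,
input checksums, package version, seed), so identical configs and seeds
reproduce byte-identical tables.

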