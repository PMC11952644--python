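# Methods

## Scope and model

`retfret` quantifies intracellular ATP in single retinal ganglion cells
from two-photon time series of a ratiometric FRET sensor. The measurement
model is deliberately minimal: the acceptor/donor emission ratio rises
monotonically with ATP and saturates near 10 mM; no absolute calibration to
millimolar units is attempted, and all downstream statistics live in the
ratio / z-score domain. The pipeline stages mirror standard practice for
in vivo 2-photon ratio imaging:

1. deinterleave the two detector channels from one multi-page TIFF;
2. subtract, per channel, one background scalar — the median over all
   (pixel, frame) samples in the scan-clipped corner regions;
3. motion-correct by subpixel phase correlation of the summed-channel
   frames against a running template, applying identical shifts to both
   channels (ratio-preserving by construction);
4. register acquisitions taken at different times with a similarity
   transform and map ROIs across sessions by exact one-to-one assignment;
5. segment somas on time-and-channel average projections (externally
   supplied label masks are ingested verbatim; the built-in fallback is
   LoG blob detection plus marker-based watershed);
6. extract per-frame per-channel ROI means, filter small/dim ROIs, smooth,
   form the ratio of means, and z-score against the baseline population.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `frame_rate` | 1.07 fps | raster-scan acquisition rate; converts frames to seconds |
| `corner_radius_px` | min(H,W)/8 | quarter-disc corner background regions (64 px at 512×512) |
| `smooth_window` | 20 frames | moving-average width for temporal noise |
| `min_pixels` | 100 | ROI area filter (boundary retained) |
| `min_sum_intensity` | 50 | time-average YFP+CFP filter (boundary retained) |
| `gate_px` | one soma radius | matching gate for cross-acquisition assignment |
| `sd_cut` | 5 | SD-below-baseline threshold for death/cleavage calls |
| `sd_mode` | population | baseline SD convention (ddof=0; sample SD via flag) |

Declared conventions where the procedure leaves room: the moving average is
centred with a symmetrically shrinking window at the edges (no phase lag in
event timing); for an even window the interior span is exactly `window`
samples, left-heavy by one. Channel means are smoothed before the ratio is
formed (`smoothing_domain="channel"`); smoothing the ratio trace directly
is available as an option. The baseline population pools all retained
cells over all baseline frames of one retina, and each retina is z-scored
to its own baseline — laser power and sensor expression differ between
eyes, so z-scores are only comparable within a retina. Quantiles in the
Q3 + 1.5·IQR rule use linear interpolation between order statistics. The
middle-60% z-slice selection takes k = round(0.6·n) slices starting at
⌊(n−k)/2⌋. Assignment ties are broken toward lower ROI ids; the assignment
itself is solved exactly (Hungarian), not greedily.

Where a published workflow uses interactive or learned tools (neural-
network segmentation, GUI landmark placement, manual track curation), this
package exposes equivalent headless contracts: plugin label images,
landmark CSV tables, and an override CSV that wins over automatic matches.

## Session registration

Rotation/scale between average projections is estimated by phase
correlation of log-polar-resampled Fourier magnitudes. Because the
magnitude spectrum is point-symmetric, the estimate is sign- and
180°-ambiguous and coarse (0.5° bins); the four candidate angles are scored
by central-crop intensity correlation after translation registration, and
the winner is refined by bounded scalar minimisation of that score (±1.5°,
0.01° tolerance). If fewer than three blob features are detectable in
either projection the rotation estimate is unreliable and the routine
falls back to translation-only phase correlation with a warning. Recovery
accuracy on synthetic fields is ≲0.01 px translation and ≲0.01° rotation;
the test suite requires 0.5 px / 0.2°.

## The synthetic scene generator

The generator is the package's ground-truth oracle, emulating the study
conditions: 512×512-class raster frames at 1.07 fps (tests use smaller
fields to the same recipe), somas as isotropic Gaussian discs (σ = r/2.5,
truncated at the footprint radius r ≈ 8 px), quarter-disc scan-clipped
corners carrying only background, rigid frame-to-frame drift, Poisson shot
noise with a gain plus Gaussian read noise, and per-type ATP set-points.
The ATP→ratio map is a Hill function r_min + (r_max−r_min)·Aʰ/(Kʰ+Aʰ) with
defaults (0.6, 6.0, K = 1 mM, h = 2.5) chosen only so the dynamic range
saturates within 1% of its ceiling near 10 mM; it is simulator
configuration, not a sensor calibration. Baseline set-points are truncated
normals (±2.5 SD) per type — baseline ATP distributions are approximately
normal, and untruncated tails in the saturating region of the sensor would
produce unphysical outliers. Defaults put α-family cells 0.8 within-type
SD (0.2 mM of 0.25 mM) below the other types.

Drug responses are piecewise exponentials per type (onset delay, decline
amplitude and time constant, optional recovery): complex I–III inhibitors
(ROT/TTFA/AA) get ~4× larger amplitudes in α/αON-S cells, complex IV
inhibition (KCN) a uniform large amplitude, circuit disinhibition (StrBic)
a uniform dip recovering toward baseline, and glutamatergic blockade
(NBQX/AP5) a slight delayed elevation. Repeat imaging redraws set-points
with day-to-day correlation 0.75 about the type mean — per-cell ATP is a
persistent but not frozen trait, which puts the pipeline's week-apart
test-retest correlation in the plausible 0.6–0.8 band; this stability
constant is a simulator choice. Immunostain volumes express markers by
true type (SPP1 for α, TBR2 for ipRGC, CART for ooDSGC, SPP1+TBR2 for
αON-S), warped by an invertible smooth deformation (affine plus bounded
sinusoidal displacement), with ≥4 landmark pairs emitted for registration.
Marker-positive types are deliberately minority fractions of the
population (8/5/15/15% vs 57% unlabeled), matching the regime the
within-image upper-quartile positivity rule presumes. The longitudinal
cohort generator works at trace level (measured ratio = true ratio with
~1% multiplicative noise): dying cells cleave on a random day ≥4 and
collapse to a fixed low ratio (z ≈ −10), survivors carry a configurable
baseline shift (default −0.5 population SD), and all living cells share a
Gaussian-in-days ATP elevation peaking at day 4.

What the generator does not emulate: optics/PSF blur, axial sectioning,
photobleaching, vasculature and glia, non-rigid within-frame motion, and
spectral bleed-through. Passing tests therefore certify the numerical
contracts of the pipeline and its recovery behaviour under the modelled
noise/drift regime, not robustness to every artefact of real retinas.

## Statistics

Group comparisons follow the named designs: pooled-variance two-sample
t-test (Welch optional), Wilcoxon rank-sum, one-way ANOVA with Tukey HSD,
and Kruskal-Wallis with Dunn's post hoc (joint-rank z statistics with tie
correction; Holm adjustment by default — adjusted p-values never fall
below raw). All tests are two-sided. Window summaries use
`numpy.trapezoid` over the frame times and divide by the realised window
duration, so a constant trace summarises to its own value exactly. Fate
classification is monotone in the SD cut, and excluding post-cleavage
frames provably cannot change pre-injury summaries (the exclusion flag
only ever applies from the death day onward).

## Degenerate inputs and numerical choices

Ratios are defined only where the donor mean is positive (NaN otherwise);
a zero-variance baseline raises rather than returning infinities; the IQR
discard rule skips all-equal populations (an all-equal image has no
outliers, though the positivity rule still scores all-equal as positive by
its ≥ comparison); cells spanning a single z-slice use that slice with a
warning; collinear landmark sets are rejected before the TPS solve.
Motion-correction shifts beyond a configurable maximum flag the frame
rather than warping it. The z-scored table keeps μ and σ in `attrs` so
later acquisitions of the same retina can reuse them.

## Problem sizes

Tests and the acceptance script run on scaled-down scenes chosen as the
package's own validation sizes: 96–320 px fields, 16–150 cells per retina,
40–150 frames per acquisition, 3 retinas for the type contrast, 100 seeded
runs for the perturbation ordering, 500-cell longitudinal cohorts, and
2,000 null replicates for test calibration. These sizes keep each property
estimable with comfortable margins while completing in minutes on one CPU.
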