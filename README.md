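# retfret

Single-cell ratiometric FRET quantification for in vivo two-photon ATP
imaging of retinal ganglion cells (RGCs).

Genetically encoded FRET ATP sensors report intracellular ATP as the ratio
of acceptor to donor emission (YFP/CFP ∝ [ATP]), and two-photon imaging
through the pupil makes that readout available per cell, in the living
retina, over days. Turning the raw movies into biology takes a long chain
of image processing: deinterleaving the two detector channels, subtracting
background measured in the scan-clipped frame corners, motion-correcting,
registering sessions taken minutes or days apart, segmenting somas,
matching the same cell across acquisitions, filtering unreliable ROIs,
smoothing, and normalising each cell's ratio to the baseline population.
`retfret` implements that chain as a tested, reusable library plus a set of
narrative analysis drivers, together with a ground-truthed synthetic scene
generator so every stage can be validated without microscope data.

## The quantification model

For each ROI *i* and frame *t*, the per-channel mean pixel intensities
Ȳᵢ(t), C̄ᵢ(t) (after background subtraction) give the FRET ratio as a
ratio of means, Rᵢ(t) = Ȳᵢ(t)/C̄ᵢ(t). Channel means are filtered with a
20-frame moving average before the ratio is formed; ROIs with fewer than
100 pixels or time-average YFP+CFP below 50 are discarded. Ratios are
z-scored against the baseline population of the same retina (pooled frames
of all retained cells):

    zᵢ(t) = (Rᵢ(t) − μ_baseline) / σ_baseline

Per-window summaries use the composite-trapezoid area under the z trace
divided by the window duration; ΔATP is the post window minus the pre
window; acute flux is max − min of z in a short window. Post hoc
immunostains are registered with a landmark thin-plate-spline warp; marker
positivity uses the within-image Q3 + 1.5·IQR rule (SPP1 → αRGC, TBR2 →
ipRGC, CART → ooDSGC, SPP1+TBR2 → αON-S). In longitudinal injury imaging,
apoptotic cleavage of the sensor collapses the ratio: a cell whose smoothed
z falls 5 SD below the pre-injury population mean (or that becomes
untrackable) is scored as dying and its post-cleavage frames are excluded
from ATP statistics.

## Layout

- `src/retfret/` — the library: `scene` (synthetic ground-truth scenes),
  `movie_io` (interleaved two-channel TIFF), `preprocess` (background,
  motion, session registration, smoothing), `segment` (soma ROIs, one-to-one
  matching, day tracking), `quant` (traces, filters, z-scores, window
  summaries), `histology` (TPS warp, IQR positivity, type calls, mito-IF),
  `survival` (fate calls, contrasts, day course), `stats` (t/rank-sum/
  ANOVA+Tukey/KW+Dunn, Pearson), `pipeline` + `cli` (orchestration;
  `retfret run --config run.json --seed N --out dir/`).
- `analysis/01…05` — numbered drivers that simulate cohorts and reproduce
  the analyses (baseline heterogeneity and test-retest, type contrasts,
  mitochondrial-inhibitor response, longitudinal survival), writing tables
  under `results/`.

## Worked example

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_baseline_heterogeneity.py
```

prints

```
baseline: 93 retained cells; population z mean 4.83e-16, sd 0.961
session registration: dy=-5.95 px dx=4.00 px rot=0.001 deg
test-retest: 90 cells matched across 7 days, Pearson R = 0.828 — per-cell ATP differences persist
```

The baseline population z-scores are centred by construction (mean ≈ 0);
the registration line shows the recovered session offset (the simulator
injected a (6, −4) px shift); and the Pearson R across one simulated week
says that a cell's standing in the ATP distribution is a stable trait of
that cell, not frame noise. Continuing with `03` (type contrasts after
immunostain registration) reports, e.g., mean baseline z of −0.72 for αRGCs
and −1.02 for αON-S versus +0.37/+0.36 for ipRGCs/ooDSGCs (ANOVA p = 0.008)
— α-type cells sit at a lower homeostatic ATP set-point. `04` shows
complex-I inhibition depleting α-family cells far more than others, and
`05` classifies simulated post-injury fates perfectly under the 5-SD rule
and recovers the injected lower-baseline-ATP-in-survivors effect.

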