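# focitrack

Quantification of DNA double-strand-break (DSB) repair foci in live-cell
time-lapse and fixed-cell fluorescence microscopy.

Ionizing radiation produces DSBs that cells mark with repair proteins such as
53BP1, visible as bright nuclear foci. Following individual foci over hours
reveals how breaks are processed: how many foci a nucleus carries over time,
how long each focus persists, how mobile the damaged chromatin is, and how
much repair protein accumulates per focus. In fixed cells, counting resection
marks (RPA foci) nested inside 53BP1 foci distinguishes single breaks from
clusters of closely interspaced breaks. `focitrack` implements this analysis
chain end to end, together with a synthetic-data generator with full ground
truth so every stage can be validated without microscope data.

## What it computes

**Adaptive segmentation.** Nuclei are found by automatic thresholding; foci
are segmented per frame with a calibrated adaptive threshold. A lower
threshold *L* chosen on the first frame fixes a dimensionless factor

```
factor = (L − mean₀) / sd₀          threshold_t = mean_t + factor · sd_t
```

where mean_t and sd_t are the mean and sample SD of the nuclear pixels of
frame *t*, so the cutoff follows global intensity drift (bleaching) without
re-tuning. Touching foci are split by watershed; each focus is measured
(area in µm², mean intensity, intensity-weighted center of mass in µm).

**Tracking.** Foci in consecutive frames are linked when their centers of
mass are closer than 0.7 µm (greedy nearest-first assignment; one-to-many and
many-to-one candidates are recorded as split/merge events). Tracks are
gap-free chains with duration = (n foci − 1) × Δt; with Δt = 20 min, a focus
present in all 51 frames of a 17-h acquisition gives 1000 min. Tracks are
binned by duration (20–80, 100–160, 180–240, 260–320, 340–400 min, overflow).

**Mobility.** Per duration group the time-averaged mean squared displacement
is computed, MSD(Δt) = ⟨r²⟩; for free 2D diffusion MSD = 4·D·Δt, so a
through-origin line y = a·t fitted to the first four points yields the
apparent diffusion coefficient D = a/4. Confined motion is detected as MSD
saturation bounded by (2·radius)².

**Distributions.** Per-focus intensity, area and total signal
(intensity × area) are summarized per frame and as Gaussian kernel density
estimates (bandwidths 6 / 0.3 / 220 respectively) whose area matches the
source histogram, with a peak-normalization factor anchored at t = 0.

**Colocalization.** In fixed two-channel images, S-phase nuclei are selected
by automatic threshold on an EdU channel, both channels are segmented per
nucleus, and each channel-B (RPA) focus is assigned to the channel-A (53BP1)
focus containing its center of mass, giving the fraction of A foci with
0 / 1 / >1 nested B foci.

## Worked example

`examples/04_confined_vs_free_motion.py` simulates 400 free tracks
(D = 0.005 µm²/min) and 300 tracks confined to a 0.5-µm disc, then runs the
MSD analysis:

```
free                 D_app=0.00504 um^2/min  shape=linear     max MSD=5.115 um^2
confined (r=0.5 um)  D_app=0.00069 um^2/min  shape=saturating max MSD=0.170 um^2
```

The free ensemble recovers the true diffusion coefficient within 1% and its
MSD is classified as linear; the confined ensemble plateaus far below the
geometric bound (2r)² = 1 µm² and is classified as saturating, with a much
smaller apparent D — confinement masks mobility. The other examples cover
simulation (`01`), adaptive-threshold segmentation (`02`), the full
segment–track–fit pipeline (`03`) and two-channel colocalization (`05`);
each prints the numbers it computes and what they mean.

A thin CLI mirrors the stages for shell use:

```
focitrack simulate --seed 1 --n-frames 51 --out run/
focitrack run --stack run/stack.tif --manual-threshold 95 --out run/analysis/
```

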