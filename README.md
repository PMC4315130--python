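# cishquant

Quantitation of chromogenic *in situ* hybridization (CISH) signal from
multispectral brightfield image cubes.

Visual grading of chromogen-stained tissue is notoriously unreliable when a
marker — here microRNA-92a in colorectal lesions — is expressed everywhere
at graded levels rather than all-or-nothing. This package implements the
alternative: acquire one grayscale image per wavelength across the visible
range (420–720 nm), convert transmitted intensity to optical density, unmix
each pixel into its dye contributions, and quantify the hybridization
signal objectively, per compartment, in OD units.

It is aimed at image-analysis and pathology-informatics users who want a
scriptable, testable version of the workflow that commercial multispectral
analyzers perform as a black box — and at methodologists who want a fully
synthetic test bed with known ground truth.

## The model

Under the Beer–Lambert law, a pixel containing NBT/BCIP (the indigo
hybridization chromogen) at amount $c_1$ and methyl green (the nuclear
counterstain) at amount $c_2$ transmits

$$I(\lambda) = I_0(\lambda)\, 10^{-[c_1 A_1(\lambda) + c_2 A_2(\lambda)]},$$

so the optical density $\mathrm{OD}(\lambda) = -\log_{10} I/I_0$ is linear
in the dye amounts. Per pixel, `cishquant` solves the non-negative least
squares problem $\min_{c \ge 0} \lVert A c - \mathrm{OD} \rVert^2$ against
peak-normalized reference spectra $A$.

Thresholding the two unmixed maps inside a region of interest (ROI) and
intersecting them partitions the signal into compartments:

- `total_signal_full` — summed NBT/BCIP amount over its mask;
- `total_signal_overlap` — the part co-localized with methyl green (nuclei);
- `signal_cyto = total_signal_full − total_signal_overlap` (cytoplasm);
- `avg_signal = total_signal / area_pixels` per compartment, their
  nucleus-to-cytoplasm ratio, and the expressed fraction of the ROI.

Each sample's mean OD is placed on a four-tier ordinal scale (negative ≤
0.377 < weak ≤ 0.5105 < moderate ≤ 0.68025 < strong positive, the quartile
cutoffs for the observed OD range 0.20825–0.9455; a data-derived quartile
scale is also available). Groups are compared with Welch's
unequal-variance *t*-test (Welch–Satterthwaite df, two-tailed), replicates
averaged to the sample level first; visual-grade/OD concordance is
summarized by Spearman's $r_s$ and an OLS slope.

A synthetic-data generator reproduces the six-group study design — lesion
stages LGIN, HGIN, CA and paralesional normal controls LGIN-N, HGIN-N,
CA-N with 10/11/13 and 9/10/12 samples, three technical replicates each —
as wavelength-stacked cubes with known ground truth, so the whole pipeline
is testable without any slide data.

## Worked example

```python
import numpy as np
import cishquant as cq

refs = cq.builtin_reference_spectra()           # synthetic NBT/BCIP + methyl green
scene = cq.simulate_scene(128, 128, n_cells=40, mean_cyto_od=0.62, mean_nuc_od=0.5,
                          overlap_fraction=0.3, seed=7)
cube = cq.render_cube(scene, refs, i0=4096, noise_model="poisson", seed=8)
maps = cq.unmix_cube(cq.compute_od_cube(cube), refs)

roi = np.ones((128, 128), bool)
nbt = cq.threshold_map(maps["NBT/BCIP"], roi, "absolute", 0.10)
mg  = cq.threshold_map(maps["methyl_green"], roi, "absolute", 0.10)
m = cq.compute_sample_metrics(maps, cq.colocalize(nbt, mg, roi))
```

prints (via the obvious f-strings):

```
mean OD           : 0.6185  (true replicate mean 0.62)
grade             : moderate
cytoplasm area    : 5098 px   nuclear overlap: 630 px
avg signal (cyto) : 0.6182  (nuc): 0.6206
N/C ratio         : 1.0039
ROI fraction      : 0.3496
```

The recovered mean OD matches the simulated ground truth to ~0.4% despite
Poisson shot noise, and 0.6185 falls in the *moderate* tier
(0.5106–0.68025). About 35% of the ROI carries signal, and the N/C ratio
near 1 reflects the configured 30% nuclear co-localization drawn from the
same cytoplasmic OD distribution.

## Command line

```sh
cishquant simulate --design default --seed 1 --out cohort/   # 195 cubes + manifest
cishquant run-all --manifest cohort/manifest.csv --out results/
cishquant unmix --cube cohort/CA-01_rep1.tif --out maps/
cishquant stats --metrics results/metrics.csv --alpha 0.05 --out results/
```

`run-all` writes `metrics.csv` (one row per sample-replicate),
`comparisons.csv` (all 15 pairwise Welch tests per metric, with raw and
Holm-adjusted p), `concordance.csv`, and a run log echoing every threshold
used.

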