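# embryostager

Quantitative analysis pipelines for the embryonic development of the
Mediterranean fruit fly (medfly, *Ceratitis capitata*), built around a
two-level staging system: six embryogenetic events — (I) blastoderm
formation, (II) early gastrulation, (III) germband elongation,
(IV) germband retraction, (V) dorsal closure, (VI) muscular movement —
partitioning seventeen stages (I: 1–5, II: 6–7, III: 8–11, IV: 12,
V: 13–15, VI: 16–17).

The package is aimed at developmental biologists working with long-term
fluorescence live-imaging recordings of nuclear-labelled embryos
(z-maximum projections and z stacks).  It quantifies:

* **Embryo length** over development: per frame, the length is the
  largest extension along the anterior–posterior axis *y* of the convex
  hull of the largest object after 3×3 mean smoothing and local-mean
  thresholding (150×150 window, pixels strictly above the windowed mean).
  Series are normalized to the initial length and to the fraction of
  development, and aggregated across embryos as mean ± sample SD on a
  common normalized-time grid.
* **Blastoderm nuclei area and density** in a posterior 150×150 px
  analysis window: Gaussian smoothing → local-mean threshold → hole
  filling → multi-scale Laplacian-of-Gaussian seeding → seeded immersion
  watershed on the inverted smoothed image → mask multiplication →
  border-object removal.  Across the 12th/13th synchronous division
  waves the mean projected nucleus area drops to about one third while
  density roughly quadruples.
* **Pole-cell nuclei in 3D**: stacks are de-rotated about *y* by
  per-dataset angles (−40°, −7°, +41°, +13°), LoG filtered, locally
  thresholded and watershed-partitioned; the object count is the number
  of germ-line precursor nuclei.
* **Germband-tip kinematics**: cumulative migration distance and speed
  from manually annotated tip positions.
* **Stage-duration statistics**: per-dataset stage tables, absolute and
  normalized durations, cross-dataset means and SDs, and the location of
  deviational peaks (boundaries with elevated inter-individual
  variability).

A synthetic-data generator renders embryo movies, nuclei windows,
tilted pole-cell stacks and jittered staging tables with exact ground
truth, so every pipeline is testable without downloading the original
recordings (deposited at Zenodo, DOI 10.5281/zenodo.13842879; run
`embryostager data` for the expected layout).

## Worked example

```python
import numpy as np
from embryostager import synth, length

def dip(t):                       # relative length, minimum 0.90 at 10 h
    return 1.0 - 0.10 * np.exp(-(((t - 10.0) / 2.5) ** 2))

spec = synth.SyntheticEmbryoSpec(rng_seed=1, length_trajectory=dip, n_frames=30)
frames, truth = synth.generate_embryo_movie(spec)   # (30, 512, 256) + truth

series = length.length_timeseries(frames, times_h=truth.times_h, dataset_id="SYN")
print(f"initial length {series.length_px[0]:.0f} px, "
      f"normalized minimum {series.normalized_length.min():.3f}")
```

prints

```
initial length 400 px, normalized minimum 0.900
```

the embryo starts at its full 400 px extent (semi-axis 200 px along *y*)
and the measured relative-length minimum recovers the generator's 0.90
dip — the same ~90 %-of-initial contraction seen during dorsal closure —
to three decimals.

The same pipelines run from the shell on TIFF/CSV inputs:

```sh
embryostager synth --out demo --seed 1        # synthetic demo dataset
embryostager length demo/movie.tif --out out  # lengths CSV + manifest
embryostager staging demo/stage_tables.csv --out out
```

Each run writes a JSON manifest (tool version, config hash, input
checksums, captured warnings); `--print-config` shows the effective
parameters, whose defaults encode the published analysis constants.

The numbered scripts under `analysis/` run the full study at synthetic
scale (data generation, length dynamics, nuclei division, pole cells,
tip kinematics, staging statistics) and write their tables to
`results/`.

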