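#!/usr/bin/env python
"""Generate the synthetic demonstration dataset.

Renders one embryo movie (with the dorsal-closure length dip), one nuclei
analysis window, one tilted pole-cell stack and five jittered staging
tables, all with exact ground truth.  TIFFs go to scratch/ (bulky,
regenerable); ground-truth tables go to results/.

Usage: python analysis/01_generate_data.py [--seed N]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from embryostager import synth
from embryostager.experiments import dip_trajectory
from embryostager.staging import write_staging_tables

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    scratch = ROOT / "scratch" / "synthetic"
    results = ROOT / "results"
    scratch.mkdir(parents=True, exist_ok=True)
    results.mkdir(exist_ok=True)

    spec = synth.SyntheticEmbryoSpec(
        rng_seed=args.seed, length_trajectory=dip_trajectory, n_frames=30)
    frames, truth = synth.generate_embryo_movie(spec)
    synth.write_movie(scratch / "embryo_movie.tif", frames)
    synth.write_ground_truth_lengths(results / "embryo_movie_truth.csv", truth)
    synth.write_spec(scratch / "embryo_movie_spec.yaml", spec)
    print(f"embryo movie: {spec.n_frames} frames, true length "
          f"{truth.lengths_px.min():.0f}-{truth.lengths_px.max():.0f} px")

    window, wtruth = synth.generate_nuclei_window(25, sigma=3.0, seed=args.seed + 1)
    synth.write_movie(scratch / "nuclei_window.tif", window[np.newaxis])
    pd.DataFrame(wtruth.centers, columns=["row", "col"]).assign(
        halfmax_area_px=wtruth.halfmax_areas_px
    ).to_csv(results / "nuclei_window_truth.csv", index=False)
    print(f"nuclei window: {wtruth.count} nuclei, "
          f"mean half-max area {wtruth.mean_halfmax_area:.1f} px^2")

    stack, struth = synth.generate_pole_cell_stack(
        27, cluster_radius=16.0, shape=(56, 64, 56), tilt_angle=40.0,
        seed=args.seed + 2)
    synth.write_movie(scratch / "pole_cells_tilted.tif", stack)
    print(f"pole-cell stack: {struth.count} nuclei, tilt {struth.tilt_angle} deg "
          f"(de-rotate with -40 deg)")

    tables, ttruth = synth.generate_stage_table(5, seed=args.seed + 3)
    write_staging_tables(tables, results / "stage_tables.csv")
    print(f"staging tables: {len(tables)} datasets, "
          f"total development {ttruth['mean_boundaries'][-1]:.1f} h")


if __name__ == "__main__":
    main()
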