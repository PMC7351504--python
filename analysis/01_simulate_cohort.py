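#!/usr/bin/env python
"""Simulate the synthetic study cohort and write it to disk.

Builds the phantom source atlas (6 spatial networks on a 32×40×32 grid at
3 mm, one of them a non-brain artifact source), simulates smoothed
structural maps for 100 patients and 70 controls with the planted cingulate
covariance difference, and writes per-subject NIfTI volumes, the subjects
table, and the ground-truth record.

The functional series are *not* persisted (a full 4D cohort is ~7 GB); the
downstream scripts regenerate them deterministically from the logged seeds.
"""

import argparse
from pathlib import Path

import numpy as np

from covnet import io as cio
from covnet.cohort import (CLINICAL_SPEC_HC, CLINICAL_SPEC_PD,
                           simulate_clinical_table, simulate_structural_cohort)
from covnet.phantom import make_phantom_sources
from covnet.preprocess import smooth_map


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    ap.add_argument("--n-pd", type=int, default=100)
    ap.add_argument("--n-hc", type=int, default=70)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    seeds = np.random.default_rng(args.seed).integers(0, 2**31 - 1, size=3)
    atlas = make_phantom_sources(seed=int(seeds[0]))
    stack, truth = simulate_structural_cohort(
        atlas, n_pd=args.n_pd, n_hc=args.n_hc, seed=int(seeds[1]))
    stack = np.stack([smooth_map(v, 6.0, atlas.voxel_mm) for v in stack])

    subjects = simulate_clinical_table({
        "PD": {"n": args.n_pd, "male_frac": 0.55, **CLINICAL_SPEC_PD},
        "HC": {"n": args.n_hc, "male_frac": 30 / 70, **CLINICAL_SPEC_HC},
    }, seed=int(seeds[2]))

    maps_dir = args.out / "dbm"
    maps_dir.mkdir(exist_ok=True)
    for i, row in subjects.iterrows():
        cio.save_volume(maps_dir / f"{row['id']}.nii.gz", stack[i],
                        atlas.voxel_mm)
    cio.save_table(args.out / "subjects.tsv", subjects)
    cio.save_volume(args.out / "brain_mask.nii.gz",
                    atlas.brain_mask.astype(float), atlas.voxel_mm)
    cio.save_maps_4d(args.out / "true_sources.nii.gz", atlas.flat_sources(),
                     np.ones(atlas.grid_shape, bool), atlas.voxel_mm)
    cio.save_json(args.out / "ground_truth.json", {
        **truth.to_dict(), "roles": list(atlas.roles),
        "atlas_seed": int(seeds[0]), "cohort_seed": int(seeds[1]),
    })
    print(f"wrote {len(subjects)} structural maps "
          f"({args.n_pd} PD + {args.n_hc} HC) to {args.out}")
    print("planted: rho_hc=0.6, rho_pd=0.1, cingulate shift -0.6 SD, sigma=0.5")


if __name__ == "__main__":
    main()
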