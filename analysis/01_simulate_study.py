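#!/usr/bin/env python
"""Simulate the observer study and a reduced imaging cohort.

Writes the full-scale reader study (157 cancer pairs, 40 complete
responders, 17 readers, sequential unaided/aided reads, per-reader repeat
subsets of 51 cases) as CSV tables under results/, and a 24-case imaging
cohort (paired pre/post lesion volumes with masks) as an NPZ archive under
scratch/ for the scoring steps 02-04.

Usage: python analysis/01_simulate_study.py [--seed 1] [--outdir results]
"""

import argparse
from pathlib import Path

from respcad import io, synthetic_data as sd

IMAGE_COHORT = dict(n_cases=24, n_t0=8, repeat_subset_size=10)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    args = ap.parse_args()

    cfg = sd.SyntheticStudyConfig(seed=args.seed)
    study = sd.simulate_study(cfg)
    io.write_ratings_csv(study.ratings, args.outdir / "ratings.csv")
    io.write_truth_csv(study.truth, args.outdir / "truth.csv")
    io.write_profiles_csv(study.profiles, args.outdir / "profiles.csv")
    io.write_scores_csv(study.cad_scores, args.outdir / "cad_scores_simulated.csv")
    rep = study.design.select(round="repeated", modality="unaided")
    print(
        f"Reader study: {cfg.n_cases} cancer pairs ({cfg.n_t0} T0), "
        f"{cfg.n_readers} readers, {len(study.ratings)} ratings; "
        f"repeat subsets of {rep.groupby('reader_id')['case_id'].nunique().mean():.0f} "
        "cases per reader."
    )

    img_cfg = sd.SyntheticStudyConfig(seed=args.seed + 1, **IMAGE_COHORT)
    cases, truth = sd.generate_case_pairs(img_cfg)
    io.write_cases_npz(cases, args.scratch / "image_cohort.npz")
    io.write_truth_csv(truth, args.outdir / "image_cohort_truth.csv")
    print(
        f"Imaging cohort: {len(cases)} case pairs at "
        f"{img_cfg.voxel_size_mm} mm voxels, shape {img_cfg.image_shape}, "
        f"written to {args.scratch / 'image_cohort.npz'}."
    )


if __name__ == "__main__":
    main()
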