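#!/usr/bin/env python
"""Fuse the DL and radiomics scores into 1-10 CAD scores.

Takes the per-case max of the two discriminant scores, evaluates the
combined score by ROC, fits the cohort-anchored affine map onto [1, 10],
and fits the per-class display densities.  Writes results/case_scores.csv
and results/cad_display_curves.json.

Run after analysis/02_score_dl.py and analysis/03_score_radiomics.py.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from respcad import cad_fusion as cf, io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    dl = pd.read_csv(args.outdir / "dl_scores.csv").set_index("case_id")
    rad = pd.read_csv(args.outdir / "radiomics_scores.csv").set_index("case_id")
    truth = io.read_truth_csv(args.outdir / "image_cohort_truth.csv")

    scores, scaler = cf.build_case_scores(
        dl["dl_score"].to_dict(), rad["radiomics_score"].to_dict()
    )
    io.write_scores_csv(scores, args.outdir / "case_scores.csv")
    labels = np.array([truth.responded_of(s.case_id) for s in scores])
    cad = np.array([s.cad_score for s in scores])
    disp = cf.fit_class_distributions(cad, labels)
    io.write_display_json(disp, args.outdir / "cad_display_curves.json")
    print(
        f"Fused {len(scores)} cases; CAD AUC "
        f"{cf.roc_auc([s.combined_score for s in scores], labels):.3f} "
        f"(affine map anchors {scaler.low:.3f} -> 1, {scaler.high:.3f} -> 10)."
    )


if __name__ == "__main__":
    main()
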