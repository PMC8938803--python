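#!/usr/bin/env python
"""MRMC analysis of the simulated observer study.

Compares reader-averaged AUC with and without CAD aid over all cases, then
by difficulty subset (SD-25 stratification on the radiologists' unaided
estimates), specialty, institution and proficiency.  Writes per-reader and
subgroup tables plus average ROC coordinates under results/.

Run after analysis/01_simulate_study.py.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from respcad import io, reader_analysis as ra


def _row(name, res, extra=None):
    out = {
        "group": name,
        "n_readers": res.n_readers,
        "auc_unaided": round(res.mean_auc_a, 3),
        "auc_aided": round(res.mean_auc_b, 3),
        "auc_gain": round(res.mean_auc_b - res.mean_auc_a, 3),
        "p_value": float(f"{res.p_value:.3g}"),
        "fixed_reader_inference": res.fixed_reader,
    }
    if extra:
        out.update(extra)
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument(
        "--group",
        choices=["difficulty", "specialty", "institution", "proficiency", "all"],
        default="all",
    )
    args = ap.parse_args()

    ratings = io.read_ratings_csv(args.outdir / "ratings.csv")
    truth = io.read_truth_csv(args.outdir / "truth.csv")
    profiles = io.read_profiles_csv(args.outdir / "profiles.csv")

    overall = ra.mrmc_compare(ratings, truth)
    per_reader = pd.DataFrame(
        {
            "reader_id": list(overall.reader_aucs_a),
            "auc_unaided": [round(v, 3) for v in overall.reader_aucs_a.values()],
            "auc_aided": [
                round(overall.reader_aucs_b[r], 3) for r in overall.reader_aucs_a
            ],
        }
    )
    per_reader.to_csv(args.outdir / "reader_aucs.csv", index=False)
    print(
        f"Overall ({overall.n_pos + overall.n_neg} cases, "
        f"{overall.n_readers} readers): mean AUC "
        f"{overall.mean_auc_a:.3f} unaided -> {overall.mean_auc_b:.3f} aided "
        f"(p = {overall.p_value:.3g})."
    )

    rows = [_row("all readers", overall)]
    groupings = (
        ["difficulty", "specialty", "institution", "proficiency"]
        if args.group == "all"
        else [args.group]
    )
    for grouping in groupings:
        if grouping == "difficulty":
            radiologists = [
                p.reader_id
                for p in profiles
                if p.specialty in ("abdominal radiologist", "radiology resident")
            ]
            part = ra.stratify_cases(ratings, radiologists)
            comp = part.class_composition(truth).set_index("subset")
            print(
                f"Stratification (SD threshold {part.threshold}): "
                f"{comp.loc['easy', 'n']} easy ({comp.loc['easy', 'n_t0']} T0), "
                f"{comp.loc['difficult', 'n']} difficult "
                f"({comp.loc['difficult', 'n_t0']} T0)."
            )
            res = ra.subgroup_mrmc(
                ratings, truth, profiles, "difficulty", partition=part
            )
            for name, r in res.items():
                rows.append(_row(f"{name} cases", r, {"grouping": grouping}))
        else:
            res = ra.subgroup_mrmc(ratings, truth, profiles, grouping)
            for name, r in res.items():
                rows.append(_row(name, r, {"grouping": grouping}))

    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "subgroup_mrmc.csv", index=False)
    print(table.drop(columns=["fixed_reader_inference"]).to_string(index=False))

    # pooled average ROC coordinates per modality, for plotting
    truth_map = dict(zip(truth.case_ids, truth.responded))
    curves = []
    for modality in ("unaided", "aided"):
        sub = ratings[
            (ratings.modality == modality) & (ratings["round"] == "original")
        ]
        labels = np.array([truth_map[c] for c in sub["case_id"]])
        fpr, tpr, _ = roc_curve(labels, sub["likelihood_t0"])
        curves.append(
            pd.DataFrame({"modality": modality, "fpr": fpr, "tpr": tpr})
        )
    pd.concat(curves).to_csv(args.outdir / "roc_coordinates.csv", index=False)


if __name__ == "__main__":
    main()
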