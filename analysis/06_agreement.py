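#!/usr/bin/env python
"""Intra- and inter-reader agreement of the simulated observer study.

Analyzes the repeat-read arm (each reader re-reads their own random case
subset): original-vs-repeated MRMC comparison per modality, Bland-Altman
bias/SD of the likelihood differences, and Krippendorff alphas (per-reader
test-retest, and 17-reader inter-observer over all cases).  Writes
results/agreement.csv and results/intra_reader_aucs.csv.

Run after analysis/01_simulate_study.py.
"""

import argparse
from pathlib import Path

import pandas as pd

from respcad import io, reader_analysis as ra


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    ratings = io.read_ratings_csv(args.outdir / "ratings.csv")
    truth = io.read_truth_csv(args.outdir / "truth.csv")

    rows = []
    auc_tables = []
    for modality in ("unaided", "aided"):
        res = ra.mrmc_compare(
            ratings, truth, (modality, "original"), (modality, "repeated")
        )
        ag = ra.agreement_summary(ratings, modality)
        rows.append(
            {
                "modality": modality,
                "auc_original": round(res.mean_auc_a, 3),
                "auc_repeated": round(res.mean_auc_b, 3),
                "p_original_vs_repeated": float(f"{res.p_value:.3g}"),
                "bland_altman_mean_bias": round(ag.mean_bias, 2),
                "bland_altman_mean_sd": round(ag.mean_sd, 2),
                "mean_intra_reader_alpha": round(ag.mean_intra_alpha, 3),
                "inter_reader_alpha": round(ag.inter_alpha, 3),
            }
        )
        table = ag.bland_altman_per_reader.copy()
        table["modality"] = modality
        table["alpha"] = table["reader_id"].map(ag.intra_alphas)
        auc_tables.append(table)
        print(
            f"{modality}: original vs repeated mean AUC "
            f"{res.mean_auc_a:.3f} / {res.mean_auc_b:.3f} "
            f"(p = {res.p_value:.3g}); Bland-Altman mean SD "
            f"{ag.mean_sd:.2f}; mean test-retest alpha "
            f"{ag.mean_intra_alpha:.3f}; inter-reader alpha "
            f"{ag.inter_alpha:.3f} "
            f"(satisfactory >= {ra.ALPHA_SATISFACTORY}, tentative floor "
            f"{ra.ALPHA_TENTATIVE_FLOOR})."
        )

    pd.DataFrame(rows).to_csv(args.outdir / "agreement.csv", index=False)
    pd.concat(auc_tables).to_csv(
        args.outdir / "intra_reader_aucs.csv", index=False
    )


if __name__ == "__main__":
    main()
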