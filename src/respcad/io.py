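"""Reading and writing the pipeline's on-disk artifacts.

Case fixtures go out as NIfTI volumes (one file per volume/mask) with a JSON
manifest, or as a compact NPZ archive for test speed.  Tabular artifacts
(ratings, profiles, truth, scores, features) are plain CSV; display curves
and selection reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cad_fusion import CadDisplay
from .types import CasePair, CaseScore, GroundTruth, ReaderProfile, validate_ratings

__all__ = [
    "write_cases_nifti",
    "read_cases_nifti",
    "write_cases_npz",
    "read_cases_npz",
    "write_ratings_csv",
    "read_ratings_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_scores_csv",
    "read_scores_csv",
    "write_display_json",
    "load_config_yaml",
]


def write_cases_nifti(
    cases: list[CasePair], outdir: str | Path, voxel_size_mm: float = 1.0
) -> Path:
    """One NIfTI per volume/mask plus a JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    manifest = []
    for case in cases:
        entry = {"case_id": case.case_id, "post_stage": case.post_stage}
        for part in ("pre_volume", "post_volume", "pre_mask", "post_mask"):
            arr = getattr(case, part)
            fname = f"{case.case_id}_{part}.nii"
            nib.save(
                nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
                outdir / fname,
            )
            entry[part] = fname
        manifest.append(entry)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_cases_nifti(manifest_path: str | Path) -> list[CasePair]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    cases = []
    for entry in json.loads(manifest_path.read_text()):
        arrays = {
            part: np.asarray(nib.load(root / entry[part]).dataobj)
            for part in ("pre_volume", "post_volume", "pre_mask", "post_mask")
        }
        cases.append(
            CasePair(
                case_id=entry["case_id"],
                pre_volume=arrays["pre_volume"],
                post_volume=arrays["post_volume"],
                pre_mask=arrays["pre_mask"] > 0.5,
                post_mask=arrays["post_mask"] > 0.5,
                post_stage=entry["post_stage"],
            )
        )
    return cases


def write_cases_npz(cases: list[CasePair], path: str | Path) -> Path:
    """Compact single-archive dialect of the case fixtures."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {
        "case_ids": np.array([c.case_id for c in cases], dtype="U16"),
        "post_stages": np.array([c.post_stage for c in cases], dtype="U4"),
    }
    for case in cases:
        arrays[f"{case.case_id}_pre_volume"] = case.pre_volume.astype(np.float32)
        arrays[f"{case.case_id}_post_volume"] = case.post_volume.astype(np.float32)
        arrays[f"{case.case_id}_pre_mask"] = case.pre_mask.astype(np.uint8)
        arrays[f"{case.case_id}_post_mask"] = case.post_mask.astype(np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def read_cases_npz(path: str | Path) -> list[CasePair]:
    with np.load(path) as data:
        cases = []
        for cid, stage in zip(data["case_ids"], data["post_stages"]):
            cases.append(
                CasePair(
                    case_id=str(cid),
                    pre_volume=data[f"{cid}_pre_volume"],
                    post_volume=data[f"{cid}_post_volume"],
                    pre_mask=data[f"{cid}_pre_mask"].astype(bool),
                    post_mask=data[f"{cid}_post_mask"].astype(bool),
                    post_stage=str(stage),
                )
            )
    return cases


def write_ratings_csv(ratings: pd.DataFrame, path: str | Path) -> Path:
    validate_ratings(ratings)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ratings.to_csv(path, index=False)
    return path


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    validate_ratings(frame)
    return frame


def write_truth_csv(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_frame().to_csv(path, index=False)
    return path


def read_truth_csv(path: str | Path) -> GroundTruth:
    frame = pd.read_csv(path)
    kwargs = {}
    if "pre_diameter_mm" in frame.columns:
        kwargs = {
            "pre_diameter_mm": frame["pre_diameter_mm"].to_numpy(),
            "post_diameter_mm": frame["post_diameter_mm"].to_numpy(),
        }
    return GroundTruth(
        case_ids=frame["case_id"].astype(str).to_numpy(dtype=object),
        responded=frame["responded"].to_numpy(dtype=bool),
        latent_difficulty=frame["latent_difficulty"].to_numpy(dtype=float),
        **kwargs,
    )


def write_profiles_csv(profiles: list[ReaderProfile], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "reader_id": p.reader_id,
                "specialty": p.specialty,
                "institution": p.institution,
                "proficiency": p.proficiency,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)
    return path


def read_profiles_csv(path: str | Path) -> list[ReaderProfile]:
    frame = pd.read_csv(path)
    return [
        ReaderProfile(
            reader_id=row.reader_id,
            specialty=row.specialty,
            institution=row.institution,
            proficiency=row.proficiency,
        )
        for row in frame.itertuples()
    ]


def write_scores_csv(scores: list[CaseScore], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "case_id": s.case_id,
                "dl_score": s.dl_score,
                "radiomics_score": s.radiomics_score,
                "combined_score": s.combined_score,
                "cad_score": s.cad_score,
            }
            for s in scores
        ]
    ).to_csv(path, index=False)
    return path


def read_scores_csv(path: str | Path) -> list[CaseScore]:
    frame = pd.read_csv(path)
    return [
        CaseScore(
            case_id=str(row.case_id),
            dl_score=row.dl_score,
            radiomics_score=row.radiomics_score,
            combined_score=row.combined_score,
            cad_score=row.cad_score,
        )
        for row in frame.itertuples()
    ]


def write_display_json(display: CadDisplay, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "grid": display.grid.tolist(),
                "t0_curve": display.t0_curve.tolist(),
                "gt0_curve": display.gt0_curve.tolist(),
            }
        )
    )
    return path


def load_config_yaml(path: str | Path) -> dict:
    """Raw study-configuration mapping from a YAML file."""
    return yaml.safe_load(Path(path).read_text())
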