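"""Core data containers shared across the scoring chain and the reader study.

The pipeline operates on paired pre/post-treatment lesion volumes with binary
tumor masks, produces per-case discriminant scores, and analyzes reader rating
tables.  Ratings are carried as :class:`pandas.DataFrame` objects with the
schema of :data:`RATING_COLUMNS`; the row-level :class:`ReaderRating` dataclass
documents that schema and is convertible to/from frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STAGES = ("T0", "T1", "T2", "T3", "T4")
MODALITIES = ("unaided", "aided")
ROUNDS = ("original", "repeated")
SPECIALTIES = (
    "abdominal radiologist",
    "radiology resident",
    "urologist",
    "oncologist",
    "medical student",
    "neurology fellow",
)
INSTITUTIONS = ("UM", "UI", "PSU", "TH")
PROFICIENCIES = ("experienced", "inexperienced")

#: specialties regarded as experienced in reading treatment response
EXPERIENCED_SPECIALTIES = frozenset(
    {"abdominal radiologist", "urologist", "oncologist"}
)

RECIST_CATEGORIES = (
    "progressive_disease",
    "stable_disease",
    "partial_response",
    "complete_response",
)

RATING_COLUMNS = [
    "reader_id",
    "case_id",
    "modality",
    "round",
    "likelihood_t0",
    "percent_response",
    "recist_category",
    "recommendation",
]

DESIGN_COLUMNS = ["reader_id", "case_id", "modality", "round"]


class InputError(ValueError):
    """Invalid input to a pipeline operation."""


class SizingError(ValueError):
    """A sampled lesion does not fit inside the configured image grid."""


@dataclass
class CasePair:
    """One cancer's pre/post-treatment volumes, masks and pathological outcome.

    ``post_stage`` is the pathological stage after chemotherapy; ``T0`` means
    no residual tumor (complete response).
    """

    case_id: str
    pre_volume: np.ndarray
    post_volume: np.ndarray
    pre_mask: np.ndarray
    post_mask: np.ndarray
    post_stage: str

    def __post_init__(self) -> None:
        if self.post_stage not in STAGES:
            raise InputError(f"unknown stage {self.post_stage!r}")
        for name in ("pre", "post"):
            vol = getattr(self, f"{name}_volume")
            mask = getattr(self, f"{name}_mask")
            if vol.shape != mask.shape:
                raise InputError(
                    f"case {self.case_id}: {name} mask shape {mask.shape} "
                    f"!= volume shape {vol.shape}"
                )
            if not np.any(mask):
                raise InputError(f"case {self.case_id}: empty {name} mask")

    @property
    def responded(self) -> bool:
        """True when the post-treatment pathological stage is T0."""
        return self.post_stage == "T0"


@dataclass
class GroundTruth:
    """Per-case reference standard: complete response and latent difficulty.

    ``latent_difficulty`` is a standard-normal per-case effect shared by all
    simulated readers; the rating model scales it by its case-effect SD.
    ``pre_diameter_mm``/``post_diameter_mm`` are optional and carry the maximum
    lesion diameters used to derive percent-response answers.
    """

    case_ids: np.ndarray
    responded: np.ndarray
    latent_difficulty: np.ndarray
    pre_diameter_mm: np.ndarray | None = None
    post_diameter_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.case_ids = np.asarray(self.case_ids, dtype=object)
        self.responded = np.asarray(self.responded, dtype=bool)
        self.latent_difficulty = np.asarray(self.latent_difficulty, dtype=float)
        n = len(self.case_ids)
        if len(self.responded) != n or len(self.latent_difficulty) != n:
            raise InputError("ground-truth arrays must have equal length")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_responders(self) -> int:
        return int(self.responded.sum())

    def responded_of(self, case_id: str) -> bool:
        idx = np.flatnonzero(self.case_ids == case_id)
        if idx.size != 1:
            raise InputError(f"unknown case_id {case_id!r}")
        return bool(self.responded[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "case_id": self.case_ids,
                "responded": self.responded,
                "latent_difficulty": self.latent_difficulty,
            }
        )
        if self.pre_diameter_mm is not None:
            frame["pre_diameter_mm"] = self.pre_diameter_mm
            frame["post_diameter_mm"] = self.post_diameter_mm
        return frame


@dataclass
class HybridROI:
    """A two-panel patch joining a pre- and a post-treatment tumor ROI.

    The canonical patch is 32x32 pixels: columns 0..15 come from the
    pre-treatment ROI, columns 16..31 from the post-treatment ROI.
    """

    pixels: np.ndarray
    case_id: str
    pre_slice_index: int
    post_slice_index: int
    label: bool

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[1] % 2 != 0:
            raise InputError(
                f"hybrid patch must be 2-D with even width, got {self.pixels.shape}"
            )


@dataclass
class CaseScore:
    """Per-case discriminant scores: DL, radiomics, their max, and 1-10 CAD."""

    case_id: str
    dl_score: float
    radiomics_score: float
    combined_score: float
    cad_score: float

    def __post_init__(self) -> None:
        if not np.isclose(
            self.combined_score, max(self.dl_score, self.radiomics_score)
        ):
            raise InputError(
                f"case {self.case_id}: combined_score must equal "
                "max(dl_score, radiomics_score)"
            )
        if not 1.0 - 1e-9 <= self.cad_score <= 10.0 + 1e-9:
            raise InputError(
                f"case {self.case_id}: cad_score {self.cad_score} outside [1, 10]"
            )


@dataclass
class ReaderProfile:
    """Reader metadata: specialty, institution and proficiency class."""

    reader_id: str
    specialty: str
    institution: str
    proficiency: str

    def __post_init__(self) -> None:
        if self.specialty not in SPECIALTIES:
            raise InputError(f"unknown specialty {self.specialty!r}")
        if self.institution not in INSTITUTIONS:
            raise InputError(f"unknown institution {self.institution!r}")
        expected = (
            "experienced"
            if self.specialty in EXPERIENCED_SPECIALTIES
            else "inexperienced"
        )
        if self.proficiency != expected:
            raise InputError(
                f"reader {self.reader_id}: proficiency {self.proficiency!r} "
                f"inconsistent with specialty {self.specialty!r}"
            )


def profiles_to_frame(profiles: Iterable[ReaderProfile]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in profiles])


@dataclass
class ReaderRating:
    """One reader's answers for one case under one modality and round."""

    reader_id: str
    case_id: str
    modality: str
    round: str
    likelihood_t0: float
    percent_response: float
    recist_category: str
    recommendation: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise InputError(f"unknown modality {self.modality!r}")
        if self.round not in ROUNDS:
            raise InputError(f"unknown round {self.round!r}")
        if not 0.0 <= self.likelihood_t0 <= 100.0:
            raise InputError("likelihood_t0 outside [0, 100]")
        if not -100.0 <= self.percent_response <= 100.0:
            raise InputError("percent_response outside [-100, 100]")


def ratings_to_frame(ratings: Iterable[ReaderRating]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(r) for r in ratings], columns=RATING_COLUMNS)
    validate_ratings(frame)
    return frame


def validate_ratings(frame: pd.DataFrame) -> None:
    """Check schema, scales and (reader, case, modality, round) uniqueness."""
    missing = set(RATING_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"rating frame missing columns {sorted(missing)}")
    if len(frame):
        if frame["likelihood_t0"].min() < 0 or frame["likelihood_t0"].max() > 100:
            raise InputError("likelihood_t0 outside [0, 100]")
        if (
            frame["percent_response"].min() < -100
            or frame["percent_response"].max() > 100
        ):
            raise InputError("percent_response outside [-100, 100]")
        if frame.duplicated(DESIGN_COLUMNS).any():
            raise InputError("duplicate (reader, case, modality, round) cells")


class StudyDesign:
    """Presence/absence of reader x case x modality x round observations.

    Supports non-fully-crossed designs such as the per-reader repeat-read
    subsets of the intra-reader arm.
    """

    def __init__(self, cells: pd.DataFrame):
        missing = set(DESIGN_COLUMNS) - set(cells.columns)
        if missing:
            raise InputError(f"design frame missing columns {sorted(missing)}")
        cells = cells[DESIGN_COLUMNS].drop_duplicates().reset_index(drop=True)
        self.cells = cells

    @classmethod
    def fully_crossed(
        cls,
        reader_ids: Sequence[str],
        case_ids: Sequence[str],
        modalities: Sequence[str] = MODALITIES,
        round: str = "original",
    ) -> "StudyDesign":
        idx = pd.MultiIndex.from_product(
            [list(reader_ids), list(case_ids), list(modalities), [round]],
            names=DESIGN_COLUMNS,
        )
        return cls(idx.to_frame(index=False))

    @property
    def reader_ids(self) -> list[str]:
        return sorted(self.cells["reader_id"].unique())

    @property
    def case_ids(self) -> list[str]:
        return sorted(self.cells["case_id"].unique())

    def select(self, **criteria: str) -> pd.DataFrame:
        out = self.cells
        for col, val in criteria.items():
            out = out[out[col] == val]
        return out

    def cases_of(self, reader_id: str, modality: str, round: str) -> list[str]:
        sub = self.select(reader_id=reader_id, modality=modality, round=round)
        return sorted(sub["case_id"].unique())

    def is_fully_crossed(self, modality: str, round: str) -> bool:
        sub = self.select(modality=modality, round=round)
        if sub.empty:
            return False
        counts = sub.groupby("reader_id")["case_id"].nunique()
        n_cases = sub["case_id"].nunique()
        return bool((counts == n_cases).all()) and len(counts) == len(
            self.reader_ids
        )

    def union(self, other: "StudyDesign") -> "StudyDesign":
        return StudyDesign(pd.concat([self.cells, other.cells], ignore_index=True))

    def __len__(self) -> int:
        return len(self.cells)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyDesign):
            return NotImplemented
        a = self.cells.sort_values(DESIGN_COLUMNS).reset_index(drop=True)
        b = other.cells.sort_values(DESIGN_COLUMNS).reset_index(drop=True)
        return a.equals(b)
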