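"""Synthetic study generator: lesion image pairs, CAD scores, reader ratings.

The generator emulates a multi-institution observer study of bladder-cancer
treatment response: 157 pre/post-chemotherapy cancer pairs from 123 patients
(40 pathological complete responders, T0; 117 with residual disease, >T0),
read by 17 physicians from 6 specialties and 4 institutions, first unaided and
then aided by a 1-10 CAD score, with a per-reader random subset (mean N = 51)
re-read for intra-reader analysis.

Lesions are axis-aligned ellipsoids with multiplicative, spatially smoothed
Gaussian texture; maximum diameters are lognormal with class-dependent means
(complete responders: 30.1 mm pre / 14.3 mm post; incomplete responders:
43.0 mm pre / 31.2 mm post).  Reader ratings follow a Roe-Metz-style latent
binormal model with additive case and reader-by-case effects; aided ratings
shrink the unaided rating toward the rescaled CAD score (a convex
combination), mirroring the sequential unaided-then-aided read design.

One global seed is expanded into per-stage substreams
(:class:`numpy.random.SeedSequence`) so the case, CAD and rating stages can be
regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import (
    MODALITIES,
    CasePair,
    CaseScore,
    GroundTruth,
    InputError,
    ReaderProfile,
    SizingError,
    StudyDesign,
    validate_ratings,
)

__all__ = [
    "TextureParams",
    "ReaderModel",
    "SyntheticStudyConfig",
    "default_reader_model",
    "default_reader_profiles",
    "generate_case_pairs",
    "simulate_cad_scores",
    "generate_reader_ratings",
    "sample_repeat_subsets",
    "simulate_study",
    "SimulatedStudy",
    "binormal_auc",
    "separation_for_auc",
]


@dataclass(frozen=True)
class TextureParams:
    """Lesion appearance for one class/timepoint.

    ``lesion_mean`` is the mean in-lesion intensity (arbitrary units),
    ``noise_sd`` the relative SD of the multiplicative texture, and
    ``smooth_sigma`` the Gaussian correlation length (voxels) of the texture.
    """

    lesion_mean: float
    noise_sd: float
    smooth_sigma: float


def _default_texture_params() -> dict[str, TextureParams]:
    # Responding tumors end up fainter and more homogeneous after treatment;
    # residual tumors keep their contrast and heterogeneity.
    return {
        "t0_pre": TextureParams(110.0, 0.22, 1.5),
        "t0_post": TextureParams(70.0, 0.08, 2.5),
        "gt0_pre": TextureParams(120.0, 0.25, 1.5),
        "gt0_post": TextureParams(115.0, 0.22, 1.5),
    }


def binormal_auc(separation: float, total_sd: float = 1.0) -> float:
    """Closed-form AUC of a latent binormal model with equal class SDs.

    ``separation`` is the latent class-mean difference, ``total_sd`` the SD of
    the latent score within each class; AUC = Phi(separation / (sd * sqrt 2)).
    """
    return float(stats.norm.cdf(separation / (total_sd * math.sqrt(2.0))))


def separation_for_auc(auc: float, total_sd: float = 1.0) -> float:
    """Inverse of :func:`binormal_auc`."""
    if not 0.0 < auc < 1.0:
        raise InputError("target AUC must be in (0, 1)")
    return float(stats.norm.ppf(auc) * total_sd * math.sqrt(2.0))


@dataclass
class ReaderModel:
    """Latent binormal rating model with reader and case effects.

    The latent unaided impression of reader ``r`` for case ``c`` is

        L_rc = a_r * y_c + sigma_c * d_c + sigma_e * e_rc

    with y_c the 0/1 truth, d_c ~ N(0,1) a shared per-case difficulty,
    e_rc ~ N(0,1) a reader-by-case term, and a_r = separation * skill_r.
    The unaided 0-100 rating is 100 * Phi(L_rc) plus round-specific rating
    noise (clipped); the impression L_rc is held fixed across rounds, so
    test-retest variability comes from the rating noise alone.  The aided
    rating is the convex combination

        (1 - w) * unaided + w * (100 * (cad - 1) / 9) + noise

    shrinking toward the rescaled CAD score with weight ``aid_weight``.
    """

    separation: float = 1.0
    skill_sd: float = 0.10
    case_sd: float = 0.60
    noise_sd: float = 0.80
    aid_weight: float = 0.35
    rating_noise_sd: float = 18.0
    aided_noise_sd: float = 4.0
    percent_noise_sd: float = 15.0
    cad_auc: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 <= self.aid_weight <= 1.0:
            raise InputError("aid_weight must lie in [0, 1]")
        for name in ("skill_sd", "case_sd", "noise_sd", "rating_noise_sd",
                     "aided_noise_sd", "percent_noise_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    @property
    def latent_sd(self) -> float:
        return math.sqrt(self.case_sd**2 + self.noise_sd**2)

    def unaided_auc_noise_free(self) -> float:
        """Closed-form mean unaided AUC ignoring rating noise and skill spread."""
        return binormal_auc(self.separation, self.latent_sd)

    # -- expected AUCs of the full model, by deterministic Monte Carlo -------

    def _mc_latents(self, n: int, rng: np.random.Generator):
        y = np.repeat([0.0, 1.0], n)
        lat = (
            self.separation * y
            + self.case_sd * rng.standard_normal(2 * n)
            + self.noise_sd * rng.standard_normal(2 * n)
        )
        return y.astype(bool), lat

    def expected_unaided_auc(self, n_mc: int = 200_000, seed: int = 0) -> float:
        """Mean single-reader unaided AUC including rating-noise degradation."""
        rng = np.random.default_rng(seed)
        y, lat = self._mc_latents(n_mc, rng)
        r = np.clip(
            100.0 * stats.norm.cdf(lat)
            + self.rating_noise_sd * rng.standard_normal(lat.size),
            0.0,
            100.0,
        )
        return _fast_auc(r, y)

    def expected_aided_auc(self, n_mc: int = 200_000, seed: int = 0) -> float:
        rng = np.random.default_rng(seed)
        y, lat = self._mc_latents(n_mc, rng)
        unaided = np.clip(
            100.0 * stats.norm.cdf(lat)
            + self.rating_noise_sd * rng.standard_normal(lat.size),
            0.0,
            100.0,
        )
        cad_sep = separation_for_auc(self.cad_auc)
        cad_latent = cad_sep * y + rng.standard_normal(lat.size)
        cad01 = stats.norm.cdf(cad_latent)
        cad_rescaled = 100.0 * cad01  # affine image of the 1-10 CAD score
        aided = np.clip(
            (1.0 - self.aid_weight) * unaided
            + self.aid_weight * cad_rescaled
            + self.aided_noise_sd * rng.standard_normal(lat.size),
            0.0,
            100.0,
        )
        return _fast_auc(aided, y)

    @classmethod
    def from_target_aucs(
        cls,
        unaided_auc: float = 0.73,
        aided_auc: float = 0.77,
        cad_auc: float = 0.80,
        n_mc: int = 200_000,
        **overrides,
    ) -> "ReaderModel":
        """Solve separation and aid weight so the model's expected mean
        unaided/aided AUCs hit the given targets (bisection on a fixed
        quasi-Monte-Carlo stream; deterministic)."""
        model = cls(cad_auc=cad_auc, **overrides)

        def f_sep(sep: float) -> float:
            return replace(model, separation=sep).expected_unaided_auc(n_mc) - unaided_auc

        sep = _bisect_increasing(f_sep, 0.01, 6.0)
        model = replace(model, separation=sep)

        def f_w(w: float) -> float:
            return replace(model, aid_weight=w).expected_aided_auc(n_mc) - aided_auc

        lo, hi = f_w(0.0), f_w(1.0)
        if lo >= 0:
            w = 0.0  # already above the aided target with no aid
        elif hi <= 0:
            w = 1.0
        else:
            w = _bisect_increasing(f_w, 0.0, 1.0)
        return replace(model, aid_weight=w)


@lru_cache(maxsize=1)
def default_reader_model() -> ReaderModel:
    """The default study conditions: separation and aid weight solved so the
    expected mean unaided/aided reader AUCs are 0.73/0.77 with CAD AUC 0.80."""
    return ReaderModel.from_target_aucs()


def _bisect_increasing(f, lo: float, hi: float, iters: int = 30) -> float:
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise InputError("target not bracketed by the model parameter range")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _fast_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise InputError("AUC undefined: only one class present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def default_reader_profiles() -> list[ReaderProfile]:
    """The 17-reader roster: 6 specialties across 4 institutions."""
    spec = [
        ("abdominal radiologist", "UM"),
        ("abdominal radiologist", "UM"),
        ("abdominal radiologist", "UM"),
        ("abdominal radiologist", "UM"),
        ("abdominal radiologist", "TH"),
        ("radiology resident", "UM"),
        ("radiology resident", "UM"),
        ("radiology resident", "UM"),
        ("radiology resident", "UM"),
        ("urologist", "UM"),
        ("oncologist", "UM"),
        ("oncologist", "UM"),
        ("oncologist", "UI"),
        ("oncologist", "UI"),
        ("oncologist", "PSU"),
        ("medical student", "PSU"),
        ("neurology fellow", "UM"),
    ]
    profiles = []
    for i, (specialty, inst) in enumerate(spec, start=1):
        prof = (
            "experienced"
            if specialty in {"abdominal radiologist", "urologist", "oncologist"}
            else "inexperienced"
        )
        profiles.append(
            ReaderProfile(f"R{i:02d}", specialty, inst, prof)
        )
    return profiles


@dataclass
class SyntheticStudyConfig:
    """Full study configuration; defaults are the simulated study conditions.

    ``diameter_means_mm`` holds the class-mean maximum diameters as
    (T0 pre, T0 post, >T0 pre, >T0 post).
    """

    n_cases: int = 157
    n_t0: int = 40
    n_readers: int = 17
    reader_profiles: list[ReaderProfile] = field(
        default_factory=default_reader_profiles
    )
    diameter_means_mm: tuple[float, float, float, float] = (30.1, 14.3, 43.0, 31.2)
    diameter_cv: float = 0.25
    voxel_size_mm: float = 2.0
    image_shape: tuple[int, int, int] = (40, 72, 72)
    background_mean: float = 40.0
    background_sd: float = 6.0
    texture_params: dict[str, TextureParams] = field(
        default_factory=_default_texture_params
    )
    reader_model: ReaderModel = field(
        default_factory=lambda: default_reader_model()
    )
    repeat_subset_size: int = 51
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_readers <= 0:
            raise InputError("counts must be positive")
        if not 0 <= self.n_t0 < self.n_cases:
            raise InputError("need 0 <= n_t0 < n_cases")
        if any(d <= 0 for d in self.diameter_means_mm):
            raise InputError("diameter means must be positive")
        if self.diameter_cv <= 0 or self.voxel_size_mm <= 0:
            raise InputError("diameter_cv and voxel_size_mm must be positive")
        if self.repeat_subset_size > self.n_cases:
            raise InputError("repeat_subset_size cannot exceed n_cases")
        if len(self.reader_profiles) != self.n_readers:
            # keep the roster consistent with n_readers: recycle or trim
            base = self.reader_profiles or default_reader_profiles()
            roster = []
            i = 0
            while len(roster) < self.n_readers:
                p = base[i % len(base)]
                roster.append(
                    ReaderProfile(
                        f"R{len(roster) + 1:02d}", p.specialty, p.institution,
                        p.proficiency,
                    )
                )
                i += 1
            self.reader_profiles = roster

    def substream(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage RNG derived from the global seed."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage_key,))
        )


# ---------------------------------------------------------------------------
# case-pair generation
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def _render_lesion(
    shape: tuple[int, int, int],
    diameter_mm: float,
    voxel_mm: float,
    params: TextureParams,
    background_mean: float,
    background_sd: float,
    rng: np.random.Generator,
    case_id: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one ellipsoidal lesion; returns (volume, mask)."""
    semi_axes_mm = np.array(
        [
            diameter_mm / 2.0 * rng.uniform(0.45, 0.85),  # z: fewer slices
            diameter_mm / 2.0,                            # longest axis in-plane
            diameter_mm / 2.0 * rng.uniform(0.65, 1.0),
        ]
    )
    semi_axes_vox = semi_axes_mm / voxel_mm
    center = np.array(shape) / 2.0 + rng.uniform(-3.0, 3.0, size=3)
    if np.any(center - semi_axes_vox < 0.5) or np.any(
        center + semi_axes_vox > np.array(shape) - 0.5
    ):
        raise SizingError(
            f"case {case_id}: lesion of diameter {diameter_mm:.1f} mm does not "
            f"fit inside image of shape {shape} at {voxel_mm} mm voxels"
        )
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    dist2 = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes_vox)
    )
    mask = dist2 <= 1.0
    volume = background_mean + background_sd * rng.standard_normal(shape)
    texture = ndimage.gaussian_filter(
        rng.standard_normal(shape), params.smooth_sigma
    )
    tex_sd = texture.std()
    if tex_sd > 0:
        texture /= tex_sd
    lesion = params.lesion_mean * (1.0 + params.noise_sd * texture)
    volume = np.where(mask, lesion, volume).astype(np.float32)
    return volume, mask


def _generate_truth(
    config: SyntheticStudyConfig, rng: np.random.Generator
) -> GroundTruth:
    """Draw labels, diameters and latent difficulties for all cases."""
    n, n_t0 = config.n_cases, config.n_t0
    labels = np.zeros(n, dtype=bool)
    labels[:n_t0] = True
    rng.shuffle(labels)

    d_t0_pre, d_t0_post, d_g_pre, d_g_post = config.diameter_means_mm
    pre_mean = np.where(labels, d_t0_pre, d_g_pre)
    ratio_mean = np.where(labels, d_t0_post / d_t0_pre, d_g_post / d_g_pre)

    pre_d = _lognormal(rng, 1.0, config.diameter_cv, size=n) * pre_mean
    ratio = _lognormal(rng, 1.0, config.diameter_cv, size=n) * ratio_mean
    ratio = np.where(labels, np.minimum(ratio, 0.95), ratio)
    difficulty = rng.standard_normal(n)
    return GroundTruth(
        case_ids=np.array([f"C{i + 1:03d}" for i in range(n)], dtype=object),
        responded=labels,
        latent_difficulty=difficulty,
        pre_diameter_mm=pre_d,
        post_diameter_mm=pre_d * ratio,
    )


def generate_case_pairs(
    config: SyntheticStudyConfig,
) -> tuple[list[CasePair], GroundTruth]:
    """Generate paired pre/post lesion volumes with masks and outcome labels.

    Deterministic for a fixed ``config.seed``.  Post-treatment diameters are
    generated as pre-treatment diameter times a lognormal shrink ratio whose
    mean preserves the configured class-mean post diameter; for complete
    responders the ratio is capped at 0.95 so the post lesion is smaller.
    """
    rng = config.substream("cases")
    truth = _generate_truth(config, rng)
    labels = truth.responded
    pre_d = truth.pre_diameter_mm
    post_d = truth.post_diameter_mm
    case_ids = truth.case_ids

    cases: list[CasePair] = []
    for i in range(config.n_cases):
        cls = "t0" if labels[i] else "gt0"
        pre_vol, pre_mask = _render_lesion(
            config.image_shape,
            float(pre_d[i]),
            config.voxel_size_mm,
            config.texture_params[f"{cls}_pre"],
            config.background_mean,
            config.background_sd,
            rng,
            str(case_ids[i]),
        )
        post_vol, post_mask = _render_lesion(
            config.image_shape,
            float(post_d[i]),
            config.voxel_size_mm,
            config.texture_params[f"{cls}_post"],
            config.background_mean,
            config.background_sd,
            rng,
            str(case_ids[i]),
        )
        stage = "T0" if labels[i] else str(rng.choice(["T1", "T2", "T3", "T4"]))
        cases.append(
            CasePair(
                case_id=str(case_ids[i]),
                pre_volume=pre_vol,
                post_volume=post_vol,
                pre_mask=pre_mask,
                post_mask=post_mask,
                post_stage=stage,
            )
        )
    return cases, truth


# ---------------------------------------------------------------------------
# CAD scores (simulated stand-in for the image-scoring chain)
# ---------------------------------------------------------------------------


def simulate_cad_scores(
    config: SyntheticStudyConfig, truth: GroundTruth
) -> list[CaseScore]:
    """Simulate per-case CAD scores from a latent binormal with the configured
    CAD AUC, for reader-study analyses that do not need the image chain.

    The DL and radiomics scores are set equal to the combined score (their
    max), and the 1-10 CAD score is the cohort-anchored affine image of the
    combined score.
    """
    rng = config.substream("cad")
    sep = separation_for_auc(config.reader_model.cad_auc)
    latent = sep * truth.responded.astype(float) + rng.standard_normal(
        truth.n_cases
    )
    combined = stats.norm.cdf(latent)
    lo, hi = combined.min(), combined.max()
    if hi - lo <= 0:
        raise InputError("degenerate simulated CAD cohort")
    cad = 1.0 + 9.0 * (combined - lo) / (hi - lo)
    return [
        CaseScore(
            case_id=str(cid),
            dl_score=float(c),
            radiomics_score=float(c),
            combined_score=float(c),
            cad_score=float(k),
        )
        for cid, c, k in zip(truth.case_ids, combined, cad)
    ]


# ---------------------------------------------------------------------------
# reader ratings
# ---------------------------------------------------------------------------


def _recist_category(percent: float) -> str:
    # RECIST 1.1-style mapping on the -100..100 response scale
    if percent >= 100.0:
        return "complete_response"
    if percent >= 30.0:
        return "partial_response"
    if percent <= -20.0:
        return "progressive_disease"
    return "stable_disease"


def generate_reader_ratings(
    config: SyntheticStudyConfig,
    truth: GroundTruth,
    cad: list[CaseScore],
    design: StudyDesign | None = None,
) -> tuple[pd.DataFrame, StudyDesign]:
    """Generate the reader-rating table for every cell of ``design``.

    With ``design=None`` a fully-crossed original-round design over both
    modalities is used.  Ratings follow :class:`ReaderModel`; the latent
    impression of a reader for a case is shared between rounds, so repeat
    reads differ only by rating noise.  Percent response is derived from the
    true lesion shrinkage plus reader noise, and the RECIST category and
    treatment recommendation follow from it and from the likelihood estimate.
    """
    model = config.reader_model
    reader_ids = [p.reader_id for p in config.reader_profiles]
    case_ids = [str(c) for c in truth.case_ids]
    cad_map = {s.case_id: s.cad_score for s in cad}
    missing = [c for c in case_ids if c not in cad_map]
    if missing:
        raise InputError(f"missing CaseScore for cases {missing[:5]}")

    if design is None:
        design = StudyDesign.fully_crossed(reader_ids, case_ids)

    rng = config.substream("ratings")
    R, N = len(reader_ids), len(case_ids)
    ridx = {r: i for i, r in enumerate(reader_ids)}
    cidx = {c: i for i, c in enumerate(case_ids)}

    skill = np.maximum(0.2, 1.0 + model.skill_sd * rng.standard_normal(R))
    y = truth.responded.astype(float)
    case_effect = model.case_sd * truth.latent_difficulty
    latent = (
        np.outer(skill * model.separation, y)
        + case_effect[None, :]
        + model.noise_sd * rng.standard_normal((R, N))
    )
    base_unaided = 100.0 * stats.norm.cdf(latent)  # (R, N), shared over rounds
    cad_rescaled = np.array(
        [100.0 * (cad_map[c] - 1.0) / 9.0 for c in case_ids]
    )

    # true shrinkage on the RECIST -100..100 response scale
    if truth.pre_diameter_mm is not None:
        shrink = 100.0 * (
            1.0 - np.asarray(truth.post_diameter_mm) / np.asarray(truth.pre_diameter_mm)
        )
    else:
        shrink = np.where(truth.responded, 55.0, 25.0)
    shrink = np.clip(shrink, -100.0, 100.0)

    # per (reader, case, round) rating noise; aided noise separate
    rounds = ("original", "repeated")
    eta = {rd: rng.standard_normal((R, N)) for rd in rounds}
    eta_aid = {rd: rng.standard_normal((R, N)) for rd in rounds}
    eta_pct = {rd: rng.standard_normal((R, N)) for rd in rounds}

    unaided = {
        rd: np.clip(base_unaided + model.rating_noise_sd * eta[rd], 0.0, 100.0)
        for rd in rounds
    }
    aided = {
        rd: np.clip(
            (1.0 - model.aid_weight) * unaided[rd]
            + model.aid_weight * cad_rescaled[None, :]
            + model.aided_noise_sd * eta_aid[rd],
            0.0,
            100.0,
        )
        for rd in rounds
    }
    percent = {
        rd: np.clip(
            shrink[None, :] + model.percent_noise_sd * eta_pct[rd], -100.0, 100.0
        )
        for rd in rounds
    }

    rows = []
    cells = design.cells
    for reader_id, case_id, mod, rd in zip(
        cells["reader_id"], cells["case_id"], cells["modality"], cells["round"]
    ):
        r, c = ridx[reader_id], cidx[case_id]
        lik = unaided[rd][r, c] if mod == "unaided" else aided[rd][r, c]
        pct = percent[rd][r, c]
        rows.append(
            (
                reader_id,
                case_id,
                mod,
                rd,
                float(lik),
                float(pct),
                _recist_category(pct),
                "radiation" if lik >= 50.0 else "surgery",
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "reader_id",
            "case_id",
            "modality",
            "round",
            "likelihood_t0",
            "percent_response",
            "recist_category",
            "recommendation",
        ],
    )
    validate_ratings(frame)
    return frame, design


def sample_repeat_subsets(
    design: StudyDesign, config: SyntheticStudyConfig
) -> StudyDesign:
    """Mark a per-reader uniform random subset of cases present in the
    'repeated' round (both modalities); subsets vary across readers.

    Returns the union of the base design and the repeat cells; deterministic
    for fixed ``config.seed``.
    """
    size = config.repeat_subset_size
    rng = config.substream("repeats")
    base = design.select(round="original")
    if base.empty:
        raise InputError("base design has no original-round cells")
    rows = []
    for reader_id in sorted(base["reader_id"].unique()):
        cases = sorted(
            base.loc[base["reader_id"] == reader_id, "case_id"].unique()
        )
        if size > len(cases):
            raise InputError(
                f"repeat subset size {size} exceeds reader {reader_id}'s "
                f"{len(cases)} cases"
            )
        chosen = rng.choice(np.array(cases, dtype=object), size=size, replace=False)
        for case_id in chosen:
            for modality in MODALITIES:
                rows.append((reader_id, case_id, modality, "repeated"))
    repeats = StudyDesign(
        pd.DataFrame(
            rows, columns=["reader_id", "case_id", "modality", "round"]
        )
    )
    return design.union(repeats)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """All artifacts of one simulated observer study."""

    config: SyntheticStudyConfig
    truth: GroundTruth
    cad_scores: list[CaseScore]
    ratings: pd.DataFrame
    design: StudyDesign
    profiles: list[ReaderProfile]
    cases: list[CasePair] | None = None


def simulate_study(
    config: SyntheticStudyConfig,
    include_images: bool = False,
    include_repeats: bool = True,
) -> SimulatedStudy:
    """Run the full generator: truth (+ optionally images), CAD scores,
    repeat-subset design and reader ratings."""
    if include_images:
        cases, truth = generate_case_pairs(config)
    else:
        cases = None
        truth = _generate_truth(config, config.substream("cases"))
    cad = simulate_cad_scores(config, truth)
    design = StudyDesign.fully_crossed(
        [p.reader_id for p in config.reader_profiles],
        [str(c) for c in truth.case_ids],
    )
    if include_repeats:
        design = sample_repeat_subsets(design, config)
    ratings, design = generate_reader_ratings(config, truth, cad, design)
    return SimulatedStudy(
        config=config,
        truth=truth,
        cad_scores=cad,
        ratings=ratings,
        design=design,
        profiles=config.reader_profiles,
        cases=cases,
    )
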