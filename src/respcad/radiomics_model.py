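"""Radiomics features, pre/post percent differences, and two-loop LOCO scoring.

Ninety-one features are computed inside the tumor mask of each scan:
first-order intensity statistics, gray-level co-occurrence (GLCM) features at
three distances, gray-level run-length (GLRLM) statistics, gray-level size-zone
(GLSZM) statistics, neighborhood gray-tone difference (NGTDM) features, 3-D
shape/size descriptors, and gradient-magnitude statistics.  Texture families
use a 32-bin equal-width quantization over the in-mask intensity range; GLCM
matrices aggregate 13 unique 3-D directions per distance, run lengths the three
axis directions, and size zones 26-connected components.

Each cancer is represented by the per-feature percent difference between its
post- and pre-treatment scans, 100 * (post - pre) / |pre|, with a documented
epsilon/cap rule for near-zero denominators.  The classifier is built with a
two-loop leave-one-case-out scheme: the outer loop holds out one case; the
inner loop performs greedy forward feature selection maximizing inner-LOCO AUC
(a fast linear-discriminant candidate scorer by default) and then trains a
random forest on the outer training cases with the selected subset.  The
held-out case influences neither selection nor training (hard assertion).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier

from .types import CasePair, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureError",
    "FeatureVector",
    "TwoLoopConfig",
    "TwoLoopResult",
    "feature_names",
    "extract_features",
    "percent_difference",
    "case_feature_table",
    "two_loop_loco",
    "two_loop_loco_features",
]

N_BINS = 32
MIN_MASK_VOXELS = 10
GLCM_DISTANCES = (1, 2, 3)

_GLCM_FAMILY = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "correlation",
    "entropy",
    "cluster_shade",
    "cluster_prominence",
)
_GLRLM_FAMILY = (
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv",
)
_GLSZM_FAMILY = (
    "sae", "lae", "gln", "zsn", "zp",
    "lgze", "hgze", "salge", "sahge", "lalge", "lahge", "glv", "zv",
)
_NGTDM_FAMILY = ("coarseness", "contrast", "busyness", "complexity", "strength")
_FO_FAMILY = (
    "mean", "median", "sd", "variance", "skewness", "kurtosis",
    "min", "max", "range", "p10", "p25", "p75", "p90", "iqr",
    "energy", "entropy", "uniformity",
)
_SHAPE_FAMILY = (
    "voxel_count", "volume_mm3", "surface_area_mm2", "sphericity",
    "compactness", "max_diameter_mm", "major_axis_mm", "minor_axis_mm",
    "least_axis_mm", "elongation", "flatness", "extent", "surface_to_volume",
)
_GRAD_FAMILY = ("mean", "sd", "skewness", "kurtosis", "energy", "entropy")


class FeatureError(ValueError):
    """Feature extraction is impossible on this input."""


@dataclass
class FeatureVector:
    """Ordered feature names and values for one scan (or one case's
    percent-difference representation)."""

    case_id: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise InputError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise InputError("feature names must be unique")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def feature_names() -> list[str]:
    """The 91-name registry, in extraction order."""
    names = [f"fo_{n}" for n in _FO_FAMILY]
    for d in GLCM_DISTANCES:
        names += [f"glcm_d{d}_{n}" for n in _GLCM_FAMILY]
    names += [f"glrlm_{n}" for n in _GLRLM_FAMILY]
    names += [f"glszm_{n}" for n in _GLSZM_FAMILY]
    names += [f"ngtdm_{n}" for n in _NGTDM_FAMILY]
    names += [f"shape_{n}" for n in _SHAPE_FAMILY]
    names += [f"grad_{n}" for n in _GRAD_FAMILY]
    assert len(names) == 91 and len(set(names)) == 91
    return names


# ---------------------------------------------------------------------------
# quantization and texture matrices
# ---------------------------------------------------------------------------


def _quantize(volume: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width quantization of in-mask intensities to 0..n_bins-1;
    -1 outside the mask."""
    quant = np.full(volume.shape, -1, dtype=np.int32)
    vals = volume[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        levels = np.minimum(
            ((vals - lo) / (hi - lo) * n_bins).astype(np.int32), n_bins - 1
        )
    else:
        levels = np.zeros(vals.shape, dtype=np.int32)
    quant[mask] = levels
    return quant


_DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _offset_slices(offset):
    src, dst = [], []
    for o in offset:
        if o >= 0:
            src.append(slice(0, None if o == 0 else -o))
            dst.append(slice(o, None))
        else:
            src.append(slice(-o, None))
            dst.append(slice(0, o))
    return tuple(src), tuple(dst)


def glcm_matrix(
    quant: np.ndarray, mask: np.ndarray, distance: int, n_bins: int = N_BINS
) -> np.ndarray:
    """Symmetric, direction-aggregated 3-D co-occurrence matrix (normalized)."""
    P = np.zeros((n_bins, n_bins))
    for direction in _DIRECTIONS_13:
        offset = tuple(d * distance for d in direction)
        src, dst = _offset_slices(offset)
        a = quant[src]
        b = quant[dst]
        valid = (a >= 0) & (b >= 0)
        if valid.any():
            np.add.at(P, (a[valid], b[valid]), 1.0)
    P = P + P.T
    total = P.sum()
    if total > 0:
        P /= total
    return P


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    if P.sum() == 0:
        return {name: 0.0 for name in _GLCM_FAMILY}
    pi = P.sum(axis=1)
    mu = float((np.arange(n) * pi).sum())
    var = float(((np.arange(n) - mu) ** 2 * pi).sum())
    diff2 = (i - j) ** 2
    feats = {
        "contrast": float((P * diff2).sum()),
        "dissimilarity": float((P * np.abs(i - j)).sum()),
        "homogeneity": float((P / (1.0 + diff2)).sum()),
        "energy": float((P**2).sum()),
        "entropy": float(-(P[P > 0] * np.log2(P[P > 0])).sum()),
        "cluster_shade": float((P * (i + j - 2 * mu) ** 3).sum()),
        "cluster_prominence": float((P * (i + j - 2 * mu) ** 4).sum()),
    }
    if var > 0:
        feats["correlation"] = float(((P * i * j).sum() - mu**2) / var)
    else:
        feats["correlation"] = 1.0
    return feats


def glrlm_runs(quant: np.ndarray, n_bins: int = N_BINS):
    """Run values and lengths along the three axis directions.

    Out-of-mask voxels break runs.  Returns (values, lengths) arrays.
    """
    all_vals, all_lens = [], []
    for axis in range(quant.ndim):
        lines = np.moveaxis(quant, axis, -1).reshape(-1, quant.shape[axis])
        # sentinel column breaks runs between lines
        flat = np.concatenate(
            [lines, np.full((lines.shape[0], 1), -2, dtype=lines.dtype)], axis=1
        ).ravel()
        boundaries = np.flatnonzero(np.diff(flat) != 0)
        starts = np.concatenate([[0], boundaries + 1])
        ends = np.concatenate([boundaries, [flat.size - 1]])
        vals = flat[starts]
        lens = ends - starts + 1
        keep = vals >= 0
        all_vals.append(vals[keep])
        all_lens.append(lens[keep])
    return np.concatenate(all_vals), np.concatenate(all_lens)


def _run_or_zone_features(
    vals: np.ndarray, sizes: np.ndarray, n_voxels: int, n_directions: int,
    names: tuple,
) -> dict[str, float]:
    """Shared GLRLM/GLSZM statistics over (gray level, run/zone size) pairs."""
    out = {name: 0.0 for name in names}
    n = vals.size
    if n == 0:
        return out
    g = vals.astype(float) + 1.0  # 1-based gray level
    s = sizes.astype(float)
    out[names[0]] = float(np.mean(1.0 / s**2))          # short emphasis
    out[names[1]] = float(np.mean(s**2))                # long emphasis
    out[names[2]] = float(np.bincount(vals).astype(float).__pow__(2).sum() / n)
    out[names[3]] = float(
        np.unique(sizes, return_counts=True)[1].astype(float).__pow__(2).sum() / n
    )
    out[names[4]] = float(n / (n_directions * n_voxels))
    out[names[5]] = float(np.mean(1.0 / g**2))
    out[names[6]] = float(np.mean(g**2))
    out[names[7]] = float(np.mean(1.0 / (s**2 * g**2)))
    out[names[8]] = float(np.mean(g**2 / s**2))
    out[names[9]] = float(np.mean(s**2 / g**2))
    out[names[10]] = float(np.mean(s**2 * g**2))
    out[names[11]] = float(np.mean((g - g.mean()) ** 2))
    out[names[12]] = float(np.mean((s - s.mean()) ** 2))
    return out


def glszm_zones(quant: np.ndarray, mask: np.ndarray, n_bins: int = N_BINS):
    """Gray level and size of every 26-connected same-level zone."""
    structure = np.ones((3, 3, 3), dtype=int)
    vals, sizes = [], []
    for level in range(n_bins):
        binary = (quant == level) & mask
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary, structure=structure)
        counts = np.bincount(labeled.ravel())[1:]
        vals.extend([level] * n)
        sizes.extend(counts.tolist())
    return np.asarray(vals, dtype=np.int64), np.asarray(sizes, dtype=np.int64)


def _ngtdm_features(
    quant: np.ndarray, mask: np.ndarray, n_bins: int = N_BINS
) -> dict[str, float]:
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    maskf = mask.astype(float)
    qm = np.where(mask, quant, 0).astype(float)
    nbr_sum = ndimage.convolve(qm * maskf, kernel, mode="constant")
    nbr_cnt = ndimage.convolve(maskf, kernel, mode="constant")
    valid = mask & (nbr_cnt > 0)
    out = {name: 0.0 for name in _NGTDM_FAMILY}
    nv = int(valid.sum())
    if nv == 0:
        return out
    avg = nbr_sum[valid] / nbr_cnt[valid]
    lv = quant[valid]
    diffs = np.abs(lv - avg)
    n_i = np.bincount(lv, minlength=n_bins).astype(float)
    s_i = np.bincount(lv, weights=diffs, minlength=n_bins)
    p_i = n_i / nv
    present = np.flatnonzero(p_i > 0)
    levels = np.arange(n_bins, dtype=float)
    ps = float((p_i * s_i).sum())
    out["coarseness"] = float(1.0 / ps) if ps > 0 else 1e6
    if present.size > 1:
        ii, jj = np.meshgrid(present, present, indexing="ij")
        pij = p_i[ii] * p_i[jj]
        d2 = (levels[ii] - levels[jj]) ** 2
        ngp = present.size
        out["contrast"] = float(
            (pij * d2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / nv)
        )
        denom = np.abs(
            levels[ii] * p_i[ii] - levels[jj] * p_i[jj]
        ).sum()
        out["busyness"] = float(ps / denom) if denom > 0 else 0.0
        out["complexity"] = float(
            (
                np.abs(levels[ii] - levels[jj])
                * (p_i[ii] * s_i[ii] + p_i[jj] * s_i[jj])
                / (p_i[ii] + p_i[jj])
            ).sum()
            / nv
        )
        s_sum = float(s_i.sum())
        if s_sum > 0:
            out["strength"] = float(
                ((p_i[ii] + p_i[jj]) * d2).sum() / s_sum
            )
    return out


# ---------------------------------------------------------------------------
# shape and first-order
# ---------------------------------------------------------------------------


def _surface_area(mask: np.ndarray, voxel: float) -> float:
    padded = np.pad(mask.astype(np.uint8), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=(voxel, voxel, voxel)
        )
        return float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        # degenerate masks: exposed-face approximation
        faces = 0
        for axis in range(3):
            sl = mask.astype(np.int8)
            diff = np.abs(np.diff(sl, axis=axis)).sum()
            edge = np.take(sl, [0, -1], axis=axis).sum()
            faces += diff + edge
        return float(faces * voxel**2)


def _max_diameter(coords_mm: np.ndarray) -> float:
    if len(coords_mm) == 1:
        return 0.0
    pts = coords_mm
    if len(pts) > 500:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            rng = np.random.default_rng(0)
            pts = pts[rng.choice(len(pts), size=500, replace=False)]
    return float(pdist(pts).max())


def _shape_features(mask: np.ndarray, voxel: float) -> dict[str, float]:
    n = int(mask.sum())
    volume = n * voxel**3
    area = _surface_area(mask, voxel)
    coords = np.argwhere(mask).astype(float) * voxel
    centered = coords - coords.mean(axis=0)
    if n > 1:
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1]
        eigvals = np.maximum(eigvals, 0.0)
    else:
        eigvals = np.zeros(3)
    axes = 4.0 * np.sqrt(eigvals)
    bbox = np.ptp(np.argwhere(mask), axis=0) + 1
    sphericity = (
        np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
        if area > 0
        else 0.0
    )
    return {
        "voxel_count": float(n),
        "volume_mm3": float(volume),
        "surface_area_mm2": float(area),
        "sphericity": float(sphericity),
        "compactness": float(36.0 * np.pi * volume**2 / area**3) if area > 0 else 0.0,
        "max_diameter_mm": _max_diameter(coords),
        "major_axis_mm": float(axes[0]),
        "minor_axis_mm": float(axes[1]),
        "least_axis_mm": float(axes[2]),
        "elongation": float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0,
        "flatness": float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 1.0,
        "extent": float(n / np.prod(bbox)),
        "surface_to_volume": float(area / volume) if volume > 0 else 0.0,
    }


def _histogram_entropy(values: np.ndarray, n_bins: int) -> tuple[float, float]:
    hist, _ = np.histogram(values, bins=n_bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()), float((p**2).sum())


def _first_order(values: np.ndarray, n_bins: int) -> dict[str, float]:
    entropy, uniformity = _histogram_entropy(values, n_bins)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "sd": sd,
        "variance": sd**2,
        "skewness": float(stats.skew(values)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(values)) if sd > 0 else 0.0,
        "min": float(values.min()),
        "max": float(values.max()),
        "range": float(np.ptp(values)),
        "p10": float(np.percentile(values, 10)),
        "p25": float(np.percentile(values, 25)),
        "p75": float(np.percentile(values, 75)),
        "p90": float(np.percentile(values, 90)),
        "iqr": float(np.percentile(values, 75) - np.percentile(values, 25)),
        "energy": float(np.mean(values**2)),
        "entropy": entropy,
        "uniformity": uniformity,
    }


def _gradient_features(
    volume: np.ndarray, mask: np.ndarray, voxel: float, n_bins: int
) -> dict[str, float]:
    grads = np.gradient(volume.astype(float), voxel)
    gm = np.sqrt(sum(g**2 for g in grads))[mask]
    sd = float(gm.std(ddof=1)) if gm.size > 1 else 0.0
    entropy, _ = _histogram_entropy(gm, n_bins)
    return {
        "mean": float(gm.mean()),
        "sd": sd,
        "skewness": float(stats.skew(gm)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(gm)) if sd > 0 else 0.0,
        "energy": float(np.mean(gm**2)),
        "entropy": entropy,
    }


# ---------------------------------------------------------------------------
# public extraction API
# ---------------------------------------------------------------------------


def extract_features(
    volume: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float = 1.0,
    n_bins: int = N_BINS,
    case_id: str = "",
    min_voxels: int = MIN_MASK_VOXELS,
) -> FeatureVector:
    """Compute the 91-feature vector of one scan within its tumor mask."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape or volume.ndim != 3:
        raise InputError("volume and mask must be congruent 3-D grids")
    n_vox = int(mask.sum())
    if n_vox < min_voxels:
        raise FeatureError(
            f"mask has {n_vox} voxels; at least {min_voxels} required "
            "for quantized texture features"
        )
    values = volume[mask]
    quant = _quantize(volume, mask, n_bins)

    feats: dict[str, float] = {}
    for k, v in _first_order(values, n_bins).items():
        feats[f"fo_{k}"] = v
    for d in GLCM_DISTANCES:
        P = glcm_matrix(quant, mask, d, n_bins)
        for k, v in _glcm_features(P).items():
            feats[f"glcm_d{d}_{k}"] = v
    rv, rl = glrlm_runs(quant, n_bins)
    for k, v in _run_or_zone_features(rv, rl, n_vox, 3, _GLRLM_FAMILY).items():
        feats[f"glrlm_{k}"] = v
    zv, zs = glszm_zones(quant, mask, n_bins)
    for k, v in _run_or_zone_features(zv, zs, n_vox, 1, _GLSZM_FAMILY).items():
        feats[f"glszm_{k}"] = v
    for k, v in _ngtdm_features(quant, mask, n_bins).items():
        feats[f"ngtdm_{k}"] = v
    for k, v in _shape_features(mask, voxel_size_mm).items():
        feats[f"shape_{k}"] = v
    for k, v in _gradient_features(volume, mask, voxel_size_mm, n_bins).items():
        feats[f"grad_{k}"] = v

    names = feature_names()
    return FeatureVector(
        case_id=case_id, names=names, values=np.array([feats[n] for n in names])
    )


def percent_difference(
    pre: FeatureVector,
    post: FeatureVector,
    epsilon: float = 1e-6,
    cap: float = 1000.0,
) -> FeatureVector:
    """Per-feature percent difference 100 * (post - pre) / |pre|.

    When |pre| < epsilon: 0 if |post| is also < epsilon, otherwise the signed
    cap (logged).  All values are clipped to [-cap, cap].
    """
    if pre.names != post.names:
        raise InputError("feature name lists differ between pre and post")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = 100.0 * (post.values - pre.values) / np.abs(pre.values)
    out = np.clip(raw, -cap, cap)
    tiny_pre = np.abs(pre.values) < epsilon
    tiny_both = tiny_pre & (np.abs(post.values) < epsilon)
    degenerate = tiny_pre & ~tiny_both
    out[tiny_both] = 0.0
    out[degenerate] = np.sign(post.values[degenerate] - pre.values[degenerate]) * cap
    for idx in np.flatnonzero(degenerate):
        logger.warning(
            "case %s: feature %s has near-zero pre value; percent difference "
            "capped at %+g", pre.case_id, pre.names[idx], out[idx],
        )
    return FeatureVector(case_id=pre.case_id, names=list(pre.names), values=out)


def case_feature_table(
    cases: list[CasePair], voxel_size_mm: float = 1.0, n_bins: int = N_BINS
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Percent-difference feature matrix over cases.

    Returns (X, y, case_ids, names): X is (n_cases, 91), y the T0 labels.
    The per-scan voxel minimum adapts downward (floor 2) for lesions too
    small to reach it — typically well-responding post-treatment tumors.
    """
    names = feature_names()
    rows, labels, ids = [], [], []
    for case in cases:
        pre = extract_features(
            case.pre_volume, case.pre_mask, voxel_size_mm, n_bins, case.case_id,
            min_voxels=max(2, min(MIN_MASK_VOXELS, int(case.pre_mask.sum()))),
        )
        post = extract_features(
            case.post_volume, case.post_mask, voxel_size_mm, n_bins, case.case_id,
            min_voxels=max(2, min(MIN_MASK_VOXELS, int(case.post_mask.sum()))),
        )
        rows.append(percent_difference(pre, post).values)
        labels.append(case.responded)
        ids.append(case.case_id)
    return np.array(rows), np.array(labels, dtype=bool), ids, names


# ---------------------------------------------------------------------------
# two-loop leave-one-case-out
# ---------------------------------------------------------------------------


@dataclass
class TwoLoopConfig:
    """Settings for the nested feature-selection + random-forest scheme."""

    target_n_features: int = 4  # guide; stopping is no-improvement
    max_features: int = 8
    max_candidates: int = 20  # univariate prescreen pool for greedy search
    selection_scorer: str = "lda"  # 'lda' (fast) or 'rf'
    n_trees: int = 100
    max_depth: int | None = None
    min_gain: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InputError("forest size must be >= 1")
        if self.selection_scorer not in ("lda", "rf"):
            raise InputError("selection_scorer must be 'lda' or 'rf'")


@dataclass
class TwoLoopResult:
    """Outer-loop scores and the per-fold selection report."""

    scores: dict[str, float]
    selected: list[list[str]]
    fallback_folds: list[str] = field(default_factory=list)

    @property
    def mean_n_selected(self) -> float:
        return float(np.mean([len(s) for s in self.selected]))


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return 0.5
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _inner_scores(X: np.ndarray, y: np.ndarray, config: TwoLoopConfig):
    """Inner-LOCO scores of each training case under the selection scorer."""
    n = len(y)
    out = np.zeros(n)
    for i in range(n):
        tr = np.arange(n) != i
        if y[tr].min() == y[tr].max():
            out[i] = 0.5
            continue
        try:
            if config.selection_scorer == "lda":
                clf = LinearDiscriminantAnalysis()
            else:
                clf = RandomForestClassifier(
                    n_estimators=25, random_state=config.seed, n_jobs=1
                )
            clf.fit(X[tr], y[tr])
            out[i] = clf.predict_proba(X[i : i + 1])[0, 1]
        except (np.linalg.LinAlgError, ValueError):
            out[i] = 0.5
    return out


def _greedy_select(
    X: np.ndarray, y: np.ndarray, names: list[str], config: TwoLoopConfig
) -> list[int]:
    """Greedy forward selection maximizing inner-LOCO AUC."""
    n, p = X.shape
    uni = np.array([abs(_auc(X[:, j], y) - 0.5) for j in range(p)])
    pool = list(np.argsort(-uni)[: config.max_candidates])
    selected: list[int] = []
    best_auc = 0.5
    while len(selected) < config.max_features:
        best_j, best_j_auc = None, best_auc
        for j in pool:
            if j in selected:
                continue
            cand = selected + [j]
            auc_j = _auc(_inner_scores(X[:, cand], y, config), y)
            if auc_j > best_j_auc + config.min_gain:
                best_j, best_j_auc = j, auc_j
        if best_j is None:
            break
        selected.append(best_j)
        best_auc = best_j_auc
    return selected


def two_loop_loco_features(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    case_ids: list[str],
    config: TwoLoopConfig,
) -> TwoLoopResult:
    """Two-loop LOCO on a precomputed feature matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n = len(y)
    if n < 4:
        raise InputError("need at least 4 cases")
    if y.all() or not y.any():
        raise InputError("both classes must be represented")

    scores: dict[str, float] = {}
    selections: list[list[str]] = []
    fallbacks: list[str] = []
    for k in range(n):
        train = np.flatnonzero(np.arange(n) != k)
        # hard leakage guard: held-out case absent from selection and training
        assert k not in train
        Xtr, ytr = X[train], y[train]
        sel = _greedy_select(Xtr, ytr, names, config)
        if not sel:
            logger.warning(
                "fold %s: greedy selection chose no feature; falling back to "
                "all features", case_ids[k],
            )
            fallbacks.append(case_ids[k])
            sel = list(range(X.shape[1]))
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            random_state=(config.seed * 1009 + k) % (2**31),
            n_jobs=1,
        )
        clf.fit(Xtr[:, sel], ytr)
        scores[case_ids[k]] = float(clf.predict_proba(X[k : k + 1, sel])[0, 1])
        selections.append([names[j] for j in sel])
    return TwoLoopResult(scores=scores, selected=selections, fallback_folds=fallbacks)


def two_loop_loco(
    cases: list[CasePair],
    config: TwoLoopConfig,
    voxel_size_mm: float = 1.0,
    n_bins: int = N_BINS,
) -> TwoLoopResult:
    """Full radiomics scoring chain: extract percent-difference features and
    run the nested selection/forest scheme."""
    X, y, ids, names = case_feature_table(cases, voxel_size_mm, n_bins)
    return two_loop_loco_features(X, y, names, ids, config)
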