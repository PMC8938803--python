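"""ROI extraction from segmented tumor slices and pre/post hybrid composition.

From each axial slice whose in-slice mask area meets a minimum, one ROI
(default 32x16 pixels) is cut out centered on the slice's mask centroid,
clamped to stay inside the slice.  A hybrid patch joins a pre-treatment ROI
(left half) and a post-treatment ROI of the same tumor (right half) into a
32x32 input for the CNN stage; the full Cartesian product of pre x post ROIs
is enumerated, optionally capped by a seeded uniform subsample.
"""

from __future__ import annotations

import itertools

import numpy as np

from .types import CasePair, HybridROI, InputError

__all__ = [
    "ExtractionError",
    "extract_rois",
    "compose_hybrid",
    "enumerate_hybrids",
    "case_hybrids",
]

ROI_HEIGHT = 32
ROI_WIDTH = 16
MIN_SLICE_AREA = 10


class ExtractionError(ValueError):
    """No slice of a case yields a valid ROI."""


def extract_rois(
    volume: np.ndarray,
    mask: np.ndarray,
    roi_height: int = ROI_HEIGHT,
    roi_width: int = ROI_WIDTH,
    min_area: int = MIN_SLICE_AREA,
    case_id: str = "?",
) -> list[tuple[int, np.ndarray]]:
    """Extract one centroid-centered ROI per qualifying tumor slice.

    Returns ``(slice_index, patch)`` pairs in slice order; each patch has
    shape ``(roi_height, roi_width)``.  Windows that would leave the slice
    are shifted inward, so the shape is always exact.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape or volume.ndim != 3:
        raise InputError("volume and mask must be congruent 3-D grids")
    if not mask.any():
        raise InputError(f"case {case_id}: empty mask")
    n_rows, n_cols = volume.shape[1], volume.shape[2]
    if roi_height > n_rows or roi_width > n_cols:
        raise InputError(
            f"ROI {roi_height}x{roi_width} does not fit in slice "
            f"{n_rows}x{n_cols}"
        )
    out: list[tuple[int, np.ndarray]] = []
    for z in range(volume.shape[0]):
        sl = mask[z]
        area = int(sl.sum())
        if area < max(min_area, 1):
            continue
        rows, cols = np.nonzero(sl)
        cy, cx = rows.mean(), cols.mean()
        top = int(round(cy - roi_height / 2.0))
        left = int(round(cx - roi_width / 2.0))
        top = min(max(top, 0), n_rows - roi_height)
        left = min(max(left, 0), n_cols - roi_width)
        patch = volume[z, top : top + roi_height, left : left + roi_width]
        out.append((z, np.array(patch, dtype=float)))
    if not out:
        raise ExtractionError(
            f"case {case_id}: no slice reaches the minimum in-slice mask "
            f"area of {min_area}"
        )
    return out


def compose_hybrid(pre_roi: np.ndarray, post_roi: np.ndarray) -> np.ndarray:
    """Join a pre- and a post-treatment ROI side by side.

    The pre-treatment ROI occupies the left columns, the post-treatment ROI
    the right columns; intensities are unchanged.  Two 32x16 halves give the
    canonical 32x32 hybrid patch.
    """
    pre_roi = np.asarray(pre_roi, dtype=float)
    post_roi = np.asarray(post_roi, dtype=float)
    if pre_roi.ndim != 2 or pre_roi.shape != post_roi.shape:
        raise InputError(
            f"ROI shape mismatch: {pre_roi.shape} vs {post_roi.shape}"
        )
    return np.hstack([pre_roi, post_roi])


def enumerate_hybrids(
    pre_rois: list[tuple[int, np.ndarray]],
    post_rois: list[tuple[int, np.ndarray]],
    case_id: str,
    label: bool,
    cap: int | None = None,
    seed: int = 0,
) -> list[HybridROI]:
    """All pre x post ROI combinations of one case, as labeled hybrids.

    Without a cap the full Cartesian product (``|pre| * |post|`` hybrids) is
    returned in deterministic (pre-major) order; with a cap, a seeded uniform
    subsample of that product without replacement.
    """
    if not pre_rois or not post_rois:
        raise InputError(f"case {case_id}: both ROI lists must be nonempty")
    if cap is not None and cap <= 0:
        raise InputError("cap must be positive when given")
    pairs = list(itertools.product(range(len(pre_rois)), range(len(post_rois))))
    if cap is not None and cap < len(pairs):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pairs), size=cap, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]
    hybrids = []
    for i, j in pairs:
        zi, pre = pre_rois[i]
        zj, post = post_rois[j]
        hybrids.append(
            HybridROI(
                pixels=compose_hybrid(pre, post),
                case_id=case_id,
                pre_slice_index=zi,
                post_slice_index=zj,
                label=bool(label),
            )
        )
    return hybrids


def case_hybrids(
    case: CasePair,
    roi_height: int = ROI_HEIGHT,
    roi_width: int = ROI_WIDTH,
    min_area: int = MIN_SLICE_AREA,
    cap: int | None = None,
    seed: int = 0,
) -> list[HybridROI]:
    """Extract ROIs from both scans of a case and enumerate its hybrids.

    The in-slice area minimum adapts per scan: lesions too small to reach it
    anywhere (typically well-responding post-treatment tumors) contribute
    their largest-area slice instead of failing.
    """
    rois = []
    for volume, mask in (
        (case.pre_volume, case.pre_mask),
        (case.post_volume, case.post_mask),
    ):
        largest = int(np.asarray(mask).sum(axis=(1, 2)).max())
        effective = max(1, min(min_area, largest))
        rois.append(
            extract_rois(
                volume, mask, roi_height, roi_width, effective, case.case_id
            )
        )
    pre, post = rois
    return enumerate_hybrids(pre, post, case.case_id, case.responded, cap, seed)
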