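"""Score fusion, ROC evaluation, 1-10 CAD scaling, and class display curves.

The combined per-case score is the larger of the DL and radiomics
discriminant scores.  CAD scores are an affine image of the combined scores
onto [1, 10] anchored at the reference cohort's minimum and maximum (values
outside the reference range clip); the fitted map is kept so that new cases
are scored on the same scale.  For the reader display, one smooth density per
outcome class is fitted over [1, 10] (Gaussian KDE with boundary reflection,
or a normal fit) and renormalized to unit area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import CaseScore, InputError

__all__ = [
    "combine_scores",
    "roc_auc",
    "CadScaler",
    "scale_to_cad",
    "CadDisplay",
    "fit_class_distributions",
    "build_case_scores",
]


def combine_scores(dl: float, radiomics: float) -> float:
    """Fuse the two model scores by taking the larger value."""
    if not (np.isfinite(dl) and np.isfinite(radiomics)):
        raise InputError("scores must be finite")
    return float(max(dl, radiomics))


def roc_auc(scores, labels) -> float:
    """Empirical AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    Equals the trapezoidal area under the empirical ROC curve; computed by
    the Mann-Whitney statistic with midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must align")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise InputError("AUC undefined: only one class present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class CadScaler:
    """Affine map of combined scores onto the 1-10 CAD scale.

    Fitted on a reference cohort (min -> 1, max -> 10) and persisted so all
    readers and any new case see the same scale; out-of-range values clip.
    """

    low: float
    high: float

    @classmethod
    def fit(cls, combined) -> "CadScaler":
        combined = np.asarray(combined, dtype=float)
        if combined.size < 2:
            raise InputError("need at least 2 reference scores")
        lo, hi = float(combined.min()), float(combined.max())
        if hi <= lo:
            raise InputError("constant reference cohort: CAD scale undefined")
        return cls(low=lo, high=hi)

    def transform(self, combined) -> np.ndarray:
        combined = np.asarray(combined, dtype=float)
        cad = 1.0 + 9.0 * (combined - self.low) / (self.high - self.low)
        return np.clip(cad, 1.0, 10.0)


def scale_to_cad(combined) -> tuple[np.ndarray, CadScaler]:
    """Fit the cohort-anchored affine map and apply it."""
    scaler = CadScaler.fit(combined)
    return scaler.transform(combined), scaler


@dataclass
class CadDisplay:
    """Tabulated per-class CAD-score densities over [1, 10]."""

    grid: np.ndarray
    t0_curve: np.ndarray
    gt0_curve: np.ndarray

    def __post_init__(self) -> None:
        for curve in (self.t0_curve, self.gt0_curve):
            area = np.trapezoid(curve, self.grid)
            if abs(area - 1.0) > 1e-6:
                raise InputError(f"display curve area {area} != 1")


def _reflected_kde(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    kde = stats.gaussian_kde(values)
    dens = kde(grid) + kde(2.0 * 1.0 - grid) + kde(2.0 * 10.0 - grid)
    return dens


def fit_class_distributions(
    cad, labels, n_grid: int = 512, method: str = "kde"
) -> CadDisplay:
    """Fit one unit-area density per outcome class over the CAD scale.

    ``method='kde'`` uses a Gaussian kernel estimate with reflection at the
    scale boundaries; ``method='normal'`` a truncated normal fit.  Each curve
    is renormalized to integrate to 1 on [1, 10] (trapezoid rule).
    """
    cad = np.asarray(cad, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    grid = np.linspace(1.0, 10.0, n_grid)
    curves = {}
    for cls, name in ((True, "t0"), (False, "gt0")):
        vals = cad[labels == cls]
        if vals.size < 2:
            raise InputError(f"class {name} has fewer than 2 members")
        if method == "kde":
            if np.ptp(vals) == 0:
                # degenerate cluster: narrow normal bump at the common value
                dens = stats.norm.pdf(grid, vals[0], 0.05)
            else:
                dens = _reflected_kde(vals, grid)
        elif method == "normal":
            sd = vals.std(ddof=1)
            dens = stats.norm.pdf(grid, vals.mean(), max(sd, 1e-3))
        else:
            raise InputError(f"unknown method {method!r}")
        area = np.trapezoid(dens, grid)
        if area <= 0:
            raise InputError(f"degenerate density for class {name}")
        curves[name] = dens / area
    return CadDisplay(grid=grid, t0_curve=curves["t0"], gt0_curve=curves["gt0"])


def build_case_scores(
    dl_scores: dict[str, float], radiomics_scores: dict[str, float]
) -> tuple[list[CaseScore], CadScaler]:
    """Assemble per-case score records: combine, fit the CAD map, scale."""
    if set(dl_scores) != set(radiomics_scores):
        raise InputError("DL and radiomics score tables cover different cases")
    case_ids = sorted(dl_scores)
    combined = np.array(
        [combine_scores(dl_scores[c], radiomics_scores[c]) for c in case_ids]
    )
    cad, scaler = scale_to_cad(combined)
    out = [
        CaseScore(
            case_id=c,
            dl_score=float(dl_scores[c]),
            radiomics_score=float(radiomics_scores[c]),
            combined_score=float(comb),
            cad_score=float(k),
        )
        for c, comb, k in zip(case_ids, combined, cad)
    ]
    return out, scaler
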