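"""Observer-study statistics: per-reader ROC, MRMC modality comparison,
difficulty stratification, subgroup analyses, and agreement measures.

The multi-reader multi-case (MRMC) comparison uses the nonparametric
U-statistic framework with two-way random effects (readers and cases): the
reader-averaged empirical AUC is a weighted sum of success indicators
psi(X_neg, X_pos) and its (co)variance is estimated unbiasedly by decomposing
all pairs of indicator terms into the eight equality categories of
(reader, negative case, positive case) index pairs.  The estimator is valid
for arbitrary study designs, including the non-fully-crossed repeat-read arm
where every reader re-reads a different random subset of cases.  A
delete-one-case jackknife is kept as an independent reference for
fully-crossed toys.

Agreement measures follow the observer-study conventions: Bland-Altman bias
and SD of (repeated - original) likelihood differences per reader, and
Krippendorff's alpha from the coincidence matrix with nominal, ordinal or
interval difference functions and full missing-data support (0.8 is the
customary satisfactory-reliability threshold, 0.667 the tentative floor).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import GroundTruth, InputError, ReaderProfile

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANCE_FLOOR",
    "ALPHA_SATISFACTORY",
    "ALPHA_TENTATIVE_FLOOR",
    "MrmcResult",
    "SubsetPartition",
    "AgreementResult",
    "empirical_auc",
    "reader_auc",
    "mrmc_compare",
    "jackknife_variance",
    "stratify_cases",
    "subgroup_mrmc",
    "bland_altman",
    "krippendorff_alpha",
    "inter_reader_matrix",
    "test_retest_matrix",
    "intra_reader_alphas",
]

VARIANCE_FLOOR = 1e-12
ALPHA_SATISFACTORY = 0.8
ALPHA_TENTATIVE_FLOOR = 0.667

Arm = tuple[str, str]  # (modality, round)


def _as_arm(arm) -> Arm:
    if isinstance(arm, str):
        return (arm, "original")
    modality, rnd = arm
    return (modality, rnd)


def empirical_auc(scores, labels) -> float:
    """Wilcoxon AUC with midrank tie handling (= trapezoidal ROC area)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise InputError("AUC undefined: only one class present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# success-matrix construction
# ---------------------------------------------------------------------------


def _arm_matrices(
    ratings: pd.DataFrame,
    truth: GroundTruth,
    arm: Arm,
    reader_ids: list[str],
    case_ids: list[str] | None = None,
):
    """Per-reader success and design matrices for one (modality, round) arm.

    Returns (S, D, readers) with S[r, i, j] = psi(score_neg_i, score_pos_j)
    where psi is 1 / 0.5 / 0 for pos > / = / < neg, and D[r, i, j] = 1 when
    reader r rated both cases in this arm; zero elsewhere.
    """
    modality, rnd = arm
    truth_frame = truth.to_frame().set_index("case_id")
    if case_ids is None:
        case_ids = [str(c) for c in truth.case_ids]
    case_ids = [c for c in case_ids if c in truth_frame.index]
    responded = truth_frame.loc[case_ids, "responded"].to_numpy(dtype=bool)
    neg_ids = [c for c, r in zip(case_ids, responded) if not r]
    pos_ids = [c for c, r in zip(case_ids, responded) if r]
    n0, n1 = len(neg_ids), len(pos_ids)

    sub = ratings[
        (ratings["modality"] == modality)
        & (ratings["round"] == rnd)
        & (ratings["case_id"].isin(case_ids))
        & (ratings["reader_id"].isin(reader_ids))
    ]
    pivot = sub.pivot_table(
        index="reader_id", columns="case_id", values="likelihood_t0"
    )
    S = np.zeros((len(reader_ids), n0, n1))
    D = np.zeros((len(reader_ids), n0, n1))
    for r, reader in enumerate(reader_ids):
        if reader not in pivot.index:
            continue
        row = pivot.loc[reader]
        sneg = row.reindex(neg_ids).to_numpy(dtype=float)
        spos = row.reindex(pos_ids).to_numpy(dtype=float)
        have = np.isfinite(sneg)[:, None] & np.isfinite(spos)[None, :]
        diff = spos[None, :] - sneg[:, None]
        psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
        S[r] = np.where(have, psi, 0.0)
        D[r] = have.astype(float)
    return S, D, neg_ids, pos_ids


def _reader_weights(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equal-reader weights 1/(R_eff * m0_r * m1_r); zero for empty readers."""
    per_reader_pairs = D.sum(axis=(1, 2))
    active = per_reader_pairs > 0
    r_eff = int(active.sum())
    w = np.zeros(D.shape[0])
    if r_eff:
        w[active] = 1.0 / (r_eff * per_reader_pairs[active])
    return w, active


def _grams(A, B):
    """Per-reader-pair sums of term products over the four case-index
    equality categories: (same i same j, same i diff j, diff i same j,
    diff i diff j); each entry [r, r'] sums over reader r's terms times
    reader r''s terms."""
    E = np.einsum("aij,bij->ab", A, B)
    Pr = A.sum(axis=2) @ B.sum(axis=2).T
    Pc = A.sum(axis=1) @ B.sum(axis=1).T
    Pt = np.outer(A.sum(axis=(1, 2)), B.sum(axis=(1, 2)))
    return (E, Pr - E, Pc - E, Pt - Pr - Pc + E)


def _ustat_cov(SX, DX, wX, SY, DY, wY, same_reader: np.ndarray):
    """Unbiased U-statistic covariance of two reader-averaged AUCs.

    Decomposes E[A_X * A_Y] over the eight (reader, neg, pos) index-equality
    categories; the product of means is estimated by the all-different
    category (independent tuples), falling back to the same-reader
    different-cases category when only one reader is shared (fixed-reader
    inference).  Returns (cov, fixed_reader_flag).
    """
    s_cats = _grams(SX, SY)
    d_cats = _grams(DX, DY)
    O = np.outer(wX, wY)
    same = same_reader.astype(bool)
    N = np.zeros(8)
    W = np.zeros(8)
    for k in range(4):
        N[k] = (O * s_cats[k])[same].sum()
        W[k] = (O * d_cats[k])[same].sum()
        N[k + 4] = (O * s_cats[k])[~same].sum()
        W[k + 4] = (O * d_cats[k])[~same].sum()

    fixed_reader = False
    if W[7] > 0:
        m_base = N[7] / W[7]
    elif W[3] > 0:
        m_base = N[3] / W[3]
        fixed_reader = True
    else:
        return 0.0, True
    return float(N.sum() - m_base), fixed_reader


def reader_auc(
    ratings: pd.DataFrame,
    truth: GroundTruth,
    reader_id: str,
    modality: str = "unaided",
    round: str = "original",
    case_ids: list[str] | None = None,
) -> tuple[float, float]:
    """One reader's empirical AUC and its U-statistic variance."""
    S, D, neg_ids, pos_ids = _arm_matrices(
        ratings, truth, (modality, round), [reader_id], case_ids
    )
    if D.sum() == 0 or not neg_ids or not pos_ids:
        raise InputError(
            f"reader {reader_id}: both classes must be rated in this arm"
        )
    w, _ = _reader_weights(D)
    auc = float((w[:, None, None] * S).sum())
    var, _ = _ustat_cov(S, D, w, S, D, w, np.ones((1, 1), dtype=bool))
    return auc, max(var, 0.0)


@dataclass
class MrmcResult:
    """Reader-averaged AUC comparison between two arms.

    ``var_a``/``var_b``/``cov_ab``/``var_diff`` are the pure U-statistic
    (two-way random readers and cases) estimates; the reported ``p_value``
    and ``ci95`` come from the t construction on per-reader differences with
    the case-covariance adjustment 2*max(Cov2 - Cov3, 0) and Hillis degrees
    of freedom, which calibrates far better at small reader counts.
    """

    arm_a: Arm
    arm_b: Arm
    reader_aucs_a: dict[str, float]
    reader_aucs_b: dict[str, float]
    mean_auc_a: float
    mean_auc_b: float
    diff: float
    var_a: float
    var_b: float
    cov_ab: float
    var_diff: float
    se_diff: float
    df: float
    cov2: float
    cov3: float
    p_value: float
    ci95: tuple[float, float]
    n_readers: int
    n_pos: int
    n_neg: int
    fixed_reader: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0
        assert self.ci95[0] - 1e-12 <= self.diff <= self.ci95[1] + 1e-12


def mrmc_compare(
    ratings: pd.DataFrame,
    truth: GroundTruth,
    arm_a="unaided",
    arm_b="aided",
    reader_ids: list[str] | None = None,
    case_ids: list[str] | None = None,
) -> MrmcResult:
    """Compare reader-averaged AUC between two arms (modality or round).

    Arms are ``modality`` strings or ``(modality, round)`` tuples.  Handles
    non-fully-crossed designs: each reader's AUC is computed on the cases they
    actually rated in that arm, and the missing-data design weights enter the
    U-statistic covariance.  Degenerate variance estimates are floored at
    ``VARIANCE_FLOOR`` with a warning.
    """
    arm_a, arm_b = _as_arm(arm_a), _as_arm(arm_b)
    warnings: list[str] = []
    if reader_ids is None:
        reader_ids = sorted(ratings["reader_id"].unique())
    if len(reader_ids) < 1:
        raise InputError("no readers")

    SA, DA, neg_ids, pos_ids = _arm_matrices(
        ratings, truth, arm_a, reader_ids, case_ids
    )
    SB, DB, _, _ = _arm_matrices(ratings, truth, arm_b, reader_ids, case_ids)
    if not neg_ids or not pos_ids:
        raise InputError("both outcome classes are required")
    wA, activeA = _reader_weights(DA)
    wB, activeB = _reader_weights(DB)
    if not activeA.any() or not activeB.any():
        raise InputError("an arm has no rated reader-case pairs")
    for r, reader in enumerate(reader_ids):
        if activeA[r] != activeB[r]:
            msg = (
                f"reader {reader} present in only one arm; handled by "
                "missing-data weights"
            )
            warnings.append(msg)
            logger.warning(msg)

    per_pairs_A = DA.sum(axis=(1, 2))
    per_pairs_B = DB.sum(axis=(1, 2))
    aucs_a = {
        reader: float(SA[r].sum() / per_pairs_A[r])
        for r, reader in enumerate(reader_ids)
        if per_pairs_A[r] > 0
    }
    aucs_b = {
        reader: float(SB[r].sum() / per_pairs_B[r])
        for r, reader in enumerate(reader_ids)
        if per_pairs_B[r] > 0
    }
    mean_a = float((wA[:, None, None] * SA).sum())
    mean_b = float((wB[:, None, None] * SB).sum())
    diff = mean_a - mean_b

    eye = np.eye(len(reader_ids), dtype=bool)
    var_a, fixed_a = _ustat_cov(SA, DA, wA, SA, DA, wA, eye)
    var_b, fixed_b = _ustat_cov(SB, DB, wB, SB, DB, wB, eye)
    cov_ab, _ = _ustat_cov(SA, DA, wA, SB, DB, wB, eye)
    var_diff = var_a + var_b - 2.0 * cov_ab
    if var_diff < VARIANCE_FLOOR:
        msg = (
            f"degenerate U-statistic variance estimate {var_diff:.3g} "
            f"floored at {VARIANCE_FLOOR}"
        )
        warnings.append(msg)
        logger.debug(msg)
        var_diff = VARIANCE_FLOOR

    # conditional-on-readers case covariances of per-reader AUCs; for each
    # reader pair the product-of-means base is the all-cases-different
    # category (disjoint case tuples are independent given the readers)
    both = activeA & activeB
    common = np.flatnonzero(both)
    fixed_reader = fixed_a or fixed_b or len(common) < 2

    auc_vec_a = np.array(
        [SA[r].sum() / per_pairs_A[r] if per_pairs_A[r] else np.nan
         for r in range(len(reader_ids))]
    )
    auc_vec_b = np.array(
        [SB[r].sum() / per_pairs_B[r] if per_pairs_B[r] else np.nan
         for r in range(len(reader_ids))]
    )

    def _pairwise_case_cov(Sx, Dx, aucx, Sy, Dy, aucy):
        """Matrix C[r, r'] of case-induced covariances between reader r's
        arm-x AUC and reader r''s arm-y AUC."""
        sub4 = _grams(Sx, Sy)[3][np.ix_(common, common)]
        cnt4 = _grams(Dx, Dy)[3][np.ix_(common, common)]
        with np.errstate(invalid="ignore", divide="ignore"):
            m4 = np.where(cnt4 > 0, sub4 / np.maximum(cnt4, 1), 0.0)
        return np.outer(aucx[common], aucy[common]) - m4

    cov2 = cov3 = 0.0
    if len(common) >= 2:
        R = len(common)
        off = ~np.eye(R, dtype=bool)
        C_ab = _pairwise_case_cov(SA, DA, auc_vec_a, SB, DB, auc_vec_b)
        C_aa = _pairwise_case_cov(SA, DA, auc_vec_a, SA, DA, auc_vec_a)
        C_bb = _pairwise_case_cov(SB, DB, auc_vec_b, SB, DB, auc_vec_b)
        # Obuchowski-Rockette convention: Cov2 = different readers, same
        # arm (averaged over arms); Cov3 = different readers, different arms
        cov2 = float((C_aa[off].mean() + C_bb[off].mean()) / 2.0)
        cov3 = float(C_ab[off].mean())
        d_r = auc_vec_a[common] - auc_vec_b[common]
        s2d = float(np.var(d_r, ddof=1))
        adj = max(cov2 - cov3, 0.0)
        se2 = s2d / R + 2.0 * adj
        if se2 < VARIANCE_FLOOR:
            se2 = VARIANCE_FLOOR
        se = math.sqrt(se2)
        if s2d > 0:
            ms_tr = s2d / 2.0
            df = (R - 1) * ((ms_tr + R * adj) / ms_tr) ** 2
        else:
            df = np.inf
        t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        q = float(stats.t.ppf(0.975, df))
        ci = (diff - q * se, diff + q * se)
    else:
        # single shared reader (or none): case-variance-only inference
        se = math.sqrt(var_diff)
        df = np.inf
        z = diff / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        ci = (diff - 1.959963984540054 * se, diff + 1.959963984540054 * se)
    return MrmcResult(
        arm_a=arm_a,
        arm_b=arm_b,
        reader_aucs_a=aucs_a,
        reader_aucs_b=aucs_b,
        mean_auc_a=mean_a,
        mean_auc_b=mean_b,
        diff=diff,
        var_a=max(var_a, 0.0),
        var_b=max(var_b, 0.0),
        cov_ab=cov_ab,
        var_diff=var_diff,
        se_diff=se,
        df=float(df),
        cov2=cov2,
        cov3=cov3,
        p_value=p,
        ci95=ci,
        n_readers=int(max(activeA.sum(), activeB.sum())),
        n_pos=len(pos_ids),
        n_neg=len(neg_ids),
        fixed_reader=fixed_reader,
        warnings=warnings,
    )


def jackknife_variance(
    ratings: pd.DataFrame,
    truth: GroundTruth,
    arm_a="unaided",
    arm_b="aided",
    reader_ids: list[str] | None = None,
    case_ids: list[str] | None = None,
) -> float:
    """Delete-one-case jackknife variance of the reader-mean AUC difference.

    Reference implementation for fully-crossed designs; used to cross-check
    the U-statistic estimator on small instances.
    """
    if case_ids is None:
        case_ids = [str(c) for c in truth.case_ids]
    n = len(case_ids)
    full = mrmc_compare(ratings, truth, arm_a, arm_b, reader_ids, case_ids)
    deltas = np.empty(n)
    for i, drop in enumerate(case_ids):
        kept = [c for c in case_ids if c != drop]
        res = mrmc_compare(ratings, truth, arm_a, arm_b, reader_ids, kept)
        deltas[i] = res.diff
    return float((n - 1) / n * ((deltas - deltas.mean()) ** 2).sum())


# ---------------------------------------------------------------------------
# difficulty stratification and subgroup analyses
# ---------------------------------------------------------------------------


@dataclass
class SubsetPartition:
    """Easy/difficult case split by the SD of designated readers' unaided
    likelihood estimates (sample SD, n-1); SD <= threshold is easy (the
    boundary goes to easy)."""

    per_case_sd: pd.Series
    threshold: float
    easy_ids: list[str]
    difficult_ids: list[str]

    def __post_init__(self) -> None:
        assert not set(self.easy_ids) & set(self.difficult_ids)

    def class_composition(self, truth: GroundTruth) -> pd.DataFrame:
        frame = truth.to_frame().set_index("case_id")
        rows = []
        for name, ids in (("easy", self.easy_ids), ("difficult", self.difficult_ids)):
            resp = frame.loc[ids, "responded"]
            rows.append(
                {"subset": name, "n": len(ids), "n_t0": int(resp.sum()),
                 "n_gt0": int((~resp).sum())}
            )
        return pd.DataFrame(rows)


def stratify_cases(
    ratings: pd.DataFrame,
    reader_ids: list[str],
    threshold: float = 25.0,
    modality: str = "unaided",
    round: str = "original",
) -> SubsetPartition:
    """Partition cases by inter-reader disagreement of the designated readers
    (conventionally the radiologist subgroup) in the unaided original read."""
    sub = ratings[
        (ratings["modality"] == modality)
        & (ratings["round"] == round)
        & (ratings["reader_id"].isin(reader_ids))
    ]
    pivot = sub.pivot_table(
        index="case_id", columns="reader_id", values="likelihood_t0"
    )
    missing_cols = set(reader_ids) - set(pivot.columns)
    if missing_cols:
        raise InputError(f"readers {sorted(missing_cols)} have no ratings")
    incomplete = pivot.index[pivot[list(reader_ids)].isna().any(axis=1)]
    if len(incomplete):
        raise InputError(
            f"cases missing a designated reader's rating: {list(incomplete)[:10]}"
        )
    sd = pivot[list(reader_ids)].std(axis=1, ddof=1)
    easy = sorted(sd.index[sd <= threshold])
    difficult = sorted(sd.index[sd > threshold])
    return SubsetPartition(
        per_case_sd=sd, threshold=threshold, easy_ids=easy, difficult_ids=difficult
    )


def subgroup_mrmc(
    ratings: pd.DataFrame,
    truth: GroundTruth,
    profiles: list[ReaderProfile],
    grouping: str,
    partition: SubsetPartition | None = None,
    arm_a="unaided",
    arm_b="aided",
) -> dict[str, MrmcResult]:
    """One MRMC comparison per subgroup.

    ``grouping`` is ``specialty``, ``institution`` or ``proficiency``
    (restrict readers), or ``difficulty`` (restrict cases using
    ``partition``).  Empty subgroups are skipped with a warning; single-reader
    subgroups use case-variance-only (fixed-reader) inference, flagged on the
    result.
    """
    results: dict[str, MrmcResult] = {}
    if grouping == "difficulty":
        if partition is None:
            raise InputError("difficulty grouping requires a SubsetPartition")
        groups = {"easy": partition.easy_ids, "difficult": partition.difficult_ids}
        for name, ids in groups.items():
            if not ids:
                logger.warning("subgroup %s is empty; skipped", name)
                continue
            results[name] = mrmc_compare(
                ratings, truth, arm_a, arm_b, case_ids=list(ids)
            )
        return results
    if grouping not in ("specialty", "institution", "proficiency"):
        raise InputError(f"unknown grouping {grouping!r}")
    values = sorted({getattr(p, grouping) for p in profiles})
    rated = set(ratings["reader_id"].unique())
    for value in values:
        members = [
            p.reader_id
            for p in profiles
            if getattr(p, grouping) == value and p.reader_id in rated
        ]
        if not members:
            logger.warning("subgroup %s=%s is empty; skipped", grouping, value)
            continue
        results[value] = mrmc_compare(
            ratings, truth, arm_a, arm_b, reader_ids=members
        )
    return results


# ---------------------------------------------------------------------------
# agreement: Bland-Altman and Krippendorff's alpha
# ---------------------------------------------------------------------------


def bland_altman(
    ratings: pd.DataFrame, modality: str = "unaided"
) -> pd.DataFrame:
    """Per-reader test-retest agreement of likelihood estimates.

    Differences are (repeated - original) on the cases a reader rated in
    both rounds; returns a frame with per-reader ``bias`` (mean difference),
    ``sd`` (n-1 SD of differences) and ``n``.  Readers without at least two
    overlapping cases are skipped with a warning.
    """
    sub = ratings[ratings["modality"] == modality]
    rows = []
    for reader, grp in sub.groupby("reader_id"):
        pivot = grp.pivot_table(
            index="case_id", columns="round", values="likelihood_t0"
        )
        if "original" not in pivot.columns or "repeated" not in pivot.columns:
            logger.warning("reader %s: no repeat reads; skipped", reader)
            continue
        both = pivot.dropna(subset=["original", "repeated"])
        if len(both) < 2:
            logger.warning(
                "reader %s: fewer than 2 overlapping cases; skipped", reader
            )
            continue
        d = both["repeated"] - both["original"]
        rows.append(
            {
                "reader_id": reader,
                "bias": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                "n": int(len(d)),
            }
        )
    return pd.DataFrame(rows, columns=["reader_id", "bias", "sd", "n"])


def _delta_sq(values: np.ndarray, marginals: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise squared difference function over the value domain.

    For the ordinal metric, delta(v,k) is the sum of the marginal counts of
    all categories from v to k inclusive minus half of each endpoint count.
    """
    v = values[:, None]
    k = values[None, :]
    if metric == "nominal":
        return (v != k).astype(float)
    if metric == "interval":
        return (v - k) ** 2
    if metric == "ordinal":
        idx = np.arange(len(marginals))
        lower = np.minimum(idx[:, None], idx[None, :])
        upper = np.maximum(idx[:, None], idx[None, :])
        cum = np.concatenate([[0.0], np.cumsum(marginals)])
        seg = cum[upper + 1] - cum[lower]
        return (seg - (marginals[lower] + marginals[upper]) / 2.0) ** 2
    raise InputError(f"unknown metric {metric!r}")


def krippendorff_alpha(data, metric: str = "interval") -> float:
    """Krippendorff's alpha for a coders x units matrix with missing entries
    (NaN).  ``metric`` selects the difference function: nominal, ordinal
    (by category rank) or interval.

    Alpha = 1 - observed/expected disagreement from the coincidence matrix;
    units with fewer than two non-missing values are ignored.  If every
    pairable value is identical, expected disagreement is zero and alpha is
    reported as 1 (degenerate perfect agreement, logged).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise InputError("data must be a 2-D coders x units matrix")
    counts = np.isfinite(data).sum(axis=0)
    usable = counts >= 2
    if usable.sum() < 1:
        raise InputError("need at least one unit with >= 2 non-missing values")
    cols = data[:, usable]
    vals = cols[np.isfinite(cols)]
    uniq = np.unique(vals)
    v_index = {v: i for i, v in enumerate(uniq)}
    nv = len(uniq)

    # per-unit category counts
    O = np.zeros((nv, nv))
    for u in range(cols.shape[1]):
        col = cols[:, u]
        col = col[np.isfinite(col)]
        m = len(col)
        cnt = np.zeros(nv)
        for x in col:
            cnt[v_index[x]] += 1
        O += (np.outer(cnt, cnt) - np.diag(cnt)) / (m - 1)
    n_margin = O.sum(axis=1)
    n_total = n_margin.sum()

    values_for_delta = (
        np.arange(nv, dtype=float) if metric == "ordinal" else uniq
    )
    d2 = _delta_sq(values_for_delta, n_margin, metric)
    d_obs = float((O * d2).sum())
    d_exp = float((np.outer(n_margin, n_margin) * d2).sum()) / (n_total - 1.0)
    if d_exp == 0.0:
        logger.warning(
            "expected disagreement is zero (all pairable values identical); "
            "alpha reported as 1"
        )
        return 1.0
    alpha = 1.0 - d_obs / d_exp
    assert alpha <= 1.0 + 1e-12
    return float(alpha)


def inter_reader_matrix(
    ratings: pd.DataFrame, modality: str = "unaided", round: str = "original"
) -> np.ndarray:
    """Readers x cases likelihood matrix (NaN for unrated cells)."""
    sub = ratings[
        (ratings["modality"] == modality) & (ratings["round"] == round)
    ]
    pivot = sub.pivot_table(
        index="reader_id", columns="case_id", values="likelihood_t0"
    )
    return pivot.to_numpy(dtype=float)


def test_retest_matrix(
    ratings: pd.DataFrame, reader_id: str, modality: str = "unaided"
) -> np.ndarray:
    """2 x cases matrix (original, repeated rounds as coders) for one reader."""
    sub = ratings[
        (ratings["reader_id"] == reader_id) & (ratings["modality"] == modality)
    ]
    pivot = sub.pivot_table(
        index="round", columns="case_id", values="likelihood_t0"
    ).reindex(["original", "repeated"])
    return pivot.to_numpy(dtype=float)


def intra_reader_alphas(
    ratings: pd.DataFrame, modality: str = "unaided", metric: str = "interval"
) -> pd.Series:
    """Per-reader test-retest Krippendorff alpha (original vs repeated)."""
    out = {}
    for reader in sorted(ratings["reader_id"].unique()):
        mat = test_retest_matrix(ratings, reader, modality)
        if np.isfinite(mat).all(axis=0).sum() < 2:
            logger.warning("reader %s: no repeat overlap; skipped", reader)
            continue
        out[reader] = krippendorff_alpha(mat, metric=metric)
    return pd.Series(out, name=f"alpha_{modality}")


@dataclass
class AgreementResult:
    """Bundled intra-/inter-reader agreement summaries for one modality."""

    bland_altman_per_reader: pd.DataFrame
    mean_bias: float
    mean_sd: float
    intra_alphas: pd.Series
    mean_intra_alpha: float
    inter_alpha: float


def agreement_summary(
    ratings: pd.DataFrame, modality: str = "unaided", metric: str = "interval"
) -> AgreementResult:
    ba = bland_altman(ratings, modality)
    alphas = intra_reader_alphas(ratings, modality, metric)
    inter = krippendorff_alpha(
        inter_reader_matrix(ratings, modality, "original"), metric=metric
    )
    return AgreementResult(
        bland_altman_per_reader=ba,
        mean_bias=float(ba["bias"].mean()) if len(ba) else float("nan"),
        mean_sd=float(ba["sd"].mean()) if len(ba) else float("nan"),
        intra_alphas=alphas,
        mean_intra_alpha=float(alphas.mean()) if len(alphas) else float("nan"),
        inter_alpha=inter,
    )
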