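"""Shared fixtures: small synthetic studies and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from respcad import synthetic_data as sd
from respcad.types import GroundTruth

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the package implementations)
# ---------------------------------------------------------------------------


def brute_force_auc(scores, labels) -> float:
    """Exhaustive positive-negative pair counting with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_alpha(data: np.ndarray, metric: str = "interval") -> float:
    """Krippendorff's alpha via explicit pairwise coincidences."""
    data = np.asarray(data, dtype=float)
    units = []
    for u in range(data.shape[1]):
        col = data[:, u]
        vals = col[np.isfinite(col)]
        if len(vals) >= 2:
            units.append(vals)
    pooled = np.concatenate(units)
    uniq = np.sort(np.unique(pooled))
    rank = {v: i for i, v in enumerate(uniq)}
    marg = np.zeros(len(uniq))
    # coincidence-weighted marginals
    for vals in units:
        m = len(vals)
        for v in vals:
            marg[rank[v]] += 1.0  # each value contributes (m-1)/(m-1)=1

    def delta2(a, b):
        if metric == "nominal":
            return 0.0 if a == b else 1.0
        if metric == "interval":
            return (a - b) ** 2
        if metric == "ordinal":
            i, j = sorted((rank[a], rank[b]))
            seg = marg[i : j + 1].sum()
            return (seg - (marg[i] + marg[j]) / 2.0) ** 2
        raise ValueError(metric)

    n = sum(len(v) for v in units)
    d_obs = 0.0
    for vals in units:
        m = len(vals)
        for i in range(m):
            for j in range(m):
                if i != j:
                    d_obs += delta2(vals[i], vals[j]) / (m - 1)
    d_obs /= n
    d_exp = 0.0
    for a in pooled:
        for b in pooled:
            d_exp += delta2(a, b)
    d_exp /= n * (n - 1)
    if d_exp == 0:
        return 1.0
    return 1.0 - d_obs / d_exp


def make_ratings_frame(rows) -> pd.DataFrame:
    """Rating rows as (reader, case, modality, round, likelihood)."""
    return pd.DataFrame(
        [
            (r, c, m, rnd, lik, 0.0, "stable_disease", "surgery")
            for (r, c, m, rnd, lik) in rows
        ],
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


def make_truth(case_ids, responded, difficulty=None) -> GroundTruth:
    case_ids = np.asarray(case_ids, dtype=object)
    responded = np.asarray(responded, dtype=bool)
    if difficulty is None:
        difficulty = np.zeros(len(case_ids))
    return GroundTruth(
        case_ids=case_ids, responded=responded, latent_difficulty=difficulty
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_image_config() -> sd.SyntheticStudyConfig:
    """A 12-case imaging cohort small enough for LOCO CNN tests."""
    return sd.SyntheticStudyConfig(
        n_cases=12,
        n_t0=5,
        n_readers=4,
        repeat_subset_size=6,
        reader_model=sd.ReaderModel(separation=1.2),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cases(small_image_config):
    cases, truth = sd.generate_case_pairs(small_image_config)
    return cases, truth


@pytest.fixture(scope="session")
def reader_study():
    """A moderate reader study (20 cases, 6 readers) with repeats."""
    cfg = sd.SyntheticStudyConfig(
        n_cases=20,
        n_t0=8,
        n_readers=6,
        repeat_subset_size=10,
        reader_model=sd.ReaderModel(separation=1.4, rating_noise_sd=8.0),
        seed=5,
    )
    return sd.simulate_study(cfg)
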