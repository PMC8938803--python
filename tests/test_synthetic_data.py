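"""Generator contracts: cohort composition, diameters, rating model, repeats."""

import numpy as np
import pandas as pd
import pytest

from respcad import synthetic_data as sd
from respcad.types import InputError, SizingError, StudyDesign

from conftest import brute_force_auc


def test_default_cohort_counts():
    """Default study: 157 cancer pairs, exactly 40 complete responders."""
    cfg = sd.SyntheticStudyConfig(seed=1)
    truth = sd._generate_truth(cfg, cfg.substream("cases"))
    assert truth.n_cases == 157
    assert truth.n_responders == 40


def test_single_nonresponder_case():
    cfg = sd.SyntheticStudyConfig(
        n_cases=1, n_t0=0, n_readers=2, repeat_subset_size=1, seed=0
    )
    cases, truth = sd.generate_case_pairs(cfg)
    assert len(cases) == 1
    assert not truth.responded[0]
    assert cases[0].pre_mask.any() and cases[0].post_mask.any()
    assert not cases[0].responded


def test_diameter_means_match_configuration():
    """Monte-Carlo: sample means of max diameter track the configured
    class means within 3 standard errors."""
    cfg = sd.SyntheticStudyConfig(n_cases=500, n_t0=250, repeat_subset_size=10, seed=3)
    truth = sd._generate_truth(cfg, cfg.substream("cases"))
    for resp, (pre_mean, post_mean) in ((True, (30.1, 14.3)), (False, (43.0, 31.2))):
        sel = truth.responded == resp
        d = np.asarray(truth.pre_diameter_mm)[sel]
        se = d.std(ddof=1) / np.sqrt(sel.sum())
        assert abs(d.mean() - pre_mean) < 3 * se
    # responders' post lesions are smaller than their pre lesions
    post = np.asarray(truth.post_diameter_mm)[truth.responded]
    pre = np.asarray(truth.pre_diameter_mm)[truth.responded]
    assert (post < pre).all()


def test_lesion_masks_match_rendered_lesions(small_cases):
    cases, truth = small_cases
    for case in cases[:3]:
        assert case.pre_volume.shape == case.pre_mask.shape
        # masked voxels carry lesion texture distinct from background
        inside = case.pre_volume[case.pre_mask].mean()
        outside = case.pre_volume[~case.pre_mask].mean()
        assert inside != pytest.approx(outside, abs=1.0)


def test_oversized_lesion_raises_sizing_error():
    cfg = sd.SyntheticStudyConfig(
        n_cases=2, n_t0=1, repeat_subset_size=1,
        image_shape=(8, 12, 12), voxel_size_mm=1.0, seed=0,
    )
    with pytest.raises(SizingError, match="C0"):
        sd.generate_case_pairs(cfg)


def test_generation_deterministic_for_fixed_seed():
    cfg = sd.SyntheticStudyConfig(
        n_cases=4, n_t0=2, n_readers=3, repeat_subset_size=2,
        reader_model=sd.ReaderModel(), seed=9,
    )
    a = sd.simulate_study(cfg, include_images=True)
    b = sd.simulate_study(cfg, include_images=True)
    assert np.array_equal(a.truth.responded, b.truth.responded)
    for ca, cb in zip(a.cases, b.cases):
        assert np.array_equal(ca.pre_volume, cb.pre_volume)
        assert np.array_equal(ca.post_mask, cb.post_mask)
    pd.testing.assert_frame_equal(a.ratings, b.ratings)
    assert a.design == b.design


def test_rating_scales_respected(reader_study):
    r = reader_study.ratings
    assert r["likelihood_t0"].between(0, 100).all()
    assert r["percent_response"].between(-100, 100).all()
    assert set(r["modality"]) <= {"unaided", "aided"}
    assert set(r["round"]) <= {"original", "repeated"}


def test_zero_aid_weight_leaves_ratings_unchanged():
    """With shrinkage weight 0 and no aided noise, aided == unaided."""
    model = sd.ReaderModel(aid_weight=0.0, aided_noise_sd=0.0)
    cfg = sd.SyntheticStudyConfig(
        n_cases=10, n_t0=4, n_readers=3, repeat_subset_size=5,
        reader_model=model, seed=2,
    )
    st = sd.simulate_study(cfg, include_repeats=False)
    pivot = st.ratings.pivot_table(
        index=["reader_id", "case_id"], columns="modality",
        values="likelihood_t0",
    )
    assert np.allclose(pivot["aided"], pivot["unaided"])


def test_full_aid_weight_reproduces_cad_ranking():
    """With weight 1 and no noise, every reader's aided AUC equals the CAD
    AUC (rank preservation under a monotone transform)."""
    model = sd.ReaderModel(aid_weight=1.0, aided_noise_sd=0.0)
    cfg = sd.SyntheticStudyConfig(
        n_cases=12, n_t0=5, n_readers=3, repeat_subset_size=5,
        reader_model=model, seed=4,
    )
    st = sd.simulate_study(cfg, include_repeats=False)
    cad_auc = brute_force_auc(
        [s.cad_score for s in st.cad_scores], st.truth.responded
    )
    aided = st.ratings[
        (st.ratings.modality == "aided") & (st.ratings["round"] == "original")
    ]
    truth_map = dict(zip(st.truth.case_ids, st.truth.responded))
    for _, grp in aided.groupby("reader_id"):
        labels = [truth_map[c] for c in grp["case_id"]]
        assert brute_force_auc(grp["likelihood_t0"], labels) == pytest.approx(
            cad_auc
        )


def test_unaided_auc_matches_binormal_closed_form():
    """Mean empirical unaided AUC tracks the noise-free binormal closed form
    when rating noise and skill spread are off."""
    target = 0.78
    model = sd.ReaderModel(
        separation=sd.separation_for_auc(target),
        case_sd=np.sqrt(0.5),
        noise_sd=np.sqrt(0.5),
        skill_sd=0.0,
        rating_noise_sd=0.0,
    )
    assert model.unaided_auc_noise_free() == pytest.approx(target)
    cfg = sd.SyntheticStudyConfig(
        n_cases=157, n_t0=40, repeat_subset_size=10, reader_model=model, seed=7
    )
    st = sd.simulate_study(cfg, include_repeats=False)
    unaided = st.ratings[
        (st.ratings.modality == "unaided") & (st.ratings["round"] == "original")
    ]
    truth_map = dict(zip(st.truth.case_ids, st.truth.responded))
    aucs = []
    for _, grp in unaided.groupby("reader_id"):
        labels = [truth_map[c] for c in grp["case_id"]]
        aucs.append(brute_force_auc(grp["likelihood_t0"], labels))
    # Monte-Carlo tolerance: SE of a single-reader AUC ~ 0.04, 17 readers
    assert abs(np.mean(aucs) - target) < 0.03


def test_increasing_separation_never_lowers_expected_auc():
    """Class-conditional monotonicity over a seed ensemble."""
    seps = [0.5, 1.0, 1.5, 2.0]
    means = []
    for sep in seps:
        aucs = []
        for seed in range(4):
            model = sd.ReaderModel(separation=sep, rating_noise_sd=5.0)
            cfg = sd.SyntheticStudyConfig(
                n_cases=60, n_t0=20, n_readers=4, repeat_subset_size=10,
                reader_model=model, seed=seed,
            )
            st = sd.simulate_study(cfg, include_repeats=False)
            unaided = st.ratings[st.ratings.modality == "unaided"]
            truth_map = dict(zip(st.truth.case_ids, st.truth.responded))
            for _, grp in unaided.groupby("reader_id"):
                labels = [truth_map[c] for c in grp["case_id"]]
                aucs.append(brute_force_auc(grp["likelihood_t0"], labels))
        means.append(np.mean(aucs))
    assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


class TestRepeatSubsets:
    def test_each_reader_gets_exact_subset_size(self, reader_study):
        rep = reader_study.design.select(round="repeated", modality="unaided")
        counts = rep.groupby("reader_id")["case_id"].nunique()
        assert (counts == reader_study.config.repeat_subset_size).all()
        assert len(counts) == reader_study.config.n_readers

    def test_exhaustive_subset_equals_original_design(self):
        cfg = sd.SyntheticStudyConfig(
            n_cases=6, n_t0=2, n_readers=2, repeat_subset_size=6,
            reader_model=sd.ReaderModel(), seed=1,
        )
        truth = sd._generate_truth(cfg, cfg.substream("cases"))
        base = StudyDesign.fully_crossed(
            [p.reader_id for p in cfg.reader_profiles],
            [str(c) for c in truth.case_ids],
        )
        full = sd.sample_repeat_subsets(base, cfg)
        rep = full.select(round="repeated")
        orig = full.select(round="original")
        assert set(map(tuple, rep[["reader_id", "case_id", "modality"]].values)) == set(
            map(tuple, orig[["reader_id", "case_id", "modality"]].values)
        )

    def test_subsets_vary_across_seeds(self):
        def subsets(seed):
            cfg = sd.SyntheticStudyConfig(
                n_cases=20, n_t0=8, n_readers=3, repeat_subset_size=5,
                reader_model=sd.ReaderModel(), seed=seed,
            )
            truth = sd._generate_truth(cfg, cfg.substream("cases"))
            base = StudyDesign.fully_crossed(
                [p.reader_id for p in cfg.reader_profiles],
                [str(c) for c in truth.case_ids],
            )
            rep = sd.sample_repeat_subsets(base, cfg).select(round="repeated")
            return {
                r: frozenset(g["case_id"])
                for r, g in rep.groupby("reader_id")
            }

        differing = sum(subsets(2 * k) != subsets(2 * k + 1) for k in range(10))
        assert differing == 10

    def test_oversized_subset_rejected(self):
        cfg = sd.SyntheticStudyConfig(
            n_cases=6, n_t0=2, n_readers=2, repeat_subset_size=6,
            reader_model=sd.ReaderModel(), seed=1,
        )
        base = StudyDesign.fully_crossed(["R01"], ["C1", "C2"])
        with pytest.raises(InputError):
            sd.sample_repeat_subsets(base, cfg)


def test_missing_cad_score_rejected():
    cfg = sd.SyntheticStudyConfig(
        n_cases=4, n_t0=2, n_readers=2, repeat_subset_size=2,
        reader_model=sd.ReaderModel(), seed=0,
    )
    truth = sd._generate_truth(cfg, cfg.substream("cases"))
    cad = sd.simulate_cad_scores(cfg, truth)[:-1]
    with pytest.raises(InputError, match="missing CaseScore"):
        sd.generate_reader_ratings(cfg, truth, cad)


def test_invalid_configs_rejected():
    with pytest.raises(InputError):
        sd.SyntheticStudyConfig(n_cases=10, n_t0=10)
    with pytest.raises(InputError):
        sd.SyntheticStudyConfig(n_cases=10, n_t0=2, repeat_subset_size=11)
    with pytest.raises(InputError):
        sd.ReaderModel(aid_weight=1.5)
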