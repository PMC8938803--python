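"""Observer-study statistics against exhaustive and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from respcad import reader_analysis as ra, synthetic_data as sd
from respcad.types import InputError

from conftest import brute_force_alpha, brute_force_auc, make_ratings_frame, make_truth


class TestReaderAuc:
    def test_perfect_reader(self):
        truth = make_truth(["a", "b", "c", "d"], [True, True, False, False])
        rows = [("R1", c, "unaided", "original", v)
                for c, v in zip("abcd", [100, 100, 0, 0])]
        auc, var = ra.reader_auc(make_ratings_frame(rows), truth, "R1")
        assert auc == 1.0

    def test_constant_reader(self):
        truth = make_truth(["a", "b", "c", "d"], [True, True, False, False])
        rows = [("R1", c, "unaided", "original", 50.0) for c in "abcd"]
        auc, _ = ra.reader_auc(make_ratings_frame(rows), truth, "R1")
        assert auc == 0.5

    def test_matches_exhaustive_pair_counting(self):
        scores = [10.0, 40.0, 40.0, 70.0, 20.0]
        labels = [False, True, False, True, True]
        truth = make_truth(list("abcde"), labels)
        rows = [("R1", c, "unaided", "original", s)
                for c, s in zip("abcde", scores)]
        auc, var = ra.reader_auc(make_ratings_frame(rows), truth, "R1")
        assert auc == pytest.approx(brute_force_auc(scores, labels))
        assert var >= 0

    def test_single_class_rejected(self):
        truth = make_truth(["a", "b"], [True, True])
        rows = [("R1", c, "unaided", "original", 50.0) for c in "ab"]
        with pytest.raises(InputError):
            ra.reader_auc(make_ratings_frame(rows), truth, "R1")

    @given(
        scale=st.floats(0.5, 3.0),
        shift=st.floats(-20.0, 20.0),
    )
    def test_invariant_under_monotone_transforms(self, scale, shift):
        rng = np.random.default_rng(0)
        scores = rng.uniform(10, 90, size=12)
        labels = np.array([True] * 5 + [False] * 7)
        truth = make_truth([f"c{i}" for i in range(12)], labels)
        base = make_ratings_frame(
            [("R1", f"c{i}", "unaided", "original", s)
             for i, s in enumerate(scores)]
        )
        trans = base.copy()
        trans["likelihood_t0"] = np.clip(
            scale * trans["likelihood_t0"] * 0.5 + shift + 10, 0, 100
        )
        a1, _ = ra.reader_auc(base, truth, "R1")
        a2, _ = ra.reader_auc(trans, truth, "R1")
        # clipping can merge extreme scores; restrict to non-clipped range
        if trans["likelihood_t0"].min() > 0 and trans["likelihood_t0"].max() < 100:
            assert a1 == pytest.approx(a2)


def _two_modality_study(rng, R=4, n=14, n_pos=6, effect=0.0):
    y = np.zeros(n, dtype=bool)
    y[:n_pos] = True
    case = 0.6 * rng.standard_normal(n)
    cids = [f"c{i}" for i in range(n)]
    rows = []
    for mod, extra in (("unaided", 0.0), ("aided", effect)):
        lat = (
            np.add.outer(np.zeros(R), (1.0 + extra) * y.astype(float))
            + case[None, :]
            + 0.8 * rng.standard_normal((R, n))
        )
        lik = 100 * stats.norm.cdf(lat)
        for r in range(R):
            rows += [
                (f"R{r}", cids[i], mod, "original", lik[r, i]) for i in range(n)
            ]
    return make_ratings_frame(rows), make_truth(cids, y, case)


class TestMrmcCompare:
    def test_identical_arms_give_zero_diff_and_p_one(self):
        rng = np.random.default_rng(0)
        ratings, truth = _two_modality_study(rng)
        una = ratings[ratings.modality == "unaided"]
        dup = una.copy()
        dup["modality"] = "aided"
        res = ra.mrmc_compare(pd.concat([una, dup]), truth)
        assert res.diff == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_mean_auc_is_mean_of_reader_aucs(self):
        rng = np.random.default_rng(1)
        ratings, truth = _two_modality_study(rng)
        res = ra.mrmc_compare(ratings, truth)
        assert res.mean_auc_a == pytest.approx(
            np.mean(list(res.reader_aucs_a.values()))
        )
        assert res.ci95[0] <= res.diff <= res.ci95[1]

    def test_reader_aucs_match_pair_counting(self):
        rng = np.random.default_rng(2)
        ratings, truth = _two_modality_study(rng)
        res = ra.mrmc_compare(ratings, truth)
        truth_map = dict(zip(truth.case_ids, truth.responded))
        una = ratings[ratings.modality == "unaided"]
        for reader, grp in una.groupby("reader_id"):
            labels = [truth_map[c] for c in grp["case_id"]]
            assert res.reader_aucs_a[reader] == pytest.approx(
                brute_force_auc(grp["likelihood_t0"], labels)
            )

    def test_ustat_variance_close_to_jackknife_on_fully_crossed_toy(self):
        """The U-statistic variance of the AUC difference tracks the
        delete-one-case jackknife reference on a small fully-crossed study."""
        rel = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            ratings, truth = _two_modality_study(rng, R=3, n=18, n_pos=8)
            res = ra.mrmc_compare(ratings, truth)
            jk = ra.jackknife_variance(ratings, truth)
            rel.append(res.var_diff / jk)
        # both are consistent estimators of the same case-sampling variance
        assert 0.5 < np.median(rel) < 2.0

    def test_reader_in_one_arm_handled_with_warning(self):
        rng = np.random.default_rng(3)
        ratings, truth = _two_modality_study(rng)
        partial = ratings[
            ~((ratings.reader_id == "R0") & (ratings.modality == "aided"))
        ]
        res = ra.mrmc_compare(partial, truth)
        assert any("R0" in w for w in res.warnings)
        assert "R0" in res.reader_aucs_a and "R0" not in res.reader_aucs_b

    def test_non_fully_crossed_repeat_arm(self, reader_study):
        """Original vs repeated comparison on per-reader random subsets."""
        res = ra.mrmc_compare(
            reader_study.ratings,
            reader_study.truth,
            ("unaided", "original"),
            ("unaided", "repeated"),
        )
        assert 0.0 <= res.p_value <= 1.0
        assert res.n_readers == reader_study.config.n_readers


class TestStratification:
    def test_unanimous_case_is_easy(self):
        rows = []
        for r in ("R1", "R2", "R3"):
            rows.append((r, "agree", "unaided", "original", 60.0))
            rows.append((r, "split", "unaided", "original",
                         {"R1": 0.0, "R2": 50.0, "R3": 100.0}[r]))
        part = ra.stratify_cases(make_ratings_frame(rows), ["R1", "R2", "R3"])
        assert part.easy_ids == ["agree"]
        assert part.difficult_ids == ["split"]

    def test_threshold_splits_sds_10_and_30(self):
        rows = []
        for i, r in enumerate(("R1", "R2")):
            rows.append((r, "low", "unaided", "original", 50.0 + i * np.sqrt(2) * 10))
            rows.append((r, "high", "unaided", "original", 40.0 + i * np.sqrt(2) * 30))
        part = ra.stratify_cases(make_ratings_frame(rows), ["R1", "R2"], threshold=25.0)
        assert part.per_case_sd["low"] == pytest.approx(10.0)
        assert part.per_case_sd["high"] == pytest.approx(30.0)
        assert part.easy_ids == ["low"] and part.difficult_ids == ["high"]

    def test_partition_matches_independent_recomputation(self, reader_study):
        readers = [p.reader_id for p in reader_study.profiles][:4]
        part = ra.stratify_cases(reader_study.ratings, readers)
        sub = reader_study.ratings[
            (reader_study.ratings.modality == "unaided")
            & (reader_study.ratings["round"] == "original")
            & (reader_study.ratings.reader_id.isin(readers))
        ]
        for case_id, grp in sub.groupby("case_id"):
            sd_ref = np.std(grp["likelihood_t0"].to_numpy(), ddof=1)
            assert part.per_case_sd[case_id] == pytest.approx(sd_ref)
            expected = "easy" if sd_ref <= 25.0 else "difficult"
            assert case_id in (
                part.easy_ids if expected == "easy" else part.difficult_ids
            )

    def test_missing_rating_rejected(self):
        rows = [("R1", "a", "unaided", "original", 10.0),
                ("R1", "b", "unaided", "original", 10.0),
                ("R2", "a", "unaided", "original", 20.0)]
        with pytest.raises(InputError, match="b"):
            ra.stratify_cases(make_ratings_frame(rows), ["R1", "R2"])


class TestSubgroups:
    def test_single_group_reduces_to_overall(self, reader_study):
        profiles = reader_study.profiles
        overall = ra.mrmc_compare(reader_study.ratings, reader_study.truth)
        by_prof = ra.subgroup_mrmc(
            reader_study.ratings, reader_study.truth, profiles, "proficiency"
        )
        # reader partition: subgroup AUC lists partition the overall list
        all_readers = set(overall.reader_aucs_a)
        group_readers = [set(res.reader_aucs_a) for res in by_prof.values()]
        assert set().union(*group_readers) == all_readers
        assert sum(len(g) for g in group_readers) == len(all_readers)
        for res in by_prof.values():
            for reader, auc in res.reader_aucs_a.items():
                assert auc == pytest.approx(overall.reader_aucs_a[reader])

    def test_difficulty_grouping_orders_aucs(self):
        """Planted difficulty: cases with large latent difficulty spread are
        harder; the easy-subset mean AUC exceeds the difficult-subset one
        for the same readers (checked over seeds)."""
        wins = 0
        for seed in range(3):
            model = sd.ReaderModel(separation=1.4, case_sd=1.2,
                                   rating_noise_sd=5.0)
            cfg = sd.SyntheticStudyConfig(
                n_cases=60, n_t0=24, n_readers=6, repeat_subset_size=10,
                reader_model=model, seed=seed + 40,
            )
            study = sd.simulate_study(cfg, include_repeats=False)
            part = ra.stratify_cases(
                study.ratings, [p.reader_id for p in study.profiles]
            )
            if len(part.easy_ids) < 8 or len(part.difficult_ids) < 8:
                continue
            try:
                res = ra.subgroup_mrmc(
                    study.ratings, study.truth, study.profiles, "difficulty",
                    partition=part,
                )
            except InputError:  # a subset may lack an outcome class
                continue
            if "easy" in res and "difficult" in res:
                wins += res["easy"].mean_auc_a > res["difficult"].mean_auc_a
        assert wins >= 2


class TestBlandAltman:
    @staticmethod
    def _paired(rows):
        return make_ratings_frame(rows)

    def test_identical_rounds_give_zero_bias_and_sd(self):
        rows = []
        for c, v in zip("abc", (10.0, 50.0, 90.0)):
            rows.append(("R1", c, "unaided", "original", v))
            rows.append(("R1", c, "unaided", "repeated", v))
        ba = ra.bland_altman(self._paired(rows))
        assert ba.loc[0, "bias"] == 0.0
        assert ba.loc[0, "sd"] == 0.0

    def test_plus_minus_ten_differences(self):
        rows = [
            ("R1", "a", "unaided", "original", 50.0),
            ("R1", "a", "unaided", "repeated", 60.0),
            ("R1", "b", "unaided", "original", 50.0),
            ("R1", "b", "unaided", "repeated", 40.0),
        ]
        ba = ra.bland_altman(self._paired(rows))
        assert ba.loc[0, "bias"] == 0.0
        assert ba.loc[0, "sd"] == pytest.approx(np.sqrt(200), abs=0.01)

    def test_sd_matches_sqrt2_closed_form(self):
        """Independent test-retest noise of SD sigma on both reads gives a
        difference SD of sigma * sqrt(2)."""
        sigma = 6.0
        model = sd.ReaderModel(
            separation=0.0, case_sd=0.3, noise_sd=0.3,
            rating_noise_sd=sigma, aid_weight=0.0, aided_noise_sd=0.0,
        )
        cfg = sd.SyntheticStudyConfig(
            n_cases=120, n_t0=40, n_readers=8, repeat_subset_size=120,
            reader_model=model, seed=13,
        )
        study = sd.simulate_study(cfg)
        ba = ra.bland_altman(study.ratings)
        assert ba["sd"].mean() == pytest.approx(sigma * np.sqrt(2), rel=0.08)


class TestKrippendorffAlpha:
    WORKED = np.array(
        [
            [1, 2, 3, 3, 2, 1, 4, 1, 2, np.nan],
            [1, 2, 3, 3, 2, 2, 4, 1, 2, 5],
            [np.nan, 3, 3, 3, 2, 3, 4, 2, 2, 5],
            [1, 2, 3, 3, 2, 4, 4, 1, 2, 5],
        ],
        dtype=float,
    )

    def test_perfect_agreement(self):
        data = np.tile(np.arange(1.0, 6.0), (3, 1))
        assert ra.krippendorff_alpha(data) == 1.0

    @pytest.mark.parametrize("metric", ["nominal", "ordinal", "interval"])
    def test_matches_brute_force_on_worked_matrix(self, metric):
        impl = ra.krippendorff_alpha(self.WORKED, metric=metric)
        ref = brute_force_alpha(self.WORKED, metric=metric)
        assert impl == pytest.approx(ref)

    def test_random_ratings_give_alpha_near_zero(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 100, size=(6, 300))
        assert abs(ra.krippendorff_alpha(data)) < 0.05

    def test_invariant_to_coder_and_unit_relabeling(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 5, size=(4, 20)).astype(float)
        data[rng.uniform(size=data.shape) < 0.2] = np.nan
        base = ra.krippendorff_alpha(data)
        perm = data[np.random.default_rng(2).permutation(4)][
            :, np.random.default_rng(3).permutation(20)
        ]
        assert ra.krippendorff_alpha(perm) == pytest.approx(base)

    def test_degenerate_identical_values(self):
        data = np.full((3, 5), 7.0)
        assert ra.krippendorff_alpha(data) == 1.0

    def test_intra_reader_alphas_on_repeat_subsets(self, reader_study):
        alphas = ra.intra_reader_alphas(reader_study.ratings)
        assert len(alphas) == reader_study.config.n_readers
        assert (alphas <= 1.0).all()
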