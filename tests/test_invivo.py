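"""Longitudinal preprocessing, abundance-change t-statistics, dysbiosis test."""

import numpy as np
import pandas as pd
import pytest

from microimpact import synthetic_data as sd
from microimpact.invivo import (
    LongitudinalStudy,
    abundance_change_tstats,
    cohort_agreement,
    dysbiosis_test,
    preprocess_study,
    shuffled_feature_control,
)


def make_filter_fixture():
    """10 samples x 30 ASVs engineered to hit every filter threshold.

    4 subjects x {before, after} at depth 5000 plus two 800-read samples;
    20 ASVs at 4.9% everywhere, 10 ASVs at 0.2% everywhere.
    """
    asvs = [f"asv{i:02d}" for i in range(30)]
    profile = np.array([0.049] * 20 + [0.002] * 10)
    rows, meta = [], []
    for s in range(4):
        for phase in ("before", "after"):
            sid = f"s{s}_{phase}"
            rows.append(pd.Series(profile, index=asvs, name=sid))
            meta.append(
                {"sample_id": sid, "subject_id": f"s{s}", "phase": phase,
                 "timepoint": 0, "read_depth": 5000}
            )
    for k in range(2):
        sid = f"shallow{k}"
        rows.append(pd.Series(profile, index=asvs, name=sid))
        meta.append(
            {"sample_id": sid, "subject_id": f"x{k}", "phase": "before",
             "timepoint": 0, "read_depth": 800}
        )
    return LongitudinalStudy(
        pd.DataFrame(rows), pd.DataFrame(meta).set_index("sample_id")
    )


class TestPreprocess:
    def test_fixture_filters_to_8_samples_by_20_asvs(self):
        out = preprocess_study(make_filter_fixture())
        assert out.abundance.shape == (8, 20)
        assert np.allclose(out.abundance.sum(axis=1), 1.0, atol=1e-6)

    def test_idempotent(self):
        once = preprocess_study(make_filter_fixture())
        twice = preprocess_study(once)
        pd.testing.assert_frame_equal(once.abundance, twice.abundance)

    def test_same_phase_samples_averaged(self):
        asvs = ["a", "b"]
        rows = {
            "s0_after_0": [0.1, 0.9],
            "s0_after_1": [0.2, 0.8],
            "s0_after_2": [0.3, 0.7],
            "s0_before_0": [0.5, 0.5],
        }
        ab = pd.DataFrame.from_dict(rows, orient="index", columns=asvs)
        meta = pd.DataFrame(
            {
                "subject_id": ["s0"] * 4,
                "phase": ["after", "after", "after", "before"],
                "timepoint": [0, 1, 2, 0],
                "read_depth": [5000] * 4,
            },
            index=ab.index,
        )
        out = preprocess_study(LongitudinalStudy(ab, meta))
        assert out.abundance.loc["s0__after", "a"] == pytest.approx(0.2)

    def test_all_samples_shallow_is_error(self):
        fx = make_filter_fixture()
        fx.metadata["read_depth"] = 10
        with pytest.raises(ValueError, match="read depth"):
            preprocess_study(fx)

    def test_single_phase_subject_excluded_with_warning(self):
        fx = make_filter_fixture()
        keep = fx.metadata["phase"].eq("before") | fx.metadata["subject_id"].ne("s0")
        fx = LongitudinalStudy(fx.abundance.loc[keep], fx.metadata.loc[keep])
        with pytest.warns(UserWarning, match="single phase"):
            out = preprocess_study(fx)
        assert "s0" not in set(out.metadata["subject_id"])


class TestTStatistics:
    def _study(self, before, after):
        asvs = [f"a{i}" for i in range(np.shape(before)[1])]
        rows, meta = [], []
        for i, prof in enumerate(before):
            rows.append(pd.Series(prof, index=asvs, name=f"s{i}__before"))
            meta.append({"sample_id": f"s{i}__before", "subject_id": f"s{i}",
                         "phase": "before", "timepoint": 0, "read_depth": 5000})
        for i, prof in enumerate(after):
            rows.append(pd.Series(prof, index=asvs, name=f"s{i}__after"))
            meta.append({"sample_id": f"s{i}__after", "subject_id": f"s{i}",
                         "phase": "after", "timepoint": 0, "read_depth": 5000})
        return LongitudinalStudy(
            pd.DataFrame(rows), pd.DataFrame(meta).set_index("sample_id")
        )

    def test_hand_computed_welch_example(self):
        study = self._study(before=[[0.2], [0.4]], after=[[0.1], [0.1]])
        t, excluded = abundance_change_tstats(study)
        assert t["a0"] == pytest.approx(-2.0)
        assert not excluded

    def test_identical_phases_give_zero(self):
        study = self._study(before=[[0.3], [0.3]], after=[[0.3], [0.3]])
        t, _ = abundance_change_tstats(study)
        assert t["a0"] == 0.0

    def test_uniform_depletion_is_negative(self):
        rng = np.random.default_rng(0)
        before = rng.uniform(0.2, 0.4, size=(5, 3))
        study = self._study(before=before, after=before * 0.5)
        t, _ = abundance_change_tstats(study)
        assert (t < 0).all()

    def test_matches_welch_formula_oracle(self):
        rng = np.random.default_rng(1)
        before = rng.uniform(0, 1, size=(6, 10))
        after = rng.uniform(0, 1, size=(6, 10))
        study = self._study(before, after)
        t, _ = abundance_change_tstats(study)
        for j in range(10):
            b, a = before[:, j], after[:, j]
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            assert t[f"a{j}"] == pytest.approx((a.mean() - b.mean()) / se, abs=1e-9)

    def test_paired_mode_uses_subject_matching(self):
        before = [[0.2], [0.4], [0.6]]
        after = [[0.1], [0.3], [0.5]]
        study = self._study(before, after)
        t, _ = abundance_change_tstats(study, paired=True)
        # constant shift of -0.1 with zero variance of differences -> -inf;
        # add jitter instead
        before = [[0.2], [0.4], [0.6]]
        after = [[0.05], [0.35], [0.52]]
        t, _ = abundance_change_tstats(self._study(before, after), paired=True)
        diffs = np.array([-0.15, -0.05, -0.08])
        expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
        assert t["a0"] == pytest.approx(expected, abs=1e-9)


class TestDysbiosisTest:
    def test_exact_small_sample_p(self):
        impact = pd.Series(
            [0.9, 0.8, 0.7, 0.3, 0.2, 0.1], index=list("abcdef")
        )
        t = pd.Series([-1, -1, -1, 1, 1, 1.0], index=list("abcdef"))
        res = dysbiosis_test(impact, t)
        assert res.p_value == pytest.approx(0.1)
        assert res.rank_biserial == pytest.approx(1.0)
        assert res.n_decreased == 3 and res.n_increased == 3

    def test_zero_t_asvs_counted_but_excluded(self):
        impact = pd.Series([0.9, 0.8, 0.2, 0.1, 0.5], index=list("abcde"))
        t = pd.Series([-1, -1, 1, 1, 0.0], index=list("abcde"))
        res = dysbiosis_test(impact, t)
        assert res.n_zero_t == 1
        assert res.n_decreased + res.n_increased == 4

    def test_empty_group_rejected(self):
        impact = pd.Series([0.5, 0.6], index=["a", "b"])
        with pytest.raises(ValueError, match="non-empty"):
            dysbiosis_test(impact, pd.Series([-1, -1.0], index=["a", "b"]))

    def test_p_invariant_under_monotone_transform_of_scores(self):
        rng = np.random.default_rng(3)
        impact = pd.Series(rng.uniform(0, 1, 20), index=range(20))
        t = pd.Series(rng.normal(size=20), index=range(20))
        base = dysbiosis_test(impact, t)
        warped = dysbiosis_test(impact**3 * 0.5 + 0.1, t)
        assert base.p_value == pytest.approx(warped.p_value)
        assert base.rank_biserial == pytest.approx(warped.rank_biserial)


class TestShuffledControl:
    def test_zero_shuffles_rejected(self, small_screen):
        from microimpact.model import train

        tm = train(small_screen["dataset"], hyperparams={"n_estimators": 30}, seed=0)
        with pytest.raises(ValueError):
            shuffled_feature_control(
                tm,
                small_screen["dataset"].drug_features.iloc[0],
                small_screen["microbe_features"],
                pd.Series(1.0, index=small_screen["microbe_features"].index),
                n_shuffles=0,
            )

    def test_deterministic_for_fixed_seed(self, small_screen):
        from microimpact.model import train

        ds = small_screen["dataset"]
        tm = train(ds, hyperparams={"n_estimators": 30}, seed=0)
        rng = np.random.default_rng(0)
        taxa = ds.microbe_features.index
        t = pd.Series(rng.normal(size=len(taxa)), index=taxa)
        args = (tm, ds.drug_features.iloc[0], ds.microbe_features, t)
        a = shuffled_feature_control(*args, n_shuffles=5, seed=9)
        b = shuffled_feature_control(*args, n_shuffles=5, seed=9)
        assert np.array_equal(a, b)


class TestCohortAgreement:
    def test_perfect_anticorrelation_recovered(self):
        taxa = [f"t{i}" for i in range(5)]
        predicted = np.linspace(0.1, 0.9, 5)
        rows = []
        for m, p in zip(taxa, predicted):
            rows.append({"drug_id": "g", "microbe_id": m, "impact_score": p})
        catalog = pd.DataFrame(rows)
        assoc = pd.DataFrame(
            {"taxon": taxa, "drug_group": "g", "effect_size": -predicted}
        )
        out = cohort_agreement(catalog, assoc)
        assert out["taxon_correlation"]["pearson_r"] == pytest.approx(-1.0)

    def test_wilcoxon_only_for_strictly_more_than_30_associations(self):
        rng = np.random.default_rng(4)

        def build(n):
            taxa = [f"t{i}" for i in range(n)]
            pred = np.concatenate([rng.uniform(0.6, 1, n // 2),
                                   rng.uniform(0, 0.4, n - n // 2)])
            catalog = pd.DataFrame(
                {"drug_id": "g", "microbe_id": taxa, "impact_score": pred}
            )
            effect = np.where(np.arange(n) < n // 2, -1.0, 1.0)
            assoc = pd.DataFrame(
                {"taxon": taxa, "drug_group": "g", "effect_size": effect}
            )
            return catalog, assoc

        catalog, assoc = build(30)
        assert cohort_agreement(catalog, assoc)["high_burden_drug_tests"] == {}
        catalog, assoc = build(31)
        tests = cohort_agreement(catalog, assoc)["high_burden_drug_tests"]
        assert "g" in tests and tests["g"]["p_value"] < 0.05

    def test_unmappable_group_dropped_with_warning(self):
        catalog = pd.DataFrame(
            {"drug_id": ["g"] * 2, "microbe_id": ["a", "b"], "impact_score": [0.1, 0.9]}
        )
        assoc = pd.DataFrame(
            {"taxon": ["a", "zz"], "drug_group": ["g", "nope"], "effect_size": [-1, 1.0]}
        )
        with pytest.warns(UserWarning, match="unmappable"):
            out = cohort_agreement(catalog, assoc)
        assert list(out["per_drug"].index) == ["g"]


def test_generated_low_depth_samples_are_filtered_out():
    rng = np.random.default_rng(0)
    impact = pd.Series(rng.uniform(0, 1, 12), index=[f"a{i}" for i in range(12)])
    study = sd.gen_longitudinal(
        impact, n_subjects=4, effect_strength=1.0, seed=1, low_depth_samples=2
    )
    assert (study.metadata["read_depth"] < 1000).sum() == 2
    out = preprocess_study(study)
    assert (out.metadata["read_depth"] >= 1000).all()
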