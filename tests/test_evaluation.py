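"""Metrics and hold-out schemes: oracles, leakage structure, edge cases."""

import numpy as np
import pandas as pd
import pytest

import microimpact.evaluation as ev
from microimpact.evaluation import (
    UndefinedMetricError,
    binary_metrics,
    kfold_cv,
    leave_one_drug_out,
    leave_one_microbe_out,
    leave_phylum_out,
)
from microimpact.model import InteractionDataset, train

from .conftest import FAST_FOREST


def _auc_oracle(scores, labels):
    """Pairwise comparison probability with half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_hand_computed_four_point_example(self):
        roc, _ = binary_metrics([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0])
        assert roc == pytest.approx(0.75)

    def test_perfect_ranking(self):
        roc, pr = binary_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc == 1.0 and pr == 1.0

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            binary_metrics([0.1, 0.9], [1, 1])

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = rng.integers(4, 200)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # coarse grid forces ties
            scores = rng.integers(0, 5, size=n) / 4.0
            roc, _ = binary_metrics(scores, labels)
            assert roc == pytest.approx(_auc_oracle(scores, labels), abs=1e-12)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.random(1000)
        labels = rng.integers(0, 2, 1000)
        roc, _ = binary_metrics(scores, labels)
        assert roc == pytest.approx(0.5, abs=0.05)


@pytest.fixture(scope="module")
def screen(small_screen):
    return small_screen["dataset"]


class TestKFold:
    def test_held_out_predictions_partition_pairs(self, screen):
        res = kfold_cv(screen, k=5, seed=0, hyperparams=FAST_FOREST)
        assert len(res.predictions) == len(screen.pairs)
        key = res.predictions[["drug_id", "microbe_id"]].apply(tuple, axis=1)
        assert key.is_unique

    def test_same_seed_reproduces_pooled_auc(self, screen):
        a = kfold_cv(screen, k=5, seed=1, hyperparams=FAST_FOREST)
        b = kfold_cv(screen, k=5, seed=1, hyperparams=FAST_FOREST)
        assert a.roc_auc == b.roc_auc and a.pr_auc == b.pr_auc

    def test_k_below_two_rejected(self, screen):
        with pytest.raises(ValueError):
            kfold_cv(screen, k=1)


class TestLeakageStructure:
    """Every scheme must keep its held-out unit entirely out of training."""

    def _record_training(self, monkeypatch):
        seen = []
        original = ev._fit_predict

        def spy(dataset, train_mask, test_pairs, hyperparams, seed):
            seen.append(
                (
                    set(dataset.pairs.loc[train_mask, "drug_id"]),
                    set(dataset.pairs.loc[train_mask, "microbe_id"]),
                    set(test_pairs["drug_id"]),
                    set(test_pairs["microbe_id"]),
                )
            )
            return original(dataset, train_mask, test_pairs, hyperparams, seed)

        monkeypatch.setattr(ev, "_fit_predict", spy)
        return seen

    def test_lodo_never_trains_on_held_out_drug(self, screen, monkeypatch):
        seen = self._record_training(monkeypatch)
        leave_one_drug_out(screen, seed=0, hyperparams=FAST_FOREST)
        assert seen
        for train_drugs, _, test_drugs, _ in seen:
            assert not train_drugs & test_drugs

    def test_lomo_never_trains_on_held_out_strain(self, screen, monkeypatch):
        seen = self._record_training(monkeypatch)
        leave_one_microbe_out(screen, seed=0, hyperparams=FAST_FOREST)
        for _, train_microbes, _, test_microbes in seen:
            assert not train_microbes & test_microbes

    def test_lopho_excludes_the_whole_phylum(self, small_screen, monkeypatch):
        screen = small_screen["dataset"]
        taxonomy = small_screen["panel"].taxonomy["phylum"]
        seen = self._record_training(monkeypatch)
        leave_phylum_out(screen, taxonomy, seed=0, hyperparams=FAST_FOREST)
        for _, train_microbes, _, test_microbes in seen:
            held_phyla = set(taxonomy.loc[list(test_microbes)])
            train_phyla = set(taxonomy.loc[list(train_microbes)])
            assert not held_phyla & train_phyla


class TestLeaveOneDrugOut:
    def test_cutoff_one_equals_plain_scheme(self, small_screen):
        screen = small_screen["dataset"]
        fps = small_screen["drugs"].fingerprints
        plain = leave_one_drug_out(screen, seed=2, hyperparams=FAST_FOREST)
        cut = leave_one_drug_out(
            screen, tc_cutoff=1.0, fingerprints=fps, seed=2, hyperparams=FAST_FOREST
        )
        assert plain.roc_auc == pytest.approx(cut.roc_auc)

    def test_cutoff_without_fingerprints_rejected(self, screen):
        with pytest.raises(ValueError, match="fingerprints"):
            leave_one_drug_out(screen, tc_cutoff=0.5)

    def test_per_drug_diagnostics_report_training_size(self, small_screen):
        screen = small_screen["dataset"]
        fps = small_screen["drugs"].fingerprints
        res = leave_one_drug_out(
            screen, tc_cutoff=0.8, fingerprints=fps, seed=2, hyperparams=FAST_FOREST
        )
        ok = res.per_unit[res.per_unit["evaluable"]]
        assert (ok["n_train_drugs"] < screen.pairs["drug_id"].nunique()).all()
        assert ok["nn_tc_distance"].between(0, 1).all()


class TestLeaveOneMicrobeOut:
    def test_fewer_than_three_strains_rejected(self, screen):
        two = screen.subset(
            screen.pairs["microbe_id"].isin(screen.pairs["microbe_id"].unique()[:2])
        )
        with pytest.raises(ValueError, match="3 strains"):
            leave_one_microbe_out(two)

    def test_constant_distances_reported_undefined(self, screen):
        strains = screen.pairs["microbe_id"].unique()
        dist = pd.DataFrame(1.0, index=strains, columns=strains)
        np.fill_diagonal(dist.values, 0.0)
        res = leave_one_microbe_out(
            screen, phylo_distances=dist, seed=0, hyperparams=FAST_FOREST
        )
        assert res.params["auc_distance_pearson"] is None

    def test_distance_correlation_computed_when_variable(self, small_screen):
        res = leave_one_microbe_out(
            small_screen["dataset"],
            phylo_distances=small_screen["panel"].distances,
            seed=0,
            hyperparams=FAST_FOREST,
        )
        assert "auc_distance_pearson" in res.params
        assert res.params["auc_distance_pearson"] is not None


class TestLeavePhylumOut:
    def test_singleton_phylum_strain_is_skipped(self, small_screen):
        screen = small_screen["dataset"]
        taxonomy = small_screen["panel"].taxonomy["phylum"].copy()
        lone = screen.pairs["microbe_id"].unique()[0]
        taxonomy.loc[lone] = "Verrucomicrobia"
        res = leave_phylum_out(screen, taxonomy, seed=0, hyperparams=FAST_FOREST)
        row = res.per_unit.set_index("microbe_id").loc[lone]
        assert bool(row["skipped"])

    def test_single_phylum_everywhere_is_error(self, screen):
        strains = screen.pairs["microbe_id"].unique()
        taxonomy = pd.Series("Firmicutes", index=strains)
        with pytest.raises(ValueError, match="one phylum"):
            leave_phylum_out(screen, taxonomy)

    def test_two_phyla_match_leave_clade_out_brute_force(self, small_screen):
        screen = small_screen["dataset"]
        taxonomy = small_screen["panel"].taxonomy["phylum"]
        res = leave_phylum_out(screen, taxonomy, seed=4, hyperparams=FAST_FOREST)
        # oracle: for one strain, train manually on the other phylum only
        strain = res.predictions["unit"].iloc[0]
        other = taxonomy.index[taxonomy != taxonomy[strain]]
        keep = screen.pairs["microbe_id"].isin(other)
        tm = train(screen.subset(keep), hyperparams=FAST_FOREST, seed=4)
        from microimpact.model import assemble_pair_features

        held = screen.pairs[screen.pairs["microbe_id"] == strain]
        X, _ = assemble_pair_features(screen, held)
        oracle_scores = tm.estimator.impact_scores(tm.check_features(X))
        got = res.predictions.loc[
            res.predictions["unit"] == strain, "score"
        ].to_numpy()
        assert np.allclose(got, oracle_scores)
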