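"""Metric suite, AUC, fold construction, negative sampling and leakage."""

import numpy as np
import pytest

from drugrelink.evaluate import (
    EvalReport,
    _training_view,
    compute_metrics,
    make_folds,
    roc_auc,
    sample_negatives,
)
from drugrelink.model import DrugDiseaseModel
from .conftest import random_association


class TestComputeMetrics:
    def test_worked_confusion_matrix(self):
        # TP=90, FP=10, FN=10, TN=90
        y = np.r_[np.ones(100), np.zeros(100)].astype(int)
        p = np.r_[np.ones(90), np.zeros(10), np.ones(10), np.zeros(90)].astype(int)
        acc, prec, rec, f1 = compute_metrics(y, p)
        assert (acc, prec, rec, f1) == pytest.approx((0.9, 0.9, 0.9, 0.9))

    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        assert compute_metrics(y, y) == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_no_predicted_positives(self, caplog):
        with caplog.at_level("WARNING"):
            acc, prec, rec, f1 = compute_metrics([1, 0, 1], [0, 0, 0])
        assert prec == 0.0 and rec == 0.0 and f1 == 0.0
        assert any("precision" in r.message for r in caplog.records)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 0], [1])

    def test_against_sklearn_oracle_on_random_instances(self):
        from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            acc, prec, rec, f1 = compute_metrics(y, p)
            assert acc == pytest.approx(accuracy_score(y, p))
            assert prec == pytest.approx(precision_score(y, p, zero_division=0))
            assert rec == pytest.approx(recall_score(y, p, zero_division=0))
            assert f1 == pytest.approx(f1_score(y, p, zero_division=0))


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.1, 0.2])

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 2000)
        s = rng.random(2000)
        _, auc = roc_auc(y, s)
        n1, n0 = (y == 1).sum(), (y == 0).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))  # null SE of Mann-Whitney AUC
        assert abs(auc - 0.5) < 3 * se

    def test_matches_concordance_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            _, auc = roc_auc(y, s)
            pos, neg = s[y == 1], s[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_roc_endpoints(self):
        roc, _ = roc_auc([0, 1, 0, 1], [0.3, 0.6, 0.2, 0.9])
        assert roc[0].tolist() == [0.0, 0.0]
        assert roc[-1].tolist() == [1.0, 1.0]


class TestSampleNegatives:
    def test_never_collides_with_positives(self, tiny_assoc):
        negs = sample_negatives(tiny_assoc, 5, seed=0)
        for drug_id, disease_id, lab in negs:
            assert lab == 0
            assert tiny_assoc.values[
                tiny_assoc.disease_index(disease_id), tiny_assoc.drug_index(drug_id)
            ] == 0

    def test_seed_determinism_and_difference(self, tiny_assoc):
        a = sample_negatives(tiny_assoc, 6, seed=1)
        b = sample_negatives(tiny_assoc, 6, seed=1)
        c = sample_negatives(tiny_assoc, 6, seed=2)
        assert a == b
        assert a != c

    def test_without_replacement_and_bounds(self, tiny_assoc):
        n_zero = int((tiny_assoc.values == 0).sum())
        negs = sample_negatives(tiny_assoc, n_zero, seed=0)
        assert len(set(negs)) == n_zero
        with pytest.raises(ValueError):
            sample_negatives(tiny_assoc, n_zero + 1, seed=0)


class TestFolds:
    def test_partition_and_stratification(self, synth_small):
        am, _, _, _ = synth_small
        positives = [
            (am.drug_ids[j], am.disease_ids[i], 1) for i, j in np.argwhere(am.values == 1)
        ]
        negatives = sample_negatives(am, len(positives), seed=0)
        samples = positives + negatives
        folds = make_folds(samples, 5, seed=0)
        all_test = [p for f in folds for p in f.test_pairs]
        assert sorted(all_test) == sorted(samples)  # disjoint union
        pos_counts = [sum(l for _, _, l in f.test_pairs) for f in folds]
        assert max(pos_counts) - min(pos_counts) <= 1
        for f in folds:
            assert sorted(f.train_pairs + f.test_pairs) == sorted(samples)

    def test_too_few_positives_rejected(self, tiny_assoc):
        positives = [("d1", "e1", 1), ("d2", "e1", 1)]
        with pytest.raises(ValueError):
            make_folds(positives + [("d3", "e2", 0)] * 3, 10, seed=0)


class TestEvalReport:
    def test_mean_sd_recomputable(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "fold": range(1, 11),
            "acc": rng.random(10) * 100,
            "prec": rng.random(10) * 100,
            "recall": rng.random(10) * 100,
            "f1": rng.random(10) * 100,
            "auc": rng.random(10),
        })
        rep = EvalReport(df, [], seed=0)
        for col in ["acc", "prec", "recall", "f1", "auc"]:
            assert rep.mean[col] == pytest.approx(df[col].mean(), abs=1e-9)
            assert rep.std[col] == pytest.approx(df[col].std(ddof=1), abs=1e-9)
        assert "Average" in rep.summary()

    def test_json_round_trip(self, tmp_path):
        import json
        import pandas as pd

        df = pd.DataFrame(
            {"fold": [1], "acc": [90.0], "prec": [91.0], "recall": [89.0],
             "f1": [90.0], "auc": [0.95]}
        )
        rep = EvalReport(df, [], seed=3)
        rep.to_json(tmp_path / "r.json")
        back = json.loads((tmp_path / "r.json").read_text())
        assert back["seed"] == 3
        assert back["folds"][0]["acc"] == 90.0


class TestLeakage:
    def test_marker_test_pair_never_influences_training_view(self, synth_small):
        """A positive that sits in the test fold must leave no trace in the
        similarity matrices the fold's model trains on."""
        am, dsim, esim, _ = synth_small
        zero_cells = np.argwhere(am.values == 0)
        i, j = zero_cells[0]
        marked = am.copy()
        marked.values[i, j] = 1  # plant a unique marker association
        marker_pair = (am.drug_ids[j], am.disease_ids[i], 1)

        view_plain = _training_view(am, [])
        view_marked = _training_view(marked, [marker_pair])
        assert np.array_equal(view_plain.values, view_marked.values)

        rsim_a, sim_a = DrugDiseaseModel(view_plain, dsim, esim).fused_similarities()
        rsim_b, sim_b = DrugDiseaseModel(view_marked, dsim, esim).fused_similarities()
        assert np.array_equal(rsim_a.values, rsim_b.values)
        assert np.array_equal(sim_a.values, sim_b.values)

    def test_training_view_zeroes_only_test_positives(self, synth_small):
        am, _, _, _ = synth_small
        positives = [
            (am.drug_ids[j], am.disease_ids[i], 1) for i, j in np.argwhere(am.values == 1)
        ]
        test = positives[:5] + [(am.drug_ids[0], am.disease_ids[0], 0)]
        view = _training_view(am, test)
        assert am.n_associations - view.n_associations == sum(
            am.values[am.disease_index(e), am.drug_index(d)] for d, e, l in test if l
        )
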