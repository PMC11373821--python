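"""Metrics against brute-force oracles; training, prediction and protocols."""

import numpy as np
import pytest

from icrbp import (
    EncodingConfig, LabeledDataset, ModelConfig, SplitSpec, TrainConfig,
    assemble_model, compute_metrics, cross_validate, generalizability_split,
    predict, train,
)
from icrbp.sequence_io import NucleotideSequence, SequenceError
from icrbp.train_eval import ConfusionCounts


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_confusion(labels, scores, thr=0.5):
    tp = fp = tn = fn = 0
    for y, s in zip(labels, scores):
        if s >= thr:
            tp, fp = tp + (y == 1), fp + (y == 0)
        else:
            fn, tn = fn + (y == 1), tn + (y == 0)
    return tp, fp, tn, fn


def oracle_auc(labels, scores):
    """Pairwise probability that a positive outscores a negative (ties 1/2)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if not pos or not neg:
        return None
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetricsOracle:
    def test_perfect_separation(self):
        rep = compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert (rep.auc, rep.acc, rep.mcc, rep.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_symmetric_confusion(self):
        labels = [1] * 50 + [0] * 50
        scores = [0.9] * 25 + [0.1] * 25 + [0.9] * 25 + [0.1] * 25
        rep = compute_metrics(labels, scores)
        assert rep.counts == ConfusionCounts(25, 25, 25, 25)
        assert rep.acc == 0.5
        assert rep.mcc == 0.0

    def test_derived_arithmetic_example(self):
        # TP=90, FN=10, TN=80, FP=20
        labels = [1] * 100 + [0] * 100
        scores = [0.9] * 90 + [0.1] * 10 + [0.9] * 20 + [0.1] * 80
        rep = compute_metrics(labels, scores)
        assert rep.counts == ConfusionCounts(tp=90, fp=20, tn=80, fn=10)
        assert rep.acc == pytest.approx(0.85)
        assert rep.mcc == pytest.approx(7000 / np.sqrt(110 * 100 * 100 * 90))
        assert rep.f1 == pytest.approx(180 / 210)

    def test_against_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 40)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            rep = compute_metrics(labels, scores)
            tp, fp, tn, fn = oracle_confusion(labels, scores)
            assert (rep.counts.tp, rep.counts.fp, rep.counts.tn, rep.counts.fn) == \
                (tp, fp, tn, fn)
            assert rep.auc == pytest.approx(oracle_auc(labels, scores))

    def test_auc_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        a = compute_metrics(labels, scores).auc
        b = compute_metrics(labels, np.exp(3 * scores) - 0.5).auc
        assert a == pytest.approx(b)

    def test_label_swap_symmetry_via_oracle(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        rep = compute_metrics(labels, scores)
        flipped = compute_metrics(1 - labels, 1 - scores, threshold=0.5)
        # complementing labels and scores maps TP<->TN and FP<->FN, so MCC is
        # unchanged and the new TPR is the old specificity
        assert flipped.mcc == pytest.approx(rep.mcc)
        assert flipped.tpr == pytest.approx(1 - rep.fpr)
        assert flipped.auc == pytest.approx(rep.auc)

    def test_zero_denominator_flagged_not_raised(self):
        rep = compute_metrics([1, 1, 1], [0.9, 0.8, 0.7])
        assert rep.fpr == 0.0
        assert "FPR" in rep.undefined and "AUC" in rep.undefined

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 2], [0.1, 0.9])


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained(tiny_dataset, tiny_embedding, tiny_encoding):
    model = assemble_model(ModelConfig.small(), tiny_encoding, input_length=40,
                           seed=0)
    tcfg = TrainConfig(batch_size=16, max_epochs=4, patience=4, val_fraction=0.2,
                       seed=0)
    history = train(model, tiny_dataset, tiny_embedding, tcfg)
    return model, history


class TestTraining:
    def test_loss_decreases(self, trained):
        _, history = trained
        assert history["loss"][-1] < history["loss"][0]

    def test_determinism(self, tiny_dataset, tiny_embedding, tiny_encoding):
        def run():
            m = assemble_model(ModelConfig.small(), tiny_encoding, 40, seed=1)
            h = train(m, tiny_dataset, tiny_embedding,
                      TrainConfig(batch_size=16, max_epochs=2, patience=2,
                                  val_fraction=0.2, seed=1))
            return h["val_auc"][-1]

        assert run() == pytest.approx(run(), abs=1e-6)

    def test_oversized_batch_auto_reduced(self, tiny_dataset, tiny_embedding,
                                          tiny_encoding):
        ds = tiny_dataset.subset(range(10))
        if len(set(ds.labels)) < 2:  # ensure both classes present
            ds = tiny_dataset.subset(range(14))
        m = assemble_model(ModelConfig.small(), tiny_encoding, 40, seed=2)
        h = train(m, ds, tiny_embedding,
                  TrainConfig(batch_size=1024, max_epochs=1, val_fraction=0.3,
                              seed=2))
        assert len(h["loss"]) == 1

    def test_single_class_rejected(self, tiny_dataset, tiny_embedding,
                                   tiny_encoding):
        seqs = [s for s, y in zip(tiny_dataset.sequences, tiny_dataset.labels)
                if y == 1]
        ds = LabeledDataset(seqs, [1] * len(seqs))
        m = assemble_model(ModelConfig.small(), tiny_encoding, 40, seed=0)
        with pytest.raises(SequenceError):
            train(m, ds, tiny_embedding, TrainConfig(seed=0))


class TestPredict:
    def test_codomain_and_order(self, trained, tiny_dataset, tiny_embedding):
        model, _ = trained
        scores = predict(model, tiny_dataset, tiny_embedding)
        assert scores.shape == (len(tiny_dataset),)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_duplicates_get_equal_scores(self, trained, tiny_dataset,
                                         tiny_embedding):
        model, _ = trained
        s = tiny_dataset.sequences[0]
        ds = LabeledDataset([s, s], [0, 1])
        scores = predict(model, ds, tiny_embedding)
        assert scores[0] == pytest.approx(scores[1], abs=1e-12)

    def test_empty_dataset(self, trained, tiny_embedding):
        model, _ = trained
        assert predict(model, LabeledDataset([], []), tiny_embedding).size == 0


class TestProtocols:
    def test_cross_validate_shape_and_determinism(self, tiny_dataset,
                                                  tiny_encoding):
        tcfg = TrainConfig(batch_size=16, max_epochs=1, val_fraction=0.25, seed=0)
        spec = SplitSpec(n_folds=3, seed=0)
        res1 = cross_validate(tiny_dataset, ModelConfig.small(), tcfg, spec,
                              tiny_encoding, input_length=40)
        assert len(res1.fold_reports) == 3
        assert set(res1.mean) == {"AUC", "ACC", "Sen", "TPR", "FPR", "F1", "MCC"}
        res2 = cross_validate(tiny_dataset, ModelConfig.small(), tcfg, spec,
                              tiny_encoding, input_length=40)
        assert res1.mean["AUC"] == pytest.approx(res2.mean["AUC"], abs=1e-9)

    def test_generalizability_pooling(self):
        def mk(name, n, label):
            seqs = [NucleotideSequence(f"{name}{i}", "ACGTACGTAC")
                    for i in range(n)]
            return LabeledDataset(seqs, [label] * n, name=name)

        dsets = [mk("a", 3, 1), mk("b", 4, 0), mk("c", 5, 1), mk("d", 2, 0)]
        tr, te = generalizability_split(dsets, ["a", "b", "c"], ["d"])
        assert len(tr) == 12 and len(te) == 2

    def test_generalizability_errors(self):
        ds = LabeledDataset([NucleotideSequence("x", "ACGT")], [1], name="a")
        with pytest.raises(ValueError):
            generalizability_split([ds], ["a"], ["a"])
        with pytest.raises(ValueError):
            generalizability_split([ds], ["a"], [])
        with pytest.raises(ValueError):
            generalizability_split([ds], ["a"], ["zzz"])
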