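"""Metrics, AUC, training loop, CV, stability and the two-layer cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from enhancerscan.sequence_io import Dataset, SequenceRecord
from enhancerscan.synthetic_data import SimConfig, generate_dataset
from enhancerscan.training_eval import (
    ConfusionCounts,
    DualScaleAttentionClassifier,
    TrainConfig,
    auc,
    confusion,
    cross_validate,
    evaluate_scores,
    metrics,
    seed_stability,
    two_layer_predict,
)
from conftest import oracle_auc

FAST = dict(n_filters=4, skipgram_epochs=2, epochs=3, batch_size=16,
            validation_fraction=0.0)


class TestConfusion:
    def test_degenerate_all_positive(self):
        c = confusion([1.0] * 5, ["positive"] * 5)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 0, 0)

    def test_threshold_tie_predicts_positive(self):
        c = confusion([0.5], ["negative"])
        assert c.fp == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.random(30)
        labels = rng.choice(["positive", "negative"], 30)
        c1 = confusion(scores, labels)
        perm = rng.permutation(30)
        c2 = confusion(scores[perm], labels[perm])
        assert c1 == c2

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestMetrics:
    def test_layer1_benchmark_confusion(self):
        # 200 positives / 200 negatives with SN 79.5% and SP 85.5%
        rep = metrics(ConfusionCounts(tp=159, fn=41, tn=171, fp=29))
        assert 100 * rep.acc == pytest.approx(82.50)
        assert rep.mcc == pytest.approx(0.651, abs=5e-4)
        assert 100 * rep.sn == pytest.approx(79.50)
        assert 100 * rep.sp == pytest.approx(85.50)

    def test_layer2_benchmark_confusion(self):
        rep = metrics(ConfusionCounts(tp=98, fn=2, tn=85, fp=15))
        assert 100 * rep.acc == pytest.approx(91.50)
        assert rep.mcc == pytest.approx(0.837, abs=5e-4)
        assert 100 * rep.sn == pytest.approx(98.00)
        assert 100 * rep.sp == pytest.approx(85.00)

    def test_single_class_zero_denominator_convention(self):
        rep = metrics(ConfusionCounts(tp=7, fp=0, tn=0, fn=0))
        assert rep.acc == 1.0 and rep.sn == 1.0 and rep.mcc == 0.0

    def test_matches_independent_recomputation(self):
        # 1000 random confusion tables against a scalar re-derivation and
        # against sklearn's MCC
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            if tp + fp + tn + fn == 0:
                continue
            rep = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            total = tp + fp + tn + fn
            assert rep.acc == (tp + tn) / total
            assert rep.sn == (tp / (tp + fn) if tp + fn else 0.0)
            assert rep.sp == (tn / (tn + fp) if tn + fp else 0.0)
            denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            expect_mcc = ((tp * tn) - (fp * fn)) / denom if denom else 0.0
            assert rep.mcc == pytest.approx(expect_mcc)
            assert -1.0 <= rep.mcc <= 1.0
            if denom:
                y_true = [1] * (tp + fn) + [0] * (tn + fp)
                y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
                assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_mcc_one_iff_perfect_with_both_classes(self):
        assert metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)).mcc == 1.0
        assert metrics(ConfusionCounts(tp=5, fp=1, tn=5, fn=0)).mcc < 1.0


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], ["positive", "positive", "negative", "negative"]) == 1.0

    def test_all_tied_is_half(self):
        assert auc([0.5] * 6, ["positive"] * 3 + ["negative"] * 3) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], ["positive", "positive"])

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(min_value=2, max_value=50),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_equals_pair_counting_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        # coarse grid of scores forces plenty of ties
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        labels = rng.choice(["positive", "negative"], size=n).tolist()
        if len(set(labels)) < 2:
            labels[0] = "positive"
            labels[-1] = "negative"
        assert auc(scores, labels) == pytest.approx(oracle_auc(scores, labels), abs=1e-12)


def _separable_dataset(n=40, length=40, seed=0):
    """Linearly separable toy task: positives are GC-rich, negatives AT-rich."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n // 2):
        gc = "".join(rng.choice(list("GC"), length))
        at = "".join(rng.choice(list("AT"), length))
        recs.append(SequenceRecord(f"p{i}", gc, "positive"))
        recs.append(SequenceRecord(f"n{i}", at, "negative"))
    return Dataset(recs)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        ds = _separable_dataset()
        clf = DualScaleAttentionClassifier(
            n_filters=8, skipgram_epochs=3, epochs=8, batch_size=8,
            validation_fraction=0.0, random_state=0)
        clf.fit(ds.sequences, ds.labels)
        losses = clf.history_["train_loss"]
        assert losses[-1] < losses[0]
        assert clf.score(ds.sequences, ds.labels) > 0.9

    def test_identical_seeds_identical_weights(self):
        ds = _separable_dataset(n=20)
        runs = []
        for _ in range(2):
            clf = DualScaleAttentionClassifier(random_state=3, **FAST)
            clf.fit(ds.sequences, ds.labels)
            runs.append(clf)
        a, b = runs
        for pa, pb in zip(a.params_.branches, b.params_.branches):
            assert np.array_equal(pa.weights, pb.weights)
        assert np.array_equal(a.params_.head.weights, b.params_.head.weights)
        assert np.array_equal(a.embedding_table_.vectors, b.embedding_table_.vectors)

    def test_full_batch_is_one_step_per_epoch(self):
        ds = _separable_dataset(n=16)
        clf = DualScaleAttentionClassifier(
            n_filters=4, skipgram_epochs=2, epochs=3, batch_size=len(ds),
            validation_fraction=0.0, random_state=0)
        clf.fit(ds.sequences, ds.labels)
        assert clf.history_["steps"] == 3  # one optimizer step per epoch

    def test_single_class_rejected(self):
        ds = _separable_dataset(n=10)
        pos = [r for r in ds.records if r.label == "positive"]
        clf = DualScaleAttentionClassifier(**FAST)
        with pytest.raises(ValueError):
            clf.fit([r.seq for r in pos], [r.label for r in pos])

    def test_predict_proba_columns_align_with_classes(self):
        ds = _separable_dataset(n=20)
        clf = DualScaleAttentionClassifier(random_state=1, **FAST)
        clf.fit(ds.sequences, ds.labels)
        proba = clf.predict_proba(ds.sequences)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        pos_col = list(clf.classes_).index("positive")
        assert np.allclose(clf.decision_scores(ds.sequences), proba[:, pos_col])


class TestCrossValidate:
    def test_every_record_evaluated_once_and_mean_definition(self):
        sim = generate_dataset(SimConfig(n_per_class=12, length=40, seed=3))
        clf = DualScaleAttentionClassifier(random_state=0, **FAST)
        report = cross_validate(sim.dataset, clf, k=3, seed=1)
        assert len(report.folds) == 3
        assert sum(f.counts.total for f in report.folds) == len(sim.dataset)
        assert report.mean["acc"] == pytest.approx(
            np.mean([f.acc for f in report.folds]))

    def test_duplicate_ids_rejected(self):
        recs = [SequenceRecord("same", "ACGT" * 10, "positive"),
                SequenceRecord("same", "TGCA" * 10, "negative")] * 4
        with pytest.raises(ValueError, match="unique"):
            cross_validate(Dataset(recs), DualScaleAttentionClassifier(**FAST), k=2)


class TestSeedStability:
    def test_identical_seeds_zero_variance(self):
        sim = generate_dataset(SimConfig(n_per_class=10, length=40, seed=5))
        tr = sim.dataset.subset(range(0, len(sim.dataset), 2))
        te = sim.dataset.subset(range(1, len(sim.dataset), 2))
        clf = DualScaleAttentionClassifier(**FAST)
        out = seed_stability(tr, te, clf, seeds=[7, 7, 7])
        assert out["acc_var"] == 0.0
        assert out["mcc_var"] == 0.0
        assert len(out["reports"]) == 3

    def test_requires_two_seeds(self):
        sim = generate_dataset(SimConfig(n_per_class=6, length=40, seed=5))
        with pytest.raises(ValueError):
            seed_stability(sim.dataset, sim.dataset,
                           DualScaleAttentionClassifier(**FAST), seeds=[1])


class TestTwoLayerCascade:
    def test_all_negative_gate_blocks_layer_two(self):
        ds = _separable_dataset(n=16)
        m1 = DualScaleAttentionClassifier(random_state=0, **FAST)
        m1.fit(ds.sequences, ds.labels)
        m2 = DualScaleAttentionClassifier(random_state=1, **FAST)
        m2.fit(ds.sequences, ds.labels)
        # force classifier I to reject everything
        m1.params_.head.weights[:] = 0
        m1.params_.head.bias[:] = np.array([-5.0, 5.0], dtype=np.float32)
        out = two_layer_predict(ds.sequences, m1, m2)
        assert set(out) == {"non-enhancer"}

    def test_layer_isolated_evaluation_matches_metrics(self):
        ds = _separable_dataset(n=20)
        clf = DualScaleAttentionClassifier(random_state=2, **FAST)
        clf.fit(ds.sequences, ds.labels)
        rep = clf.evaluate(ds.sequences, ds.labels)
        direct = evaluate_scores(clf.decision_scores(ds.sequences), ds.labels)
        assert rep.counts == direct.counts
        assert rep.mcc == direct.mcc


class TestProtocolsOnPlantedMotifs:
    """Seeded end-to-end protocol checks at desk scale."""

    def test_cascade_three_class_accuracy(self):
        # benchmark-shaped setup: the layer-1 gate trains on strong + weak
        # enhancers together vs. background; layer 2 on strong vs. weak
        from enhancerscan.sequence_io import (NEGATIVE, POSITIVE,
                                              train_test_split_dataset)

        simC = generate_dataset(SimConfig(n_per_class=100, seed=31),
                                layer="classification")
        simI = generate_dataset(SimConfig(n_per_class=100, seed=32))
        sw_tr, sw_te = train_test_split_dataset(simC.dataset, 0.2, seed=3)
        bg = [r for r in simI.dataset.records if r.label == NEGATIVE]
        bg_tr, bg_te = bg[:160], bg[160:]

        m1 = DualScaleAttentionClassifier(n_filters=32, epochs=30, patience=5,
                                          random_state=1)
        m1.fit(sw_tr.sequences + [r.seq for r in bg_tr],
               [POSITIVE] * len(sw_tr) + [NEGATIVE] * len(bg_tr))
        m2 = DualScaleAttentionClassifier(n_filters=32, epochs=30, patience=5,
                                          random_state=2)
        m2.fit(sw_tr.sequences, sw_tr.labels)

        seqs = sw_te.sequences + [r.seq for r in bg_te]
        truth = (["strong enhancer" if r.label == POSITIVE else "weak enhancer"
                  for r in sw_te.records]
                 + ["non-enhancer"] * len(bg_te))
        pred = two_layer_predict(seqs, m1, m2)
        acc3 = np.mean([p == t for p, t in zip(pred, truth)])
        assert acc3 >= 0.8

    def test_five_seed_variance_is_small_on_strong_signal(self):
        # fully trained runs on strong-signal data vary by well under
        # 2 percentage points squared across seeds
        from enhancerscan.sequence_io import train_test_split_dataset

        sim = generate_dataset(SimConfig(n_per_class=200, seed=41))
        tr, te = train_test_split_dataset(sim.dataset, 0.2, seed=4)
        clf = DualScaleAttentionClassifier(n_filters=32)
        out = seed_stability(tr, te, clf, seeds=[101, 202, 303, 404, 505])
        assert out["acc_var"] * 1e4 < 2.0  # pp^2
        assert out["acc_mean"] > 0.85


def test_save_load_round_trip(tmp_path):
    ds = _separable_dataset(n=16)
    clf = DualScaleAttentionClassifier(random_state=4, **FAST)
    clf.fit(ds.sequences, ds.labels)
    clf.save(tmp_path / "model")
    loaded = DualScaleAttentionClassifier.load(tmp_path / "model")
    np.testing.assert_allclose(
        loaded.decision_scores(ds.sequences), clf.decision_scores(ds.sequences),
        rtol=1e-6)
    assert list(loaded.classes_) == list(clf.classes_)
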