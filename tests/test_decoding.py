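"""SVM population decoding: datasets, CV, controls, transfer, weights."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

import fearcal as fc
from fearcal import decoding as dec
from fearcal import synth
from fearcal.protocol import CS_MINUS, CS_PLUS


@pytest.fixture(scope="module")
def decoder_population(protocols):
    """58 cells with distinct CS+/CS- conditioning responses."""
    cfg = synth.SynthConfig(cells_per_animal=58, seed=19)
    cfg.us_proportions = {"null": 1.0}
    cfg.xday_proportions = {"stable_activated": 0.3, "stable_inhibited": 0.2, "null": 0.5}
    pop, _ = synth.generate_population(
        cfg, {d: protocols[d] for d in ("conditioning", "test_ext1", "ext2")}, seed=19)
    return pop


class TestBuildDataset:
    def test_balanced_cardinality(self, decoder_population, protocols):
        ds = dec.build_dataset(decoder_population, protocols["test_ext1"],
                               n_cells=37, seed=0)
        # 4 usable blocks per class (CS- count limits), 30 one-second bins each
        assert ds.X.shape == (3 * 4 * 30, 37)
        counts = {c: (ds.y == c).sum() for c in ds.classes}
        assert set(counts.values()) == {120}

    def test_subsample_size_and_determinism(self, decoder_population, protocols):
        a = dec.build_dataset(decoder_population, protocols["conditioning"], seed=3)
        b = dec.build_dataset(decoder_population, protocols["conditioning"], seed=3)
        assert a.X.shape[1] == 37
        assert np.array_equal(a.cell_indices, b.cell_indices)
        assert np.array_equal(a.X, b.X)

    def test_insufficient_cells_names_animal(self, protocols, rng):
        pop = fc.preprocess_traces(
            {"conditioning": rng.normal(size=(5, int(protocols["conditioning"].duration_s * 20)))},
            animal_id="tiny")
        pop.sessions["conditioning"] = pop.sessions.pop("session") \
            if "session" in pop.sessions else pop.sessions["conditioning"]
        with pytest.raises(ValueError, match="tiny"):
            dec.build_dataset(pop, protocols["conditioning"], n_cells=37)


class TestCrossval:
    def test_separable_classes_decode_perfectly(self):
        ds = synth.separable_decoder_dataset(seed=0)
        res = dec.crossval_multiclass(ds, folds=10, seed=0)
        assert res.accuracy >= 0.99

    def test_shuffled_labels_at_chance(self):
        ds = synth.separable_decoder_dataset(seed=1)
        accs = dec.shuffled_label_control(ds, n_shuffles=20, folds=10, seed=0)
        assert abs(accs.mean() - 1 / 3) < 0.05

    def test_real_labels_beat_shuffled_distribution(self):
        ds = synth.separable_decoder_dataset(seed=2)
        real = dec.crossval_multiclass(ds, folds=10, seed=0).accuracy
        accs = dec.shuffled_label_control(ds, n_shuffles=20, folds=10, seed=0)
        assert real > np.quantile(accs, 0.95)

    def test_single_class_rejected(self):
        ds = synth.separable_decoder_dataset(seed=0)
        only = ds.restrict((dec.BASELINE,))
        with pytest.raises(ValueError, match="class"):
            dec.crossval_multiclass(only)


class TestMetricIdentities:
    def test_formulas_on_frozen_confusion(self):
        import pandas as pd
        cm = pd.DataFrame([[10, 0], [0, 10]], index=["a", "b"], columns=["a", "b"])
        res = dec.DecoderResult.from_confusion(cm)
        assert res.accuracy == 1.0
        assert res.f1 == {"a": 1.0, "b": 1.0}

    def test_identities_against_sklearn(self):
        """accuracy/precision/recall/F1 agree with an independent routine."""
        ds = synth.separable_decoder_dataset(noise_sd=1.5, seed=4)
        res = dec.crossval_multiclass(ds, folds=5, seed=0)
        cm = res.confusion.to_numpy()
        # rebuild a label sequence realizing the confusion matrix
        y_true, y_pred = [], []
        for i, c in enumerate(res.confusion.index):
            for j, c2 in enumerate(res.confusion.columns):
                y_true += [c] * cm[i, j]
                y_pred += [c2] * cm[i, j]
        classes = list(res.confusion.index)
        assert res.accuracy == pytest.approx(accuracy_score(y_true, y_pred), abs=1e-12)
        for avg_fn, ours in ((precision_score, res.precision), (recall_score, res.recall),
                             (f1_score, res.f1)):
            ref = avg_fn(y_true, y_pred, labels=classes, average=None, zero_division=0)
            for c, r in zip(classes, ref):
                assert ours[c] == pytest.approx(r, abs=1e-12)

    def test_balanced_permutation_accuracy_converges(self):
        """Any label permutation of balanced classes decodes at ~1/#classes."""
        rng = np.random.default_rng(8)
        ds = synth.separable_decoder_dataset(seed=5)
        perm = rng.permutation(len(ds.y))
        shuffled = dec.DecoderDataset(ds.X, ds.y[perm], ds.animal_id, ds.day_kind,
                                      ds.cell_indices, ds.bin_width)
        res = dec.crossval_multiclass(shuffled, folds=10, seed=0)
        assert abs(res.accuracy - 1 / 3) < 0.05


class TestSubsetControls:
    @staticmethod
    def flags_classification(flags, stim):
        n = len(flags)
        p = np.where(np.asarray(flags)[:, None], 1e-4, 0.9) * np.ones((n, 5))
        return fc.classify_cells(p, np.ones((n, 5), int), stimulus=stim)

    def test_subset_selection(self):
        resp_plus = [True] * 10 + [False] * 20
        cls = {CS_PLUS: self.flags_classification(resp_plus, CS_PLUS),
               CS_MINUS: self.flags_classification([False] * 30, CS_MINUS)}
        assert np.array_equal(dec.select_cells(cls, "responsive_only", 30), np.arange(10))
        non = dec.select_cells(cls, "nonresponsive_only", 30)
        assert np.array_equal(non, np.arange(10, 30))
        matched = dec.select_cells(cls, "random_size_matched", 30, n_match=len(non), seed=0)
        assert len(matched) == len(non)

    def test_signal_carried_by_responsive_cells(self, rng):
        """Signal-free cells decode at chance; informative cells decode."""
        n_cells, n_per = 20, 120
        pattern = np.zeros(n_cells)
        pattern[:10] = rng.normal(0, 2, 10)       # only the first 10 cells code
        X = np.concatenate([np.zeros((n_per, n_cells)), pattern + np.zeros((n_per, n_cells))])
        X += rng.normal(0, 0.5, X.shape)
        y = np.repeat([dec.BASELINE, CS_PLUS], n_per)
        base = dec.DecoderDataset(X, y, "a", "conditioning", np.arange(n_cells), 1.0)
        informative = dec.DecoderDataset(X[:, :10], y, "a", "conditioning", np.arange(10), 1.0)
        noise_only = dec.DecoderDataset(X[:, 10:], y, "a", "conditioning", np.arange(10), 1.0)
        acc_all = dec.crossval_multiclass(base, 10, 0).accuracy
        acc_resp = dec.crossval_multiclass(informative, 10, 0).accuracy
        acc_non = dec.crossval_multiclass(noise_only, 10, 0).accuracy
        assert acc_resp >= acc_all - 0.02
        assert abs(acc_non - 0.5) < 0.1

    def test_empty_subset_rejected(self):
        cls = {CS_PLUS: self.flags_classification([True] * 5, CS_PLUS)}
        with pytest.raises(ValueError, match="fewer than 2"):
            dec.select_cells(cls, "nonresponsive_only", 5)


class TestTwoWayAndTransfer:
    def test_uninformative_feature_gets_small_weight(self, rng):
        n_per = 100
        X = np.zeros((2 * n_per, 3))
        X[n_per:, 0] = 2.0                       # only feature 0 discriminates
        X[:, 1] = 0.0                            # zero variance
        X[:, 2] = rng.normal(0, 1, 2 * n_per)    # noise
        y = np.repeat([dec.BASELINE, CS_PLUS], n_per)
        model = dec.train_twoway(dec.DecoderDataset(X, y, "a", "d", np.arange(3), 1.0))
        assert model.abs_weights[1] < 1e-6
        assert model.abs_weights.argmax() == 0

    def test_three_classes_rejected(self):
        ds = synth.separable_decoder_dataset(seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            dec.train_twoway(ds)

    def test_same_day_transfer_equals_training_accuracy(self):
        ds = synth.separable_decoder_dataset(seed=6).restrict((dec.BASELINE, CS_PLUS))
        model = dec.train_twoway(ds)
        res = dec.cross_day_evaluate(model, ds)
        train_acc = accuracy_score(ds.y, model.clf.predict(ds.X))
        assert res.accuracy == pytest.approx(train_acc)

    def test_feature_mismatch_rejected(self):
        ds = synth.separable_decoder_dataset(seed=0).restrict((dec.BASELINE, CS_PLUS))
        model = dec.train_twoway(ds)
        other = dec.DecoderDataset(ds.X[:, :10], ds.y, "a", "d", np.arange(10), 1.0)
        with pytest.raises(ValueError, match="subsample"):
            dec.cross_day_evaluate(model, other)

    def test_cross_day_dissociation(self, protocols):
        """Stable codes transfer across days; remapped codes drop to chance."""
        days = {d: protocols[d] for d in ("test_ext1", "ext2")}

        def accs(xday, seed):
            cfg = synth.SynthConfig(cells_per_animal=58, seed=seed)
            cfg.us_proportions = {"null": 1.0}
            cfg.cs_plus_proportions = {"null": 1.0}
            cfg.cs_minus_proportions = {"null": 1.0}
            cfg.xday_proportions = xday
            pop, _ = synth.generate_population(cfg, days, seed=seed)
            cells = np.sort(np.random.default_rng(seed).choice(58, 37, replace=False))
            ds_a = dec.build_dataset(pop, protocols["test_ext1"],
                                     (dec.BASELINE, CS_PLUS), cells=cells)
            ds_b = dec.build_dataset(pop, protocols["ext2"],
                                     (dec.BASELINE, CS_PLUS), cells=cells)
            model = dec.train_twoway(ds_a)
            intra = dec.crossval_multiclass(ds_a, 10, seed)
            return intra.accuracy, dec.cross_day_evaluate(model, ds_b)

        intra_s, cross_s = accs({"stable_activated": 0.4, "stable_inhibited": 0.2,
                                 "null": 0.4}, 7)
        assert abs(intra_s - cross_s.accuracy) <= 0.05

        intra_r, cross_r = accs({"remapped": 0.6, "null": 0.4}, 8)
        assert intra_r >= 0.95
        assert abs(cross_r.accuracy - 0.5) <= 0.05
        # CS-only remapping: the baseline class keeps its meaning
        assert cross_r.f1["BASELINE"] > cross_r.f1[CS_PLUS]
        assert cross_r.recall["BASELINE"] > cross_r.recall[CS_PLUS]


class TestWeightSelectivity:
    def test_identical_weights_correlate_perfectly(self, rng):
        w = rng.normal(size=30)
        assert fc.weight_selectivity(w, w) == pytest.approx(1.0)

    def test_disjoint_coding_cells_anticorrelate(self):
        wplus = np.array([3.0, 2.5, 2.8, 0.1, 0.2, 0.1])
        wminus = np.array([0.1, 0.2, 0.1, 3.0, 2.5, 2.8])
        assert fc.weight_selectivity(wplus, wminus) < -0.5

    def test_independent_weights_near_zero(self, rng):
        rs = [fc.weight_selectivity(rng.normal(size=200), rng.normal(size=200))
              for _ in range(50)]
        assert abs(np.mean(rs)) < 0.05

    def test_constant_vector_flagged(self):
        assert np.isnan(fc.weight_selectivity(np.ones(5), np.arange(5.0)))

    def test_stability_control_on_consistent_data(self):
        ds = synth.separable_decoder_dataset(seed=9).restrict((dec.BASELINE, CS_PLUS))
        rs = dec.weight_stability_control(ds, n_pairs=5, seed=0)
        assert (rs > 0.8).all()
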