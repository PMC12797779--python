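"""Dosage encoding, SVM tuning, F1 scoring and label-noise injection."""

import numpy as np
import pandas as pd
import pytest

from popkit import bga
from popkit.bga import (
    DosageEncoder,
    SvmConfig,
    inject_label_noise,
    stratified_split,
    tune_and_train,
    weighted_f1,
)
from popkit.io import MISSING, GenotypeTable, LocusInfo


def _table(genos, pops=None):
    genos = np.array(genos, dtype=np.int8)
    n = genos.shape[0]
    pops = pops or ["P"] * n
    return GenotypeTable(
        [f"S{i}" for i in range(n)], pops,
        [{"P": "X"}.get(p, p[0]) for p in pops],
        [LocusInfo(f"rs{j}") for j in range(genos.shape[1])], genos,
    )


class TestDosageEncoder:
    def test_dosage_codes(self):
        t = _table([[[1, 1], [1, 0], [0, 0]]])
        X = DosageEncoder().fit(t).transform(t)
        assert X.iloc[0].tolist() == [2, 1, 0]

    def test_all_missing_training_locus_dropped(self):
        t = _table([[[1, 0], [MISSING, MISSING]], [[1, 1], [MISSING, MISSING]]])
        with pytest.warns(UserWarning, match="all-missing"):
            enc = DosageEncoder().fit(t)
        assert enc.loci_ == ["rs0"]

    def test_imputation_uses_train_means_only(self):
        train = _table([[[1, 1]], [[0, 0]]])          # mean dosage 1.0
        test_a = _table([[[MISSING, MISSING]]])
        test_b = _table([[[MISSING, MISSING]], [[1, 1]]])  # extra sample
        enc = DosageEncoder().fit(train)
        va = enc.transform(test_a).iloc[0, 0]
        vb = enc.transform(test_b).iloc[0, 0]
        assert va == vb == 1.0  # unaffected by test-set content

    def test_missing_locus_in_test_is_schema_error(self):
        train = _table([[[1, 0], [0, 0]], [[1, 1], [1, 0]]])
        test = _table([[[1, 0]]])
        enc = DosageEncoder().fit(train)
        with pytest.raises(ValueError, match="absent"):
            enc.transform(test)


class TestWeightedF1:
    def test_perfect_predictions(self):
        per, w = weighted_f1(["A", "B", "A"], ["A", "B", "A"])
        assert w == 1.0 and all(v == 1.0 for v in per.values())

    def test_confusion_matrix_hand_computation(self):
        per, w = weighted_f1(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        assert per["A"] == pytest.approx(2 / 3)
        assert per["B"] == pytest.approx(0.8)
        assert w == pytest.approx(0.73333, abs=1e-5)

    def test_invariant_to_label_renaming(self):
        yt = ["A", "A", "B", "C", "C", "B"]
        yp = ["A", "B", "B", "C", "A", "B"]
        ren = {"A": "Z", "B": "Q", "C": "R"}
        _, w1 = weighted_f1(yt, yp)
        _, w2 = weighted_f1([ren[x] for x in yt], [ren[x] for x in yp])
        assert w1 == pytest.approx(w2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_f1([], [])


class TestInjectLabelNoise:
    def test_zero_fraction_unchanged(self):
        y = ["A", "B", "C"]
        noisy, realized = inject_label_noise(y, 0.0, seed=0)
        assert noisy.tolist() == y and realized == 0.0

    def test_full_shuffle_preserves_multiset(self):
        y = ["A"] * 10 + ["B"] * 5 + ["C"] * 3
        noisy, _ = inject_label_noise(y, 1.0, seed=1)
        assert sorted(noisy.tolist()) == sorted(y)

    def test_input_labels_not_mutated(self):
        y = np.array(["A", "B", "A", "B"])
        inject_label_noise(y, 1.0, seed=2)
        assert y.tolist() == ["A", "B", "A", "B"]

    def test_realized_mismatch_matches_coincidence_expectation(self):
        """Shuffling k of N labels changes ~ fraction*(1 - sum c_i^2)."""
        rng = np.random.default_rng(3)
        y = rng.choice(["A", "B", "C", "D", "E"], size=500)
        props = pd.Series(y).value_counts(normalize=True)
        expected = 0.5 * (1 - (props**2).sum())
        realized = np.mean([
            inject_label_noise(y, 0.5, seed=s)[1] for s in range(200)
        ])
        assert realized == pytest.approx(expected, abs=0.02)

    def test_uniform_mechanism(self):
        y = ["A"] * 50 + ["B"] * 50
        noisy, realized = inject_label_noise(y, 0.5, seed=4, mechanism="uniform")
        assert 0.0 < realized <= 0.5

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            inject_label_noise(["A"], 1.5)


class TestTuneAndTrain:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 0.3, (20, 4)), rng.normal(3, 0.3, (20, 4))])
        y = np.array(["A"] * 20 + ["B"] * 20)
        return X, y

    def test_separable_blobs_perfect_training_f1(self):
        X, y = self._blobs()
        model, info = tune_and_train(X, y, SvmConfig(budget=8, seed=0))
        _, w = weighted_f1(y, model.predict(X))
        assert w == 1.0

    def test_deterministic_given_seed(self):
        X, y = self._blobs()
        _, a = tune_and_train(X, y, SvmConfig(budget=6, seed=3))
        _, b = tune_and_train(X, y, SvmConfig(budget=6, seed=3))
        assert a == b

    def test_class_smaller_than_folds_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        y = np.array(["A"] * 8 + ["B"] * 2)
        with pytest.raises(ValueError, match="stratified"):
            tune_and_train(X, y, SvmConfig(budget=2, seed=0, cv_folds=4))


class TestPanelClassification:
    def test_held_out_f1_on_strong_signal_panel(self, panel_table):
        """Five well-differentiated clusters: held-out weighted F1 > 0.95."""
        is_t = np.isin(panel_table.population, ["TGA", "TGB", "TGC"])
        ref = panel_table.subset_samples(np.flatnonzero(~is_t))
        ext = panel_table.subset_samples(np.flatnonzero(is_t))
        train, test = stratified_split(ref, seed=0)
        enc = DosageEncoder().fit(train)
        model, _ = tune_and_train(
            enc.transform(train), train.superpopulation,
            SvmConfig(budget=10, seed=0))
        _, w = weighted_f1(test.superpopulation,
                           model.predict(enc.transform(test).to_numpy()))
        assert w > 0.95
        # nested target groups classify into their parent continental group
        _, w_ext = weighted_f1(ext.superpopulation,
                               model.predict(enc.transform(ext).to_numpy()))
        assert w_ext > 0.95

    def test_split_is_stratified_and_disjoint(self, panel_table):
        train, test = stratified_split(panel_table, seed=1)
        assert not set(train.sample_ids) & set(test.sample_ids)
        assert len(test.sample_ids) == round(0.2 * panel_table.n_samples)
        tr = pd.Series(train.superpopulation).value_counts(normalize=True)
        te = pd.Series(test.superpopulation).value_counts(normalize=True)
        assert ((tr - te).abs() < 0.05).all()


class TestNoiseExperiment:
    def test_records_and_degradation(self, panel_table):
        is_t = np.isin(panel_table.population, ["TGA", "TGB", "TGC"])
        ref = panel_table.subset_samples(np.flatnonzero(~is_t))
        train, test = stratified_split(ref, seed=0)
        enc = DosageEncoder().fit(train)
        Xtr, Xte = enc.transform(train), enc.transform(test)
        res = bga.noise_experiment(
            Xtr, train.superpopulation, Xte, test.superpopulation,
            fractions=(0.01, 0.8), repetitions=2, seed=5,
            config=SvmConfig(budget=5, seed=0),
        )
        assert len(res.records) == 4
        assert res.records["realized_mismatch"].notna().all()
        s = res.summary().set_index("noise_fraction")["test_weighted_f1"]
        assert s[0.8] < s[0.01]  # heavy label noise degrades performance

    def test_identical_seed_reproduces(self, panel_table):
        train, test = stratified_split(panel_table, seed=0)
        enc = DosageEncoder().fit(train)
        Xtr, Xte = enc.transform(train), enc.transform(test)
        kw = dict(fractions=(0.2,), repetitions=1, seed=9,
                  config=SvmConfig(budget=3, seed=0))
        r1 = bga.noise_experiment(Xtr, train.superpopulation, Xte,
                                  test.superpopulation, **kw)
        r2 = bga.noise_experiment(Xtr, train.superpopulation, Xte,
                                  test.superpopulation, **kw)
        pd.testing.assert_frame_equal(r1.records, r2.records)
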