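"""Recurrent classifier, feature ensemble and evaluation protocols.

The GRU implementation is validated by a numerical gradient check; the
learning behaviour by separable-construction and label-shuffle oracles.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from tailkin import sequence_classifier as sc
from tailkin import synthetic_data as sd
from tailkin import tracking_io as tio

from conftest import frames_from_theta


def _wag_samples(n_per_class, bias_target=30.0, bias_non=-30.0, seed=0,
                 n_dogs=2, amp=10.0, noise_sd=0.0):
    """Synthetic samples whose classes differ only by wag bias."""
    design = sd.StudyDesign(seed=seed)
    samples = []
    for i, (label, bias) in enumerate(itertools.product((1, 0), (None,))):
        b = bias_target if label else bias_non
        for j in range(n_per_class):
            prof = sd.DogProfile(f"dog{j % n_dogs}", sd.WagParams(bias=b, amp_right=amp, amp_left=amp,
                                                                  freq=3.0, noise_sd=noise_sd), sd.WagShift())
            frames = sd.simulate_segment(prof, "area1", 2.0, design, sd.NoiseModel.zero(),
                                         [seed, label, j])
            seg = tio.TrajectorySegment(
                frames=frames, dog_id=prof.dog_id, area="area1",
                label="target" if label else "non_target",
                sub_label="target" if label else "distractor")
            samples.extend(sc.build_sequence_samples([seg]))
    return samples


class TestBuildSamples:
    def test_straight_tail_normalised_coordinates(self):
        frames = frames_from_theta(np.zeros(10), body_scale=100.0, tail_scale=60.0)
        seg = tio.TrajectorySegment(frames=frames, label="target", sub_label="target")
        (s,) = sc.build_sequence_samples([seg], target_fps=None)
        # body frame: tail base at origin, middle straight behind at
        # 0.5 * tail_scale / body_scale along +y
        assert np.allclose(s.series[:, 0:2], 0.0, atol=1e-12)
        assert np.allclose(s.series[:, 2], 0.0, atol=1e-9)           # mid x
        assert np.allclose(s.series[:, 3], 0.3, atol=1e-9)           # mid y
        assert np.allclose(s.series[:, 5], 0.6, atol=1e-9)           # tip y
        assert np.allclose(s.series[:, 6], 1.0)

    def test_uniform_scale_invariance(self, rng):
        frames = frames_from_theta(rng.uniform(-40, 40, 50))
        seg = tio.TrajectorySegment(frames=frames, label="target", sub_label="target")
        scaled = frames.copy()
        for c in scaled.columns:
            if c not in ("t", "conf"):
                scaled[c] = scaled[c] * 2.0
        seg2 = tio.TrajectorySegment(frames=scaled, label="target", sub_label="target")
        (a,) = sc.build_sequence_samples([seg], target_fps=None)
        (b,) = sc.build_sequence_samples([seg2], target_fps=None)
        assert np.allclose(a.series, b.series, atol=1e-9)

    def test_fully_degenerate_segment_rejected(self):
        frames = frames_from_theta(np.zeros(10))
        for c in frames.columns:
            if c.startswith(("shoulders", "tail_base")):
                frames[c] = 100.0  # S == B: no body frame anywhere
        seg = tio.TrajectorySegment(frames=frames, label="target", sub_label="target")
        with pytest.raises(ValueError, match="degenerate"):
            sc.build_sequence_samples([seg], target_fps=None)


class TestGRUGradients:
    @pytest.mark.parametrize("readout", ["mean", "last"])
    def test_backprop_matches_numerical_gradients(self, readout):
        cfg = sc.RecurrentModelConfig(gru_dims=(5, 4), fc_dims=(4, 3), dropout=0.0,
                                      readout=readout, seed=3)
        model = sc.GRUClassifier(cfg)
        rng = np.random.default_rng(0)
        samples = [sc.SequenceSample(rng.normal(size=(T, 7)), lab, "d")
                   for T, lab in [(6, 1), (4, 0), (7, 1)]]
        y = np.array([s.label for s in samples], float)
        w = np.ones(3)
        X, mask = sc._pad_batch(samples)

        def loss():
            p, _ = model._forward(X, mask, train=False)
            return sc._bce_loss_grad(p, y, w)[0]

        p, fc = model._forward(X, mask, train=False)
        _, dlogit = sc._bce_loss_grad(p, y, w)
        grads = model._backward(dlogit, fc)
        params = model.parameters()
        eps = 1e-5
        for k, v in params.items():
            for idx in itertools.islice(np.ndindex(v.shape), 3):
                orig = v[idx]
                v[idx] = orig + eps
                lp = loss()
                v[idx] = orig - eps
                lm = loss()
                v[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[k][idx]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), k


class TestTrainRecurrent:
    # batch 8 on 40 clips gives the optimiser 5 steps per epoch; within
    # 30 epochs a trivially separable construction must be fit perfectly
    CFG = sc.RecurrentModelConfig(epochs=30, batch_size=8, val_fraction=0.0, seed=0)

    def test_separable_construction_reaches_perfect_training_accuracy(self):
        samples = _wag_samples(20)
        model = sc.train_recurrent(samples, self.CFG)
        acc, _ = sc.accuracy_f1(model.predict(samples), [s.label for s in samples])
        assert acc == 1.0

    def test_single_class_rejected(self):
        samples = _wag_samples(5)
        pos = [s for s in samples if s.label == 1]
        with pytest.raises(ValueError, match="both classes"):
            sc.train_recurrent(pos, self.CFG)

    def test_same_seed_identical_model(self):
        samples = _wag_samples(6)
        cfg = sc.RecurrentModelConfig(epochs=5, val_fraction=0.0, seed=4)
        m1 = sc.train_recurrent(samples, cfg)
        m2 = sc.train_recurrent(samples, cfg)
        assert m1.history == m2.history
        assert np.array_equal(m1.predict_proba(samples), m2.predict_proba(samples))

    def test_random_labels_stay_near_chance(self):
        """Labels drawn independently of the data: held-out accuracy stays
        in the chance band.  (Independent coin-flip labels, not a
        permutation of a fixed vector — permuting makes the train/test
        label-feature associations negatively dependent.)"""
        samples = _wag_samples(12, noise_sd=3.0)
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(8):
            labels = rng.integers(0, 2, size=len(samples))
            nulled = [sc.SequenceSample(s.series, int(l), s.dog_id)
                      for s, l in zip(samples, labels)]
            tr, te = nulled[::2], nulled[1::2]
            if len({s.label for s in tr}) < 2:
                continue
            cfg = sc.RecurrentModelConfig(epochs=15, val_fraction=0.0, seed=seed)
            model = sc.train_recurrent(tr, cfg)
            acc, _ = sc.accuracy_f1(model.predict(te), [s.label for s in te])
            accs.append(acc)
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_class_weights_inverse_frequency(self):
        # w_c = n / (2 n_c): the per-sample mean weight is exactly 1, so
        # imbalance rebalances the loss without rescaling it
        w = sc.class_weights(np.array([0, 0, 0, 1]))
        assert w[0] == pytest.approx(4 / 6)
        assert w[1] == pytest.approx(2.0)
        assert np.mean([w[0]] * 3 + [w[1]]) == pytest.approx(1.0)


class TestAccuracyF1:
    def test_all_correct(self):
        assert sc.accuracy_f1([1, 0, 1], [1, 0, 1]) == (1.0, 1.0)

    def test_degenerate_all_non_target(self):
        acc, f1 = sc.accuracy_f1([0, 0, 0, 0], [1, 1, 0, 0])
        assert acc == 0.5 and f1 == 0.0

    def test_matches_confusion_matrix_oracle(self, rng):
        from sklearn.metrics import accuracy_score, f1_score
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            acc, f1 = sc.accuracy_f1(p, y)
            assert acc == pytest.approx(accuracy_score(y, p))
            assert f1 == pytest.approx(f1_score(y, p, zero_division=0))

    def test_string_labels_accepted(self):
        acc, f1 = sc.accuracy_f1(["target", "non_target"], ["target", "target"])
        assert acc == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sc.accuracy_f1([1], [1, 0])


class TestKFold:
    def test_partition_property(self):
        samples = _wag_samples(15)
        cfg = sc.RecurrentModelConfig(epochs=1, val_fraction=0.0, seed=0)
        rep = sc.kfold_eval(samples, k=5, config=cfg)
        assert rep.protocol == "kfold5"
        assert sum(m["n_test"] for m in rep.fold_metrics) == len(samples)

    def test_separable_high_accuracy(self):
        # 24 training samples/fold is a single batch per epoch, so the
        # optimiser needs a couple of hundred steps to converge
        samples = _wag_samples(15)
        cfg = sc.RecurrentModelConfig(epochs=120, batch_size=16, val_fraction=0.0, seed=0)
        rep = sc.kfold_eval(samples, k=5, config=cfg)
        assert rep.accuracy >= 0.95

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            sc.kfold_eval(_wag_samples(5), k=1)


class TestLODO:
    def test_two_dogs_two_disjoint_folds(self):
        samples = _wag_samples(10, n_dogs=2)
        cfg = sc.RecurrentModelConfig(epochs=2, val_fraction=0.0, seed=0)
        rep = sc.leave_one_dog_out_eval(samples, cfg)
        assert rep.protocol == "leave_one_dog_out"
        assert len(rep.fold_metrics) == 2
        assert set(rep.per_dog) == {"dog0", "dog1"}

    def test_opposite_dog_effects_block_generalisation(self):
        """Dog-specific effects with opposite signs: LODO cannot beat chance."""
        design = sd.StudyDesign(seed=0)
        samples = []
        for d in range(4):
            sign = 1.0 if d % 2 == 0 else -1.0
            for label in (0, 1):
                for j in range(8):
                    bias = sign * (25.0 if label else -25.0)
                    prof = sd.DogProfile(f"dog{d}", sd.WagParams(bias=bias, amp_right=8, amp_left=8,
                                                                 noise_sd=2.0), sd.WagShift())
                    frames = sd.simulate_segment(prof, "area1", 2.0, design,
                                                 sd.NoiseModel.zero(), [d, label, j])
                    seg = tio.TrajectorySegment(frames=frames, dog_id=prof.dog_id, area="area1",
                                                label="target" if label else "non_target",
                                                sub_label="target" if label else "distractor")
                    samples.extend(sc.build_sequence_samples([seg]))
        cfg = sc.RecurrentModelConfig(epochs=20, val_fraction=0.0, seed=0)
        rep = sc.leave_one_dog_out_eval(samples, cfg)
        assert rep.accuracy <= 0.65


class TestFeatureEnsemble:
    def _table(self, rng, n=40, sep=6.0):
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6))
        X[y == 1, 1] += sep   # amp_positive column shifted for targets
        df = pd.DataFrame(X, columns=sc.FEATURE_COLUMNS)
        df["label"] = np.where(y == 1, "target", "non_target")
        return df

    def test_equal_weight_tie_resolves_to_non_target(self):
        cfg = sc.EnsembleConfig(weights=(1.0, 1.0), seed=0)
        ens = sc.FeatureEnsemble(cfg)
        ens.weights = np.array([1.0, 1.0])
        ens._member_votes = lambda X: np.array([[1], [0]])  # members disagree
        assert ens.predict(np.zeros((1, 6)))[0] == 0

    def test_dominant_weight_wins(self):
        cfg = sc.EnsembleConfig(weights=(2.0, 1.0), seed=0)
        ens = sc.FeatureEnsemble(cfg)
        ens.weights = np.array([2.0, 1.0])
        ens._member_votes = lambda X: np.array([[1], [0]])
        assert ens.predict(np.zeros((1, 6)))[0] == 1

    def test_separable_fixture_perfect_training_accuracy(self, rng):
        df = self._table(rng, sep=10.0)
        model = sc.train_feature_ensemble(df, sc.EnsembleConfig(seed=0))
        X, y = sc.features_matrix(df)
        acc, _ = sc.accuracy_f1(model.predict(X), y)
        assert acc == 1.0

    def test_single_class_rejected(self, rng):
        df = self._table(rng)
        with pytest.raises(ValueError, match="both classes"):
            sc.train_feature_ensemble(df[df["label"] == "target"])

    def test_probabilities_within_unit_interval(self, rng):
        df = self._table(rng)
        model = sc.train_feature_ensemble(df, sc.EnsembleConfig(seed=0))
        p = model.predict_proba(sc.features_matrix(df)[0])
        assert ((p >= 0) & (p <= 1)).all()


class TestThresholdGeneralization:
    def _dilution_table(self, rng, dil, n=30, sep=3.0):
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6))
        X[y == 1, 2] += sep
        df = pd.DataFrame(X, columns=sc.FEATURE_COLUMNS)
        df["label"] = np.where(y == 1, "target", "non_target")
        df["dilution_exponent"] = dil
        return df

    def test_overlapping_dilutions_rejected(self, rng):
        tr = self._dilution_table(rng, -3)
        te = pd.concat([self._dilution_table(rng, -3), self._dilution_table(rng, -4)])
        with pytest.raises(ValueError, match="overlap"):
            sc.threshold_generalization_eval(tr, te)

    def test_per_dilution_reports(self, rng):
        tr = self._dilution_table(rng, -3, n=60)
        te = pd.concat([self._dilution_table(rng, d) for d in (-4, -5, -6)])
        rep = sc.threshold_generalization_eval(tr, te, sc.EnsembleConfig(seed=0))
        assert set(rep.per_dilution) == {-4, -5, -6}
        assert all(0.0 <= v["accuracy"] <= 1.0 for v in rep.per_dilution.values())

    def test_empty_dilution_flagged_and_omitted(self, rng):
        tr = self._dilution_table(rng, -3, n=60)
        te = self._dilution_table(rng, -4)
        te = pd.concat([te, te.iloc[0:0].assign(dilution_exponent=-5)])
        rep = sc.threshold_generalization_eval(tr, te, sc.EnsembleConfig(seed=0))
        assert set(rep.per_dilution) == {-4}
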