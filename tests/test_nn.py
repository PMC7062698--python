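import numpy as np
import pytest

import simondecode as sd
from simondecode.core import EpochSet
from simondecode.nn.eegnet import _weighted_ce


def table_parameter_count(F1, D, C, T, N, k1=64, k2=16):
    """Per-layer parameter formulas of the architecture table."""
    F2 = F1 * D
    t4 = T // 4
    t32 = t4 // 8
    return (
        F1 * k1            # temporal convolution
        + 2 * F1           # batch norm 1
        + C * D * F1       # depthwise spatial convolution
        + 2 * D * F1       # batch norm 2
        + k2 * D * F1      # separable: depthwise temporal
        + F2 * (D * F1)    # separable: pointwise
        + 2 * F2           # batch norm 3
        + F2 * t32 * N + N # dense softmax
    )


class TestArchitecture:
    def test_block_shapes_for_paper_geometry(self):
        net = sd.build_model(sd.NetConfig(F1=8, D=2), C=60, T=750)
        assert net.cfg.F2 == 16
        assert net.T4 == 187      # block-1 output length (floor 750/4)
        assert net.T32 == 23
        assert net.n_flat == 368  # flattened features entering the dense layer

    @pytest.mark.parametrize("f1,d,c,t", [(8, 2, 60, 750), (4, 2, 60, 750),
                                          (8, 2, 16, 375)])
    def test_parameter_count_matches_layer_formulas(self, f1, d, c, t):
        net = sd.build_model(sd.NetConfig(F1=f1, D=d), C=c, T=t)
        assert net.n_parameters == table_parameter_count(f1, d, c, t, 4)

    def test_too_short_input_errors(self):
        with pytest.raises(ValueError, match="temporal kernel"):
            sd.build_model(sd.NetConfig(), C=8, T=32)


class TestClassWeights:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((100, 100, 100, 50), (1, 1, 1, 2)),
            ((100, 100, 100, 100), (1, 1, 1, 1)),
            ((200, 100, 100, 100), (1, 2, 2, 2)),
        ],
    )
    def test_inverse_proportion_weights(self, counts, expected):
        assert np.allclose(sd.class_weights(np.array(counts)), expected)

    def test_zero_count_errors(self):
        with pytest.raises(ValueError, match="class"):
            sd.class_weights(np.array([10, 0, 5, 5]))


class TestPredict:
    def test_probabilities_sum_to_one_and_match_scores(self, montage8):
        net = sd.build_model(sd.NetConfig(F1=4, D=2), 8, 96, seed=1)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((7, 8, 96))
        probs, scores = sd.predict(net, x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        ext = np.exp(scores - scores.max(axis=1, keepdims=True))
        assert np.allclose(probs, ext / ext.sum(axis=1, keepdims=True),
                           atol=1e-6)

    def test_zeroed_dense_layer_gives_uniform_probs(self):
        net = sd.build_model(sd.NetConfig(F1=4, D=2), 8, 96, seed=1)
        net.params["w_fc"][:] = 0.0
        net.params["b_fc"][:] = 0.0
        probs, _ = sd.predict(net, np.random.default_rng(0)
                              .standard_normal((3, 8, 96)))
        assert np.allclose(probs, 0.25, atol=1e-7)

    def test_prediction_deterministic_and_permutation_equivariant(self):
        net = sd.build_model(sd.NetConfig(F1=4, D=2), 8, 96, seed=2)
        rng = np.random.default_rng(3)
        x = rng.standard_normal((10, 8, 96))
        p1, _ = sd.predict(net, x)
        p2, _ = sd.predict(net, x)
        assert np.array_equal(p1, p2)  # dropout off, running BN stats
        perm = rng.permutation(10)
        pp, _ = sd.predict(net, x[perm])
        assert np.allclose(pp, p1[perm], atol=1e-6)

    def test_shape_mismatch_errors(self):
        net = sd.build_model(sd.NetConfig(F1=4, D=2), 8, 96)
        with pytest.raises(ValueError, match="match"):
            sd.predict(net, np.zeros((2, 8, 100)))


class TestGradients:
    def test_parameter_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        net = sd.build_model(sd.NetConfig(F1=2, D=2, dropout_p=0.0),
                             C=6, T=70, seed=3, dtype=np.float64)
        x = rng.standard_normal((8, 6, 70))
        y = rng.integers(0, 4, 8)

        def loss():
            logits, cache = net.forward(x, training=True)
            val, dl = _weighted_ce(logits, y, None)
            return val, dl, cache

        _, dl, cache = loss()
        grads, _ = net.backward(dl, cache)
        for name, g in grads.items():
            flat = net.params[name].ravel()
            idxs = np.random.default_rng(0).choice(
                flat.size, size=min(4, flat.size), replace=False
            )
            for idx in idxs:
                orig = flat[idx]
                flat[idx] = orig + 1e-6
                lp, _, _ = loss()
                flat[idx] = orig - 1e-6
                lm, _, _ = loss()
                flat[idx] = orig
                fd = (lp - lm) / 2e-6
                assert g.ravel()[idx] == pytest.approx(fd, rel=1e-3,
                                                       abs=1e-9), name


def _toy_epochs(n, seed, montage, n_classes=2):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, n)
    x = rng.standard_normal((n, len(montage), 96)) * 0.5
    x[:, 0, :] += (2 * (y % 2) - 1)[:, None] * 1.0
    return EpochSet("toy", x, np.arange(96) * 4.0, y, montage, 250.0)


class TestTraining:
    def test_linearly_separable_toy_reaches_perfect_accuracy(self, montage8):
        train_set = _toy_epochs(128, 1, montage8)
        val_set = _toy_epochs(64, 2, montage8)
        net = sd.build_model(sd.NetConfig(F1=4, D=2, n_classes=2), 8, 96,
                             seed=0)
        trained = sd.train(net, train_set, val_set, max_epochs=50, seed=0)
        probs, _ = sd.predict(trained, train_set)
        assert (probs.argmax(1) == train_set.labels).mean() == 1.0

    def test_checkpoint_is_validation_minimum(self, montage8):
        train_set = _toy_epochs(64, 3, montage8)
        val_set = _toy_epochs(32, 4, montage8)
        net = sd.build_model(sd.NetConfig(F1=4, D=2, n_classes=2), 8, 96,
                             seed=1)
        trained = sd.train(net, train_set, val_set, max_epochs=12, seed=1)
        hist = trained.history
        assert len(hist) <= 500
        assert trained.best_epoch == hist["val_loss"].idxmin()
        assert (hist["val_loss"].min()
                == hist.loc[trained.best_epoch, "val_loss"])

    def test_seeded_training_is_reproducible(self, montage8):
        train_set = _toy_epochs(64, 5, montage8)
        val_set = _toy_epochs(32, 6, montage8)
        runs = []
        for _ in range(2):
            net = sd.build_model(sd.NetConfig(F1=4, D=2, n_classes=2),
                                 8, 96, seed=7)
            runs.append(sd.train(net, train_set, val_set, max_epochs=6,
                                 seed=7))
        assert runs[0].history.equals(runs[1].history)
        for k in runs[0].model.params:
            assert np.array_equal(runs[0].model.params[k],
                                  runs[1].model.params[k])

    def test_missing_class_in_training_errors(self, montage8):
        train_set = _toy_epochs(64, 8, montage8, n_classes=2)
        val_set = _toy_epochs(32, 9, montage8, n_classes=2)
        net = sd.build_model(sd.NetConfig(F1=4, D=2, n_classes=4), 8, 96)
        with pytest.raises(ValueError):
            sd.train(net, train_set, val_set, max_epochs=2)

    def test_maxnorm_constraints_hold_after_training(self, montage8):
        train_set = _toy_epochs(64, 10, montage8)
        val_set = _toy_epochs(32, 11, montage8)
        net = sd.build_model(sd.NetConfig(F1=4, D=2, n_classes=2), 8, 96,
                             seed=2)
        trained = sd.train(net, train_set, val_set, max_epochs=8, seed=2)
        w_dw = trained.model.params["w_dw"]
        assert np.all(np.linalg.norm(w_dw, axis=2) <= 1.0 + 1e-5)
        w_fc = trained.model.params["w_fc"]
        assert np.all(np.linalg.norm(w_fc, axis=1) <= 0.25 + 1e-5)


class TestFilterConfigSelection:
    def test_single_candidate_returned_unchanged(self):
        cfg = sd.select_filter_config({}, candidates=[(4, 2)])
        assert (cfg.F1, cfg.D) == (4, 2)

    def test_selected_config_member_of_candidates(self, micro_cohort):
        _, _, dataset = micro_cohort
        cfg = sd.select_filter_config(
            dataset, candidates=[(4, 2), (8, 2)], n_val=1, seed=0,
            max_epochs=2,
        )
        assert (cfg.F1, cfg.D) in [(4, 2), (8, 2)]
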