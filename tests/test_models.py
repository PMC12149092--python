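"""Classifier architectures: layer plans, autodiff gradient correctness,
determinism and capacity on separable data."""

import numpy as np
import pytest

from vgeeg.models import (
    ModelSpec,
    TrainingParams,
    build_model,
    fit,
    load_model,
    predict_proba,
    save_model,
    sequence_layout,
)
from vgeeg.nn import Tensor, build_lstm, build_mlp
from vgeeg.nn.layers import BatchNorm, Dense, Dropout, LSTM

from conftest import separable_rows


class TestArchitecturePlans:
    def test_mlp_six_hidden_layers_of_64(self):
        net = build_mlp(630, np.random.default_rng(0))
        denses = [l for l in net.body.layers if isinstance(l, Dense)]
        widths = [d.w.shape for d in denses]
        assert widths == [(630, 64)] + [(64, 64)] * 5 + [(64, 1)]

    def test_lstm_unit_plan_and_regularization(self):
        net = build_lstm(70, 9, np.random.default_rng(0))
        layers = net.body.layers
        lstms = [l for l in layers if isinstance(l, LSTM)]
        assert [l.n_units for l in lstms] == [100, 50, 25]
        assert [l.return_sequences for l in lstms] == [True, True, False]
        assert isinstance(layers[1], BatchNorm)  # after the first LSTM
        dropouts = [l for l in layers if isinstance(l, Dropout)]
        assert len(dropouts) == 1 and dropouts[0].rate == 0.2

    def test_identical_seed_gives_identical_initialization(self):
        layout = tuple(("c0", b, "f") for b in ("delta", "theta", "alpha"))
        spec = ModelSpec("mlp", TrainingParams(seed=7))
        a = build_model(spec, layout)
        b = build_model(spec, layout)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_sequence_layout_groups_channel_band_pairs(self):
        rows = separable_rows(2, n_channels=3, n_bands=5, feats_per_group=2)
        keys, index = sequence_layout(rows[0].layout)
        assert index.shape == (15, 2)
        assert keys[0] == ("ch0", "delta")

    def test_sequence_model_needs_multiple_steps(self):
        layout = (("c0", "alpha", "f0"), ("c0", "alpha", "f1"))
        with pytest.raises(ValueError, match="steps"):
            build_model(ModelSpec("lstm"), layout)


class TestGradients:
    def _check(self, net, x, y, tol=1e-4):
        from vgeeg.models import _bce

        loss = _bce(net.forward(Tensor(x), training=False), y)
        loss.backward()
        for p in net.parameters():
            g = p.grad
            idx = np.unravel_index(np.argmax(np.abs(g)), g.shape)
            eps = 1e-6
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = float(_bce(net.forward(Tensor(x)), y).data)
            p.data[idx] = orig - eps
            lm = float(_bce(net.forward(Tensor(x)), y).data)
            p.data[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=tol, abs=1e-7)

    @pytest.mark.parametrize("arch", ["mlp", "lstm", "inception_time", "chrononet"])
    def test_backprop_matches_finite_differences(self, arch):
        from vgeeg.nn import build_chrononet, build_inception_time

        rng = np.random.default_rng(0)
        y = (rng.random(5) > 0.5).astype(float)
        g = np.random.default_rng(1)
        if arch == "mlp":
            net, x = build_mlp(8, g, hidden=(6, 6)), rng.normal(size=(5, 8))
        elif arch == "lstm":
            net, x = build_lstm(6, 3, g, units=(5, 4, 3)), rng.normal(size=(5, 6, 3))
        elif arch == "inception_time":
            net, x = build_inception_time(6, 3, g, filters=(4,)), rng.normal(size=(5, 6, 3))
        else:
            net, x = (
                build_chrononet(6, 3, g, conv_filters=3, n_conv_blocks=1, gru_units=(4,)),
                rng.normal(size=(5, 6, 3)),
            )
        self._check(net, x, y)


class TestFitPredict:
    def test_fit_determinism(self):
        rows = separable_rows(40, seed=3)
        spec = ModelSpec("mlp", TrainingParams(epochs=10, seed=5))
        p1 = predict_proba(fit(spec, rows), rows)
        p2 = predict_proba(fit(spec, rows), rows)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        rows = [r for r in separable_rows(20) if r.label == 0]
        with pytest.raises(ValueError, match="both classes"):
            fit(ModelSpec("mlp"), rows)

    def test_probabilities_within_unit_interval(self):
        rows = separable_rows(30, seed=2)
        fitted = fit(ModelSpec("mlp", TrainingParams(epochs=5, seed=1)), rows)
        p = predict_proba(fitted, rows)
        assert np.all((p >= 0) & (p <= 1))

    def test_duplicated_row_duplicated_probability(self):
        rows = separable_rows(20, seed=4)
        fitted = fit(ModelSpec("mlp", TrainingParams(epochs=5, seed=1)), rows)
        p = predict_proba(fitted, [rows[0], rows[0]])
        assert p[0] == p[1]

    def test_training_history_decreases(self):
        rows = separable_rows(40, seed=6)
        fitted = fit(ModelSpec("mlp", TrainingParams(epochs=30, seed=2)), rows)
        assert len(fitted.training_history) == 30
        assert fitted.training_history[-1] <= fitted.training_history[0] + 1e-6

    def test_layout_mismatch_rejected(self):
        rows = separable_rows(20)
        other = separable_rows(4, n_channels=3)
        fitted = fit(ModelSpec("mlp", TrainingParams(epochs=2)), rows)
        with pytest.raises(ValueError, match="layout"):
            predict_proba(fitted, other)

    @pytest.mark.parametrize("arch", ["mlp", "lstm", "inception_time", "chrononet"])
    def test_capacity_on_separable_data(self, arch):
        # every architecture must drive training accuracy to >= 0.95 on a
        # linearly separable 200-row set
        rows = separable_rows(200, n_channels=2, n_bands=5, shift=3.0, seed=9)
        spec = ModelSpec(arch, TrainingParams(epochs=25, batch_size=16, seed=0))
        fitted = fit(spec, rows)
        pred = fitted.predict(rows)
        acc = (pred == np.array([r.label for r in rows])).mean()
        assert acc >= 0.95

    def test_save_load_round_trip(self, tmp_path):
        rows = separable_rows(30, seed=11)
        fitted = fit(ModelSpec("mlp", TrainingParams(epochs=5, seed=3)), rows)
        path = save_model(fitted, tmp_path / "model.npz")
        back = load_model(path)
        assert np.allclose(predict_proba(back, rows), predict_proba(fitted, rows))
        assert back.spec == fitted.spec
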