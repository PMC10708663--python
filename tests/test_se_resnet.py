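import numpy as np
import pytest

from hsicalib.se_resnet import (
    ArchitectureSpec,
    SEResNet,
    TrainConfig,
    build_model,
    channel_convolution,
    predict,
    se_recalibrate,
    train_model,
)
from hsicalib.segmentation import SampleRecord


def tiny_spec() -> ArchitectureSpec:
    """Toy profile for optimisation tests (milliseconds per epoch)."""
    return ArchitectureSpec(
        input_hw=(8, 8), in_channels=6, stem_channels=16,
        stage_blocks=(1, 1, 1, 1), stage_channels=(16, 16, 16, 16),
        se_reduction=4, head_widths=(8, 5),
    )


def toy_records(rng, n=8, bands=6, hw=8):
    """Targets depend linearly on a per-sample base spectrum; pixels add a
    little texture so convolutions have something to look at."""
    W = rng.normal(size=(bands, 5))
    records = []
    for i in range(n):
        base = rng.uniform(0.1, 0.9, size=bands)
        patch = base[None, None, :] + 0.01 * rng.normal(size=(hw, hw, bands))
        conc = np.abs(base @ W) + 0.1
        records.append(SampleRecord(f"toy{i}", base, conc, patch))
    return records


class TestChannelConvolution:
    def test_one_by_one_kernel_scales_input(self, rng):
        X = rng.normal(size=(5, 5, 1))
        V = np.full((1, 1, 1, 1), 2.5)
        np.testing.assert_allclose(channel_convolution(X, V), 2.5 * X, rtol=1e-6)

    def test_unit_kernels_sum_channels(self, rng):
        X = rng.normal(size=(4, 4, 2))
        V = np.ones((1, 2, 1, 1))
        out = channel_convolution(X, V)
        np.testing.assert_allclose(out[:, :, 0], X.sum(axis=2), rtol=1e-5, atol=1e-6)

    def test_delta_kernel_sums_channels(self, rng):
        X = rng.normal(size=(6, 6, 3))
        V = np.zeros((1, 3, 3, 3))
        V[0, :, 1, 1] = 1.0  # spatial delta per channel
        out = channel_convolution(X, V)
        np.testing.assert_allclose(out[:, :, 0], X.sum(axis=2), rtol=1e-5, atol=1e-6)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            channel_convolution(rng.normal(size=(4, 4, 2)),
                                np.ones((1, 3, 1, 1)))


class TestSERecalibrate:
    def test_all_ones_excitation_is_identity(self, rng):
        U = rng.normal(size=(5, 5, 4)).astype(np.float32)
        out = se_recalibrate(U, reduction=2, excitation_override=np.ones(4))
        np.testing.assert_allclose(out, U, rtol=1e-6)

    def test_squeeze_of_constant_channel_is_its_value(self):
        from hsicalib.nn import SEModule

        U = np.zeros((3, 3, 2), dtype=np.float32)
        U[:, :, 0] = 0.7
        U[:, :, 1] = -1.2
        x = U.transpose(2, 0, 1)[None]
        z = x.mean(axis=(2, 3))
        np.testing.assert_allclose(z.ravel(), [0.7, -1.2], rtol=1e-6)

    def test_excitation_weights_strictly_in_unit_interval(self, rng):
        from hsicalib.nn import SEModule

        se = SEModule(8, 4, rng=np.random.default_rng(0))
        x = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        se.forward(x)
        assert np.all(se._s > 0) and np.all(se._s < 1)

    def test_reduction_must_divide_channels(self, rng):
        with pytest.raises(ValueError):
            se_recalibrate(rng.normal(size=(4, 4, 6)).astype(np.float32),
                           reduction=4)


class TestArchitecture:
    def test_default_spec_is_full_fidelity_profile(self):
        spec = ArchitectureSpec()
        assert spec.stage_blocks == (3, 4, 23, 3)
        assert spec.total_blocks == 33
        assert spec.head_in == 2048
        assert spec.head_widths == (256, 5)

    def test_default_model_builds_and_outputs_five(self):
        spec = ArchitectureSpec(input_hw=(32, 32))
        model = build_model(spec, seed=0)
        assert len(model.blocks) == 33
        assert model.fc1.weight.value.shape == (2048, 256)
        assert model.fc2.weight.value.shape == (256, 5)
        out = model.forward(
            np.random.default_rng(0).normal(size=(2, 128, 32, 32)).astype(np.float32),
            train=False,
        )
        assert out.shape == (2, 5)

    def test_parameter_count_invariant_across_seeds(self):
        spec = ArchitectureSpec.reduced()
        assert build_model(spec, seed=0).n_parameters() == \
            build_model(spec, seed=99).n_parameters()

    def test_reduced_spec_forward_is_fast(self):
        import time

        model = build_model(tiny_spec(), seed=0)
        x = np.random.default_rng(1).normal(size=(2, 6, 8, 8)).astype(np.float32)
        t0 = time.time()
        out = model.forward(x, train=False)
        assert out.shape == (2, 5)
        assert time.time() - t0 < 1.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(stage_channels=(250, 512, 1024, 2048))  # 250 % 16
        with pytest.raises(ValueError):
            ArchitectureSpec(head_widths=(256, 4))
        with pytest.raises(ValueError):
            ArchitectureSpec(stage_blocks=(0, 4, 23, 3))

    def test_spec_round_trips_through_dict(self):
        spec = ArchitectureSpec.reduced()
        assert ArchitectureSpec.from_dict(spec.to_dict()) == spec

    def test_pinned_excitations_make_plain_resnet(self, rng):
        model = build_model(tiny_spec(), seed=0)
        x = rng.normal(size=(2, 6, 8, 8)).astype(np.float32)
        base = model.forward(x, train=False)
        model.pin_excitations(True)
        pinned = model.forward(x, train=False)
        assert not np.allclose(base, pinned)


class TestTraining:
    @pytest.fixture(scope="class")
    def trained_toy(self):
        rng = np.random.default_rng(7)
        records = toy_records(rng)
        model = build_model(tiny_spec(), seed=0)
        config = TrainConfig(epochs=1000, learning_rate=3e-3, batch_size=8,
                             seed=0, input_norm="channel", augment_flips=False,
                             ema_decay=0.0)
        model, history = train_model(model, records, config)
        return records, model, history, config

    def test_overfits_toy_set(self, trained_toy):
        _, _, history, _ = trained_toy
        assert history[-1] < 1e-2

    def test_loss_moving_average_non_increasing(self, trained_toy):
        _, _, history, _ = trained_toy
        ma = np.convolve(history, np.ones(20) / 20, mode="valid")
        # allow float jitter only
        assert np.all(np.diff(ma) <= 1e-3 * ma[0])

    def test_train_set_r2_after_overfit(self, trained_toy):
        from hsicalib.evaluation import EvaluationPair, r_squared

        records, model, _, _ = trained_toy
        pred = predict(model, records)
        Y = np.stack([r.concentrations for r in records])
        for k in range(5):
            assert r_squared(EvaluationPair(Y[:, k], pred[:, k])) >= 0.99

    def test_identical_seed_identical_history(self):
        rng = np.random.default_rng(7)
        records = toy_records(rng)
        config = TrainConfig(epochs=30, learning_rate=3e-3, batch_size=8,
                             seed=0, input_norm="channel", augment_flips=False)
        _, h1 = train_model(build_model(tiny_spec(), seed=0), records, config)
        _, h2 = train_model(build_model(tiny_spec(), seed=0), records, config)
        assert h1 == h2

    def test_single_record_prediction_shape(self, trained_toy):
        records, model, _, _ = trained_toy
        assert predict(model, records[:1]).shape == (1, 5)

    def test_standardize_round_trip(self, trained_toy):
        _, model, _, _ = trained_toy
        Y = np.random.default_rng(3).normal(size=(6, 5)) * 4 + 2
        z = model.y_stats.transform(Y)
        np.testing.assert_allclose(model.y_stats.inverse(z), Y, atol=1e-10)

    def test_needs_patches_and_targets(self):
        rec = SampleRecord("a", np.zeros(6), None, None)
        with pytest.raises(ValueError):
            train_model(build_model(tiny_spec(), seed=0), [rec, rec],
                        TrainConfig(epochs=1))
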