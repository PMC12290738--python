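"""Noise-predictor contract: channel accounting, determinism, time
sensitivity, end-to-end gradients, checkpoint round trip, overfit sanity."""

import numpy as np
import pytest

from longidiff.autodiff import Tensor
from longidiff.denoiser import (Denoiser, DenoiserSpec, build_denoiser,
                                load_checkpoint, predict, save_checkpoint,
                                spec_for_layout)
from longidiff.diffusion import ConditionSet, make_schedule, training_loss
from longidiff.nn import Adam
from longidiff.unitizer import make_layout

TINY = dict(base_channels=8, depth=2, channel_mults=(1, 2),
            attention_levels=(1,), groups=4, time_embed_dim=16)


@pytest.fixture(scope="module")
def small_model():
    spec = DenoiserSpec(in_channels=9, out_channels=3, image_size=(16, 16),
                        **TINY)
    return build_denoiser(spec, np.random.default_rng(0))


class TestChannelAccounting:
    def test_past_condition(self):
        lay = make_layout(32, 32, 32, K=5, J=1)
        spec = spec_for_layout(lay, n_cond=1, preset="tiny")
        assert (spec.in_channels, spec.out_channels) == (30, 15)

    def test_past_and_following_condition(self):
        lay = make_layout(32, 32, 32, K=5, J=1)
        spec = spec_for_layout(lay, n_cond=2, preset="tiny")
        assert spec.in_channels == 45

    def test_autoencoder_has_no_target_channel(self):
        lay = make_layout(32, 32, 32, K=5, J=1)
        spec = spec_for_layout(lay, n_cond=2, preset="tiny",
                               include_target=False)
        assert spec.in_channels == 30

    def test_indivisible_image_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            DenoiserSpec(in_channels=6, out_channels=3, image_size=(15, 16),
                         **TINY)


class TestPredict:
    def test_output_shape_and_finiteness(self, small_model, rng):
        x = rng.standard_normal((2, 9, 16, 16))
        out = small_model.predict(x, np.array([1, 10]))
        assert out.shape == (2, 3, 16, 16)
        assert np.all(np.isfinite(out))

    def test_single_unit_wrapper(self, small_model, rng):
        x = rng.standard_normal((9, 16, 16))
        out = predict(small_model, x, 3)
        assert out.shape == (3, 16, 16)

    def test_time_embedding_sensitivity(self, small_model, rng):
        x = rng.standard_normal((1, 9, 16, 16))
        a = small_model.predict(x, np.array([1]))
        b = small_model.predict(x, np.array([20]))
        assert not np.allclose(a, b)

    def test_seeded_builds_coincide(self):
        spec = DenoiserSpec(in_channels=6, out_channels=3,
                            image_size=(16, 16), **TINY)
        m1 = build_denoiser(spec, np.random.default_rng(7))
        m2 = build_denoiser(spec, np.random.default_rng(7))
        x = np.random.default_rng(1).standard_normal((1, 6, 16, 16))
        assert np.array_equal(m1.predict(x, np.array([5])),
                              m2.predict(x, np.array([5])))

    def test_wrong_channel_count_rejected(self, small_model, rng):
        with pytest.raises(ValueError, match="channels"):
            small_model.predict(rng.standard_normal((1, 5, 16, 16)),
                                np.array([1]))


class TestTrainingGradients:
    def test_loss_gradients_finite_and_nonzero(self, small_model, rng):
        sched = make_schedule(10, 1e-2, 0.2)
        target = rng.random((2, 3, 16, 16))
        cond = ConditionSet("PF", (rng.random((2, 3, 16, 16)),
                                   rng.random((2, 3, 16, 16))))
        eps = rng.standard_normal(target.shape)
        small_model.zero_grad()
        loss = training_loss(small_model, target, cond, np.array([2, 7]), eps,
                             sched, return_graph=True)
        loss.backward()
        grads = [p.grad for p in small_model.parameters()]
        assert all(g is None or np.all(np.isfinite(g)) for g in grads)
        assert any(g is not None and np.abs(g).max() > 0 for g in grads)

    def test_loss_floor_at_oracle_prediction(self, rng):
        """training_loss is zero iff the model reproduces eps exactly."""
        sched = make_schedule(5, 1e-2, 0.2)

        class EpsOracle:
            def __init__(self, eps):
                self.eps = eps

            def forward(self, x, t):
                return Tensor(self.eps)

        eps = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        cond = ConditionSet("P", (np.zeros((1, 3, 8, 8)),))
        target = rng.random((1, 3, 8, 8))
        assert training_loss(EpsOracle(eps), target, cond, 3, eps, sched) == 0

        class Zero:
            def forward(self, x, t):
                return Tensor(np.zeros((1, 3, 8, 8), dtype=np.float32))

        loss = training_loss(Zero(), target, cond, 3, eps, sched)
        assert loss == pytest.approx(float(np.mean(eps ** 2)), rel=1e-5)

    def test_zero_model_expected_loss_near_one(self, rng):
        """E||eps||^2 / d = 1 for standard-normal noise (Monte Carlo)."""
        sched = make_schedule(5, 1e-2, 0.2)

        class Zero:
            def forward(self, x, t):
                return Tensor(np.zeros(x.shape[0:1] + (3, 8, 8),
                                       dtype=np.float32))

        cond = ConditionSet("P", (np.zeros((8, 3, 8, 8)),))
        target = rng.random((8, 3, 8, 8))
        losses = [training_loss(Zero(), target, cond,
                                rng.integers(1, 6, size=8),
                                rng.standard_normal(target.shape), sched)
                  for _ in range(40)]
        assert np.mean(losses) == pytest.approx(1.0, abs=0.05)


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, small_model, tmp_path,
                                              rng):
        path = tmp_path / "ckpt.npz"
        opt = Adam(small_model.parameters(), lr=1e-3)
        save_checkpoint(path, small_model, step=42,
                        optimizer_state=opt.get_state(),
                        rng_state=np.random.default_rng(3).bit_generator.state)
        model, step, opt_state, rng_state = load_checkpoint(path)
        assert step == 42
        assert model.spec == small_model.spec
        x = rng.standard_normal((1, 9, 16, 16))
        assert np.array_equal(model.predict(x, np.array([4])),
                              small_model.predict(x, np.array([4])))
        assert opt_state["step_count"] == 0
        assert rng_state["bit_generator"] == "PCG64"


class TestOverfitSanity:
    def test_short_training_beats_zero_model_baseline(self):
        """A tiny instance trained on one repeated phantom unit drives the
        noise-prediction loss clearly below the zero-model level of ~1."""
        rng = np.random.default_rng(0)
        sched = make_schedule(20, 5e-3, 0.35)
        spec = DenoiserSpec(in_channels=9, out_channels=3,
                            image_size=(16, 16), **TINY)
        model = build_denoiser(spec, rng)
        opt = Adam(model.parameters(), lr=1e-3)
        target = rng.random((4, 3, 16, 16)).astype(np.float32)
        cond = ConditionSet("PF", (target + 0.05, target - 0.05))
        losses = []
        for _ in range(300):
            t = rng.integers(1, sched.T + 1, size=4)
            eps = rng.standard_normal(target.shape)
            model.zero_grad()
            loss = training_loss(model, target, cond, t, eps, sched,
                                 return_graph=True)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert float(np.mean(losses[-50:])) < 0.8
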