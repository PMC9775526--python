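"""Resolution schedule, Wasserstein-divergence losses, interpolates,
progressive growth, and small training runs of the epoch GAN."""

import numpy as np
import pytest

from sleepgan import autodiff as ad
from sleepgan.autodiff import Tensor
from sleepgan.gan import (
    Discriminator,
    GanConfig,
    Generator,
    build_schedule,
    discriminator_loss,
    downscale_epochs,
    generator_loss,
    make_interpolates,
    sample_epochs,
    stage_learning_rates,
    train_stage,
)
from sleepgan.signal import normalize_epoch

SMOKE = GanConfig(
    channels=8, batch_size=8, epochs_per_scale=6, scheduler_milestone=5, latent_size=100
)


# ------------------------------------------------------------------ schedule
def test_default_schedule_matches_printed_sizes():
    s = build_schedule(100, 3000, 4)
    assert s.sizes == (100, 230, 965, 3000)


def test_rescale_factor_value():
    s = build_schedule(100, 3000, 4)
    assert s.rescale_factor == pytest.approx((1 / 30) ** (1 / 3), rel=1e-12)


@pytest.mark.parametrize("S,c", [(50, 3), (100, 30), (7, 2)])
def test_two_stage_schedule_degenerates_to_endpoints(S, c):
    s = build_schedule(S, S * c, 2)
    assert s.sizes == (S, S * c)


def test_schedule_rejects_bad_arguments():
    with pytest.raises(ValueError):
        build_schedule(100, 3000, 1)
    with pytest.raises(ValueError):
        build_schedule(3000, 100, 4)


def test_schedule_endpoints_and_monotonicity():
    for N in (2, 3, 4, 5):
        s = build_schedule(64, 2048, N)
        assert s.sizes[0] == 64 and s.sizes[-1] == 2048
        assert all(b > a for a, b in zip(s.sizes, s.sizes[1:]))


# -------------------------------------------------------------------- losses
def test_constant_critic_gives_zero_loss():
    cfg = GanConfig()
    loss = discriminator_loss([3.0, 3.0], [3.0, 3.0], [0.0, 0.0], cfg)
    assert loss.item() == 0.0


def test_discriminator_loss_hand_example():
    cfg = GanConfig()  # k=2, p=6
    loss = discriminator_loss([1.0, 3.0], [0.0, 0.0], [1.0, 1.0], cfg)
    assert loss.item() == pytest.approx(4.0)


def test_penalty_closed_form_and_monotonicity():
    cfg = GanConfig()
    base = discriminator_loss([0.0], [0.0], [0.0], cfg).item()
    prev = base
    for g in (0.5, 0.8, 1.0, 1.3):
        val = discriminator_loss([0.0], [0.0], [g], cfg).item()
        assert val == pytest.approx(2.0 * g**6)
        assert val > prev
        prev = val


def test_generator_loss_hand_examples():
    assert generator_loss([1.0, 2.0], [1.0, 2.0]).item() == 0.0
    assert generator_loss([0.0, 0.0], [1.0, 3.0]).item() == pytest.approx(-2.0)


def test_loss_identity_on_shared_batch(rng):
    """L_G = penalty - L_D whenever the fake batch is shared."""
    cfg = GanConfig()
    d_fake = rng.standard_normal(16)
    d_real = rng.standard_normal(16)
    norms = np.abs(rng.standard_normal(16))
    l_d = discriminator_loss(d_fake, d_real, norms, cfg).item()
    l_g = generator_loss(d_real, d_fake).item()
    penalty = cfg.k * np.mean(norms**cfg.p)
    assert l_g == pytest.approx(penalty - l_d, rel=1e-12)


def test_empty_batch_rejected():
    with pytest.raises(ValueError):
        discriminator_loss([], [1.0], [1.0], GanConfig())
    with pytest.raises(ValueError):
        generator_loss([1.0], [])


def test_interpolates_endpoints_and_midpoint():
    x_r, x_f = np.array([[2.0]]), np.array([[0.0]])
    np.testing.assert_array_equal(make_interpolates(x_r, x_f, [1.0]), x_r)
    np.testing.assert_array_equal(make_interpolates(x_r, x_f, [0.0]), x_f)
    np.testing.assert_array_equal(make_interpolates(x_r, x_f, [0.5]), [[1.0]])
    with pytest.raises(ValueError):
        make_interpolates(np.zeros((2, 3)), np.zeros((3, 3)), [0.5, 0.5])


def test_interpolates_lie_on_segment(rng):
    x_r = rng.standard_normal((5, 1, 20))
    x_f = rng.standard_normal((5, 1, 20))
    u = rng.random(5)
    x_hat = make_interpolates(x_r, x_f, u)
    for i in range(5):
        lam = u[i]
        np.testing.assert_allclose(x_hat[i], lam * x_r[i] + (1 - lam) * x_f[i])


# ---------------------------------------------------- penalty parameter grad
def test_penalty_parameter_gradient_matches_finite_differences(rng):
    """The input-gradient graph gives the exact d(penalty)/d(weights)."""
    cfg = GanConfig(channels=4)
    disc = Discriminator(cfg, rng)
    x_hat = rng.standard_normal((3, 1, 40))

    def penalty_value():
        g = disc.input_gradient_graph(x_hat)
        n = ad.sqrt(ad.sum_(g * g, axis=(1, 2)) + 1e-24)
        return (cfg.k * ad.mean(ad.power(n, cfg.p))).item()

    g = disc.input_gradient_graph(x_hat)
    norms = ad.sqrt(ad.sum_(g * g, axis=(1, 2)) + 1e-24)
    pen = cfg.k * ad.mean(ad.power(norms, cfg.p))
    disc.zero_grad()
    ad.backward(pen)

    w = disc.convs[1].weight
    eps = 1e-6
    num = np.zeros_like(w.data)
    it = np.nditer(w.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = w.data[i]
        w.data[i] = old + eps
        fp = penalty_value()
        w.data[i] = old - eps
        fm = penalty_value()
        w.data[i] = old
        num[i] = (fp - fm) / (2 * eps)
    np.testing.assert_allclose(w.grad, num, rtol=1e-4, atol=1e-8)


def test_input_gradient_graph_matches_direct_backprop(rng):
    cfg = GanConfig(channels=4)
    disc = Discriminator(cfg, rng)
    x = rng.standard_normal((2, 1, 30))
    xt = Tensor(x, requires_grad=True)
    ad.backward(ad.sum_(disc(xt)))
    np.testing.assert_allclose(xt.grad, disc.input_gradient_graph(x).data, atol=1e-12)


# ------------------------------------------------------------ growth / model
def test_grow_changes_output_length_and_preserves_parameters(rng):
    gen = Generator("N3", SMOKE, rng)
    z = rng.standard_normal((2, 1, 100))
    assert gen(z).data.shape[-1] == 100
    before = [p.data.copy() for p in gen.stages[0].parameters()]
    gen.grow(rng)
    assert gen(z).data.shape[-1] == 230
    for old, new in zip(before, gen.stages[0].parameters()):
        np.testing.assert_array_equal(old, new.data)


def test_growth_beyond_final_stage_rejected(rng):
    gen = Generator("N3", SMOKE, rng)
    for _ in range(3):
        gen.grow(rng)
    with pytest.raises(ValueError):
        gen.grow(rng)


def test_residual_path_with_identity_convs_doubles_features(rng):
    """With zero feature noise and identity-initialized new convs, the
    grown stage outputs exactly twice the upsampled features."""
    cfg = SMOKE.with_overrides(noise_amplitude=0.0, lrelu_alpha=1.0)
    gen = Generator("W", cfg, rng)
    gen.grow(rng)
    for block in gen.stages[1].blocks:
        block.conv.set_identity()
        block.bn.set_identity()
    z = rng.standard_normal((2, 1, 100))
    f0 = gen.stages[0](Tensor(z))
    up = ad.upsample_linear(f0, gen.schedule.sizes[1])
    f1 = gen.features(z)
    np.testing.assert_allclose(f1.data, 2.0 * up.data, atol=1e-10)


def test_stage_learning_rates_follow_decay():
    cfg = GanConfig()
    lrs = stage_learning_rates(top=3, config=cfg)
    assert lrs[3] == pytest.approx(5e-4)
    assert lrs[2] == pytest.approx(5e-5)
    assert lrs[1] == pytest.approx(5e-4 * 0.01)
    assert 0 not in lrs  # only the last 3 stages train concurrently


# ------------------------------------------------------------------ training
def test_train_stage_smoke_and_determinism(fixture_set):
    X = np.stack([normalize_epoch(e).samples for e in fixture_set["N3"]])
    X0 = downscale_epochs(X, 100)

    def run():
        rng = np.random.default_rng(5)
        gen = Generator("N3", SMOKE, rng)
        disc = Discriminator(SMOKE, rng)
        return train_stage(gen, disc, X0, SMOKE, rng)

    r1, r2 = run(), run()
    assert np.all(np.isfinite(r1.d_losses)) and np.all(np.isfinite(r1.g_losses))
    assert r1.d_losses == r2.d_losses and r1.g_losses == r2.g_losses


def test_train_stage_rejects_wrong_resolution(fixture_set, rng):
    X = np.stack([normalize_epoch(e).samples for e in fixture_set["N3"]])
    gen = Generator("N3", SMOKE, rng)
    disc = Discriminator(SMOKE, rng)
    with pytest.raises(ValueError, match="length"):
        train_stage(gen, disc, X, SMOKE, rng)  # full length given to stage 0


def test_sampling_requires_final_stage(rng):
    gen = Generator("W", SMOKE, rng)
    with pytest.raises(ValueError, match="final"):
        sample_epochs(gen, 2, seed=0)


def test_sampling_contract_after_growth(rng):
    gen = Generator("REM", SMOKE, rng)
    for _ in range(3):
        gen.grow(rng)
    eps = sample_epochs(gen, 5, seed=3)
    assert len(eps) == 5
    for e in eps:
        assert e.stage == "REM"
        assert len(e.samples) == 3000
        assert np.abs(e.samples).max() <= 1.0
    eps2 = sample_epochs(gen, 5, seed=3)
    np.testing.assert_array_equal(eps[0].samples, eps2[0].samples)
    eps3 = sample_epochs(gen, 5, seed=4)
    assert not np.array_equal(eps[0].samples, eps3[0].samples)


def test_downscale_preserves_full_resolution_identity(rng):
    X = rng.standard_normal((3, 50))
    np.testing.assert_array_equal(downscale_epochs(X, 50), X)
    assert downscale_epochs(X, 20).shape == (3, 20)
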