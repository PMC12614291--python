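import numpy as np
import pytest

from cbctdiff.diffusion import (
    DiffusionError,
    LossHistory,
    SamplingConfig,
    TrainConfig,
    forward_diffuse,
    forward_step,
    reverse_step,
    sample_noised_conditioned,
    sample_original,
    train,
    training_loss,
)
from cbctdiff.schedules import make_schedule
from cbctdiff.timesteps import TimestepDistribution


@pytest.fixture(scope="module")
def sched():
    return make_schedule("linear", 40, 1e-3, 0.1)


class ZeroDenoiser:
    def predict(self, x_t, y0, t):
        return np.zeros_like(x_t)


class PerfectDenoiser:
    """Returns the very noise that was injected (test rig for the loss)."""

    def __init__(self, eps):
        self.eps = eps

    def predict(self, x_t, y0, t):
        return self.eps


# -- forward process --------------------------------------------------------

def test_forward_diffuse_boundary_cases(sched, rng):
    x0 = rng.standard_normal((6, 6))
    eps = rng.standard_normal((6, 6))
    np.testing.assert_array_equal(forward_diffuse(x0, 0, eps, sched), x0)
    np.testing.assert_allclose(
        forward_diffuse(x0, 5, np.zeros_like(x0), sched),
        np.sqrt(sched.alpha_bar_at(5)) * x0,
    )
    np.testing.assert_allclose(
        forward_diffuse(np.zeros_like(x0), 5, eps, sched),
        np.sqrt(1 - sched.alpha_bar_at(5)) * eps,
    )
    with pytest.raises(DiffusionError):
        forward_diffuse(x0, 5, eps[:3], sched)


def test_forward_step_mean_matches_scaling(sched, rng):
    """Sample mean of q(x_t | x_{t-1}) approaches sqrt(1-beta_t) x_{t-1}."""
    x_prev = 0.7
    t = 30
    draws = np.array([forward_step(x_prev, t, sched, rng) for _ in range(10_000)])
    expected = np.sqrt(1 - sched.beta[t]) * x_prev
    se = np.sqrt(sched.beta[t] / 10_000)
    assert abs(draws.mean() - expected) < 4 * se
    with pytest.raises(DiffusionError):
        forward_step(x_prev, 0, sched, rng)


def test_iterated_steps_match_one_shot_in_distribution(sched, rng):
    """Chaining single Markov steps to t reproduces the closed-form jump in
    mean and variance (scalar Monte Carlo, 10^4 trials)."""
    n, t_target, x0 = 10_000, 25, 0.5
    x = np.full(n, x0)
    for t in range(1, t_target + 1):
        x = np.sqrt(1 - sched.beta[t]) * x + np.sqrt(sched.beta[t]) * rng.standard_normal(n)
    ab = sched.alpha_bar_at(t_target)
    one_shot = np.sqrt(ab) * x0 + np.sqrt(1 - ab) * rng.standard_normal(n)
    se_mean = np.sqrt((1 - ab) / n)
    assert abs(x.mean() - one_shot.mean()) < 3 * np.sqrt(2) * se_mean
    assert abs(x.var() - one_shot.var()) < 3 * np.sqrt(2) * (1 - ab) * np.sqrt(2 / n)


# -- training loss ----------------------------------------------------------

def test_training_loss_zero_for_perfect_prediction(sched, rng):
    x0 = rng.standard_normal((8, 8))
    y0 = rng.standard_normal((8, 8))
    eps = rng.standard_normal((8, 8))
    assert training_loss(PerfectDenoiser(eps), x0, y0, 10, eps, sched) == 0.0


def test_training_loss_of_zero_predictor_is_unit_noise_power(sched, rng):
    eps = rng.standard_normal((64, 64))
    loss = training_loss(ZeroDenoiser(), np.zeros((64, 64)), np.zeros((64, 64)), 10, eps, sched)
    assert loss == pytest.approx(1.0, abs=4 * np.sqrt(2 / eps.size))


def test_training_loss_invariant_under_consistent_permutation(sched, rng):
    x0, y0, eps = (rng.standard_normal((4, 4)) for _ in range(3))
    perm = rng.permutation(16)

    class Linear:
        def predict(self, x_t, y0, t):
            return 0.5 * x_t + 0.1 * y0

    base = training_loss(Linear(), x0, y0, 7, eps, sched)
    p = lambda a: a.reshape(-1)[perm].reshape(4, 4)
    permuted = training_loss(Linear(), p(x0), p(y0), 7, p(eps), sched)
    assert permuted == pytest.approx(base, rel=1e-12)


# -- reverse process --------------------------------------------------------

def test_reverse_step_plugin_formulas(sched, rng):
    x_t = rng.standard_normal((5, 5))
    t = 20
    out = reverse_step(np.zeros_like(x_t), x_t, t, sched, None)
    np.testing.assert_allclose(out, x_t / np.sqrt(sched.alpha[t]))
    tiny = make_schedule("linear", 10, 1e-9, 1e-9)
    np.testing.assert_allclose(
        reverse_step(np.zeros_like(x_t), x_t, 5, tiny, None), x_t, atol=1e-7
    )
    with pytest.raises(DiffusionError):
        reverse_step(np.zeros_like(x_t), x_t, 1, sched, np.ones_like(x_t))


def test_reverse_step_contracts_oracle_residual(sched, rng, oracle_denoiser_factory):
    """With the exact-noise oracle the residual x_t - sqrt(ab_t) x0 shrinks
    by sqrt(alpha_t)(1-ab_{t-1})/(1-ab_t) per step and t=1 lands on x0."""
    x0 = rng.standard_normal((6, 6))
    oracle = oracle_denoiser_factory(x0, sched)
    t = 15
    x_t = forward_diffuse(x0, t, rng.standard_normal((6, 6)), sched)
    r_t = x_t - np.sqrt(sched.alpha_bar[t]) * x0
    x_prev = reverse_step(oracle.predict(x_t, None, t), x_t, t, sched, None)
    r_prev = x_prev - np.sqrt(sched.alpha_bar[t - 1]) * x0
    factor = np.sqrt(sched.alpha[t]) * (1 - sched.alpha_bar[t - 1]) / (1 - sched.alpha_bar[t])
    np.testing.assert_allclose(r_prev, factor * r_t, rtol=1e-9, atol=1e-12)

    x_1 = forward_diffuse(x0, 1, rng.standard_normal((6, 6)), sched)
    x_0 = reverse_step(oracle.predict(x_1, None, 1), x_1, 1, sched, None)
    np.testing.assert_allclose(x_0, x0, atol=1e-10)


def test_oracle_samplers_recover_target(sched, rng, oracle_denoiser_factory):
    x0 = rng.standard_normal((8, 8))
    oracle = oracle_denoiser_factory(x0, sched)
    out = sample_original(oracle, sched, (8, 8), rng, stochastic_z=False)
    np.testing.assert_allclose(out, x0, atol=1e-6)
    for t_con in (sched.T, 17, 1):
        cfg = SamplingConfig(t_con=t_con, stochastic_z=False)
        out = sample_noised_conditioned(oracle, rng.standard_normal((8, 8)), sched, cfg, rng)
        np.testing.assert_allclose(out, x0, atol=1e-6)


def test_noised_conditioned_degenerate_tcon_zero(sched, rng):
    y0 = rng.standard_normal((8, 8))
    cfg = SamplingConfig(t_con=0)
    out = sample_noised_conditioned(ZeroDenoiser(), y0, sched, cfg, rng)
    np.testing.assert_array_equal(out, y0)


def test_sampling_is_seed_deterministic(sched):
    y0 = np.random.default_rng(3).standard_normal((8, 8))
    cfg = SamplingConfig(t_con=20, stochastic_z=True)
    outs = [
        sample_noised_conditioned(ZeroDenoiser(), y0, sched, cfg, np.random.default_rng(11))
        for _ in range(2)
    ]
    np.testing.assert_array_equal(outs[0], outs[1])


def test_shared_noise_difference_scales_exactly(rng):
    """x_t - y_t = sqrt(alpha_bar_t)(x0 - y0) when the same eps noises both."""
    for kind in ("linear", "cosine", "sigmoid"):
        s = make_schedule(kind, 100, 1e-4, 0.05)
        x0, y0 = rng.standard_normal((7, 7)), rng.standard_normal((7, 7))
        eps = rng.standard_normal((7, 7))
        for t in (0, 1, 50, 100):
            diff = forward_diffuse(x0, t, eps, s) - forward_diffuse(y0, t, eps, s)
            np.testing.assert_allclose(
                diff, np.sqrt(s.alpha_bar_at(t)) * (x0 - y0), rtol=1e-9, atol=1e-12
            )


# -- training loop ----------------------------------------------------------

def test_loss_history_band_assignment():
    h = LossHistory(T=1000, n_bands=10)
    assert h.band_of(950) == 10
    assert h.band_of(1) == 1
    assert h.band_of(100) == 1
    assert h.band_of(101) == 2


def test_train_rejects_empty_dataset(sched, rng):
    from cbctdiff.nn import Denoiser, DenoiserConfig

    net = Denoiser(DenoiserConfig(depth=2, base_width=4, blocks_per_level=1), rng)
    with pytest.raises(DiffusionError):
        train(net, [], sched, TimestepDistribution("uniform", sched.T),
              TrainConfig(steps=1), rng)


def test_overfit_single_pair_drives_high_t_loss_down(rng):
    """Scaled-down sanity run: on one pair, high-timestep loss falls well
    below its starting level within a few hundred steps."""
    from cbctdiff.nn import Denoiser, DenoiserConfig

    sched = make_schedule("cosine", 100, 1e-4, 0.02)
    net = Denoiser(
        DenoiserConfig(depth=2, base_width=8, blocks_per_level=1, time_embedding_dim=16),
        rng,
    )
    x0 = np.tanh(rng.standard_normal((16, 16)))
    y0 = np.tanh(rng.standard_normal((16, 16)))
    hist = train(
        net, [(x0, y0)], sched, TimestepDistribution("uniform", 100),
        TrainConfig(steps=400, batch_size=4, lr=2e-3), rng,
    )
    df = hist.to_dataframe()
    high = df[df["band"] >= 9]
    early = high[high["step"] < 40]["loss"].mean()
    late = high[high["step"] >= 360]["loss"].mean()
    assert late < 0.1 * max(early, 1.0)
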