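"""Sampler-level checks: diagnostics, summaries, prior recovery, determinism."""

import numpy as np
import pytest

from fishssm.behaviour import CovariateSeries
from fishssm.fixtures import Scenario, make_dataset, make_receiver_grid
from fishssm.inference import (
    MCMCConfig,
    PosteriorSamples,
    Priors,
    gelman_rubin,
    home_range_area,
    run_mcmc,
    summarize,
)
from fishssm.movement import MovementParams
from fishssm.observation import DetectionParams


def _samples(draws):
    draws = np.asarray(draws, float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    return PosteriorSamples(
        draws=draws,
        param_names=tuple(f"p{i}" for i in range(draws.shape[2])),
        log_density=np.zeros(draws.shape[:2]),
    )


class TestGelmanRubin:
    def test_shifted_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 2000), rng.normal(100, 1, 2000)])
        rhat = gelman_rubin(_samples(chains)).iloc[0]
        assert rhat > 5.0

    def test_well_mixed_chains_near_one(self, rng):
        chains = rng.normal(0, 1, (3, 10_000))
        rhat = gelman_rubin(_samples(chains)).iloc[0]
        assert rhat == pytest.approx(1.0, abs=0.01)

    def test_zero_between_chain_variance_at_most_one(self, rng):
        one = rng.normal(0, 1, 500)
        rhat = gelman_rubin(_samples(np.stack([one, one]))).iloc[0]
        assert rhat <= 1.0

    def test_constant_identical_chains_give_one(self):
        rhat = gelman_rubin(_samples(np.full((3, 100), 7.0))).iloc[0]
        assert rhat == 1.0

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(_samples(rng.normal(0, 1, (1, 100))))

    def test_agrees_with_arviz_on_well_mixed_chains(self, rng):
        arviz = pytest.importorskip("arviz")
        chains = rng.normal(0, 1, (4, 5000))
        ours = gelman_rubin(_samples(chains)).iloc[0]
        theirs = float(arviz.rhat(arviz.convert_to_dataset(chains))["x"].values)
        assert ours == pytest.approx(theirs, abs=0.05)


class TestSummarize:
    def test_constant_samples_zero_width(self):
        out = summarize(_samples(np.full((2, 100), 3.5)))
        assert out.loc["p0", "lower"] == out.loc["p0", "upper"] == 3.5

    def test_standard_normal_interval(self, rng):
        out = summarize(_samples(rng.normal(0, 1, (3, 20_000))), level=0.95)
        assert out.loc["p0", "lower"] == pytest.approx(-1.96, abs=0.05)
        assert out.loc["p0", "upper"] == pytest.approx(1.96, abs=0.05)

    def test_mean_inside_interval(self, rng):
        out = summarize(_samples(rng.gamma(2.0, 1.0, (2, 5000))))
        row = out.loc["p0"]
        assert row.lower <= row["mean"] <= row.upper


class TestHomeRangeArea:
    def test_study_mean_radius_rounds_to_002(self):
        assert round(home_range_area(84.25), 2) == 0.02

    def test_zero_radius(self):
        assert home_range_area(0.0) == 0.0

    def test_one_square_km_radius(self):
        assert home_range_area(564.19) == pytest.approx(1.0, abs=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            home_range_area(-1.0)


def _small_dataset(seed=0, n_steps=80):
    scenario = Scenario(
        name="custom",
        movement=MovementParams(0.0, 0.0, 0.001, 100.0),
        transition=__import__("fishssm.behaviour", fromlist=["TransitionParams"]).TransitionParams.from_probs(
            {f"{w}_{c}": 0.8 for w in "pq" for c in ("day_noise", "day_silence", "night_noise", "night_silence")}
        ),
        detection=DetectionParams(150.0, -0.02),
        n_steps=n_steps,
        seed=seed,
    )
    receivers = make_receiver_grid(9, 150.0)
    return make_dataset(scenario, receivers), receivers


class TestRunMcmc:
    def test_same_seed_identical_draws(self):
        data, receivers = _small_dataset()
        cfg = MCMCConfig(n_chains=2, n_keep=20, burn_in=30, thin=1, seed=11)
        a = run_mcmc(data.detections, data.covariates, receivers, config=cfg)
        b = run_mcmc(data.detections, data.covariates, receivers, config=cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_prior_only_recovers_radius_prior_mean(self):
        # zero-information run: the posterior is the prior, so the radius
        # draws must reproduce the U(50, 1000) mean of 525 m
        data, receivers = _small_dataset(seed=3)
        cfg = MCMCConfig(n_chains=3, n_keep=2000, burn_in=50, thin=1, seed=21)
        samples = run_mcmc(
            data.detections, data.covariates, receivers, config=cfg, prior_only=True
        )
        radius = samples.draws[:, :, list(samples.param_names).index("radius")]
        assert radius.mean() == pytest.approx(525.0, rel=0.03)

    def test_prior_only_recovers_truncated_k_prior(self):
        # k is gamma(0.1, 0.1) truncated to the stable region k*dt < 1;
        # oracle moments by numerical integration of the truncated density
        from scipy import integrate, stats

        data, receivers = _small_dataset(seed=4)
        cfg = MCMCConfig(n_chains=3, n_keep=2000, burn_in=50, thin=1, seed=22)
        samples = run_mcmc(
            data.detections, data.covariates, receivers, config=cfg, prior_only=True
        )
        k = samples.draws[:, :, list(samples.param_names).index("k")]
        kmax = 1.0 / 720.0
        z = stats.gamma.cdf(kmax, 0.1, scale=0.1)
        mean, _ = integrate.quad(
            lambda x: x * stats.gamma.pdf(x, 0.1, scale=0.1) / z, 0, kmax
        )
        assert k.mean() == pytest.approx(mean, rel=0.1)
        assert k.max() < kmax

    def test_too_few_receivers_rejected(self):
        data, _ = _small_dataset()
        from fishssm.observation import DetectionSeries, ReceiverArray

        one = ReceiverArray(ids=("a",), coords=[[0.0, 0.0]])
        with pytest.raises(ValueError):
            run_mcmc(
                DetectionSeries(counts=data.detections.counts[:, :1]),
                data.covariates,
                one,
            )

    def test_too_few_steps_rejected(self):
        data, receivers = _small_dataset()
        from fishssm.observation import DetectionSeries

        short = DetectionSeries(counts=data.detections.counts[:30])
        covs = CovariateSeries(
            daylight=data.covariates.daylight[:30], noise=data.covariates.noise[:30]
        )
        with pytest.raises(ValueError):
            run_mcmc(short, covs, receivers)

    def test_draw_shapes_and_names(self):
        data, receivers = _small_dataset()
        cfg = MCMCConfig(n_chains=2, n_keep=15, burn_in=20, thin=1, seed=9)
        samples = run_mcmc(data.detections, data.covariates, receivers, config=cfg)
        assert samples.draws.shape == (2, 15, 14)
        assert "p_day_noise" in samples.param_names
        assert np.all(np.isfinite(samples.log_density))
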