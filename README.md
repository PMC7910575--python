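# fishssm

A state-space model (SSM) for resident marine fish tracked by acoustic
telemetry, with an explicit motorboat-noise covariate. The package is for
movement ecologists who want to ask, from raw receiver detection logs and
passive-acoustic recordings, whether passing boats change the probability
that a fish keeps swimming or hides — while treating the large
observation error of telemetry honestly.

## The model

A fish switches between two behavioural states on a 12-min grid:

- **Swimming** — a biased random walk attracted to the home-range centre
  `r_HR`: per axis, `x[n] = x[n-1] + k·dt·(hr_x − x[n-1]) + ε`,
  `ε ~ N(0, v)`, with `v` calibrated so that `radius` is the 95% quantile
  of the stationary distance to the centre.
- **Hidden** — the fish shelters and keeps its previous position exactly.

Switching follows a 2×2 transition matrix `T = [[p, 1−p], [1−q, q]]`
(`p` = stay swimming, `q` = stay hidden), with one matrix per combination
of two binary covariates — daylight and motorboat-noise presence — so 8
free probabilities per fish. The fish is observed only through per-step,
per-receiver detection counts: `ND ~ Binomial(6, expit(slope·(d − d50)))`,
a decreasing logistic in the fish–receiver distance `d`. The noise
covariate comes from hydrophone WAVs: per-second sound pressure level
(SPL, dB re 1 µPa), thresholded at 1.8× the basal ambient mean-square
level (+2.55 dB), collapsed to 12-min flags.

All parameters — centre, `k`, `radius`, the 8 transition probabilities,
`d50`, `slope` — and the latent track are estimated jointly by
Metropolis-within-Gibbs MCMC (3 chains, Gelman-Rubin convergence
diagnostics, equal-tailed 95% credibility intervals). See
`docs/methods.md` for assumptions, priors, sampler design and
limitations.

## Worked example

Simulate a synthetic fish on the study geometry (14 receivers, 150 m
grid), then fit it back:

```python
import numpy as np
from fishssm import MovementParams, DetectionParams, MCMCConfig, run_mcmc, summarize
from fishssm.behaviour import TransitionParams
from fishssm.fixtures import Scenario, make_dataset, make_receiver_grid

grid = make_receiver_grid(14, 150.0)
scenario = Scenario(
    name="custom",
    movement=MovementParams(hr_x=30.0, hr_y=-20.0, k=0.001, radius=100.0),
    transition=TransitionParams.from_probs({
        "p_day_noise": 0.95, "q_day_noise": 0.85,
        "p_day_silence": 0.95, "q_day_silence": 0.85,
        "p_night_noise": 0.75, "q_night_noise": 0.95,
        "p_night_silence": 0.75, "q_night_silence": 0.95,
    }),
    detection=DetectionParams(d50=150.0, slope=-0.02),
    n_steps=1000, seed=101,
)
data = make_dataset(scenario, grid)
samples = run_mcmc(
    data.detections, data.covariates, grid,
    config=MCMCConfig(n_chains=3, n_keep=500, burn_in=800, thin=4, seed=1),
)
print(summarize(samples).round(3))
```

prints (abridged):

```
                    mean    lower    upper   rhat
hr_x              30.284   24.358   36.353  1.014
hr_y             -16.814  -22.437  -11.414  1.002
k                  0.001    0.001    0.001  1.026
radius           105.420   98.208  112.215  1.000
p_day_silence      0.962    0.932    0.983  1.019
q_day_silence      0.905    0.850    0.950  1.002
p_night_silence    0.793    0.690    0.877  1.003
q_night_silence    0.953    0.924    0.975  1.003
d50              150.261  149.257  151.274  1.006
slope             -0.020   -0.020   -0.020  1.000
```

The centre (true 30, −20), home-range radius (true 100 m), detection
curve (true d50 = 150 m, slope = −0.02) and the day/night stay
probabilities are recovered with truth inside the 95% intervals, and
every R-hat is below 1.1; `π·radius²` gives the home-range area
(`home_range_area(84.25) → 0.02 km²` for the field-typical radius).
Noise-cell probabilities (not shown) are much wider: at the
field-realistic boat-pass rate (~8.5% of steps) those cells hold little
data, which is exactly the posterior behaviour one should expect.

The same pipeline is scriptable from the shell:

```sh
fishssm simulate --outdir sim --seed 7
fishssm noise-detect rec.wav --start 2017-07-24T00:00:00Z \
        --config config.yml --outdir noise
fishssm fit --detections sim/detections.csv --covariates sim/covariates.csv \
        --receivers sim/receivers.csv --outdir fit        # exit 1 if R-hat >= 1.1
fishssm recover --outdir recovery --seed 3                # truth-vs-BCI report
```

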