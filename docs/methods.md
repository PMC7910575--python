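# Methods

## The model

`fishssm` models a resident fish that alternates between two behavioural
states on a fixed 12-min time grid (`dt` = 720 s, set by the duty cycle of
the co-deployed sound recorder):

- **Swimming (state 1).** A biased random walk (BRW) attracted to the
  home-range centre `r_HR = (hr_x, hr_y)`. Per axis the step is the AR(1)
  update

      x[n] = x[n-1] + k*dt*(hr_x - x[n-1]) + eps,   eps ~ N(0, v),

  with attraction strength `k` (per second) and home-range radius
  `radius` (metres).

- **Hidden (state 2).** The fish shelters and keeps its previous position
  exactly (a point mass at `r[n-1]`).

State switching is Markov with the 2x2 row-stochastic matrix
`T = [[p, 1-p], [1-q, q]]`, where `p` is the probability of continuing to
swim and `q` of remaining hidden. Two binary covariates — daylight and
presence of a motorboat-noise peak in the step — select one of four
matrices, giving 8 free probabilities per fish. The transition applied
from step n-1 to n uses the covariates observed at step n. A logit-linear
link (`logit(p) = b1 + b2*V`) is provided as the continuous-covariate
extension but is not used by the default fitter.

The fish is observed only through counts of decoded tag transmissions:
each of the `emissions_per_step` transmissions (default 6: one per 120 s
within a 720 s step) is decoded by receiver j independently with
probability `expit(slope*(d - d50))`, a decreasing logistic in the
fish-receiver distance `d`; counts are Binomial. `d50` is the inflection
distance (50% detection) and `slope < 0` the steepness. Detections are
conditionally independent across receivers and steps given the position,
and a hidden fish is assumed exactly as detectable as a swimming one.

## Radius calibration of the BRW innovation

The innovation variance is calibrated so that `radius` has an exact
operational meaning: it is the 95% quantile of the stationary distance to
the home-range centre while swimming. The squared distance is the sum of
two squared independent Gaussian axes, so

    v = radius^2 / chi2_95(2 df) * (1 - (1 - k*dt)^2),
    chi2_95(2 df) ~ 5.991,

which makes the per-axis stationary variance exactly
`radius^2 / 5.991` for every stable `k*dt`, and reduces to the
continuous-time Ornstein-Uhlenbeck diffusion rate
`2*k*radius^2/5.991 * dt` as `k*dt -> 0`. (Calibrating the innovation as
`sigma^2*dt` alone inflates the stationary spread by
`2*k*dt/(1-(1-k*dt)^2)`, 56% at `k*dt = 0.72`, and would break the
quantile interpretation at the attraction strengths typical of resident
fish.) The factor `1-(1-k*dt)^2` is computed as `k*dt*(2-k*dt)` to avoid
catastrophic cancellation at very small `k`. Updates with `k*dt >= 1` are
rejected (`StabilityError`): the Euler-type discretization diverges there.

A consequence worth noting: as `k -> 0` the innovation variance vanishes
(the home range is held at `radius`), so there is no free-diffusion limit;
the locally diffusive regime `k*dt << 1` is where mean squared
displacement grows linearly over short horizons.

## Noise pipeline

Hydrophone WAV (PCM16, 44.1 kHz) is converted to pressure in uPa via

    p = raw/32768 * full_scale_volts / 10^((sensitivity_dB + gain_dB)/20)

with no default sensitivity (a missing calibration is an error, never a
silent assumption). Per 1-s non-overlapping segment the pipeline computes
the power spectral density (rectangular window, so Parseval holds exactly:
integrated linear PSD = mean squared pressure) and the sound pressure
level `SPL = 10*log10(mean(p^2)/1 uPa^2)`.

A segment contains a boat pass when its mean squared pressure is at least
`factor` (default 1.8) times the basal ambient level; on the dB scale this
is a fixed offset of `10*log10(1.8) ~ 2.55 dB`. Because the original
threshold scale is ambiguous, a dB-multiplicative comparison
(`SPL >= factor * basal_SPL`) is available but not the default. The basal
level estimator is deliberately simple and robust: the 0.25 quantile of
per-segment SPL (the median of the quietest half), with a manual override
in the configuration; it is insensitive to boat passes occupying a
minority of the record and requires at least 60 segments. A 12-min step is
flagged noisy when any contained segment is flagged.

## Priors

- `logit(p)`, `logit(q)`: normal(0, 10) truncated to (-20, 20) — nearly
  flat over (0,1) in the logit metric, but note it is bathtub-shaped on
  the probability scale, concentrating mass near 0 and 1 when data are
  scarce.
- `radius ~ U(50, 1000)` m; `k ~ gamma(shape 0.1, scale 0.1)` per second,
  restricted to the stable region `k*dt < 1` (about 30% of the
  unrestricted gamma mass lies beyond it at dt = 720 s; the truncation
  constant is omitted from the joint density, which leaves every
  Metropolis ratio unchanged).
- Home-range centre: uniform on a 1000 m disc around the
  detection-weighted receiver centroid.
- `d50 ~ U(-1000, 200)` m (negative inflection points are legitimate for
  receivers that miss close transmissions); `log(-slope) ~ N(log 0.02, 1)`,
  weakly informative around the ~300 m observed detection range. The slope
  prior is the package's choice; none was stated for it in the source
  analyses we follow.
- Initial latent position: Gaussian at the stationary scale around the
  centre; initial state uniform on {swimming, hidden}.

## Sampler

All parameters and the latent track (positions and states) are sampled by
Metropolis-within-Gibbs. Per sweep:

1. **Joint (state, position) flips** at each interior step, in an even/odd
   checkerboard (same-colour sites are conditionally independent given
   their neighbours). A hidden-to-swimming proposal draws the freed
   position from the BRW transition density, which cancels exactly in the
   Metropolis ratio; swimming-to-hidden pins the position to its
   predecessor. Flips that would break a downstream hidden step's equality
   constraint have zero target density and reject automatically.
2. **Block shifts**: maximal constant-position blocks (a free position
   plus the hidden run copying it) receive a joint random-walk shift,
   even/odd coloured over blocks.
3. **Hidden-run left-edge moves.** Single-site flips can only create runs
   and move their right boundary, so the left edge of a run of length >= 2
   would otherwise freeze. Per run (even/odd coloured, skipping runs that
   touch step 0), with probability 1/2 each: the preceding swimming step
   joins the run, or the first hidden step leaves it with a fresh position
   drawn from the BRW density (cancelling in the ratio). Moves that would
   merge two runs are excluded here to keep the pairing reversible;
   merging is handled by the dedicated move below.
4. **Split/merge toggles** at randomly drawn sites whose predecessor is
   hidden, processed sequentially: a hidden site leaves its run (split —
   fresh position from the BRW density, the downstream remainder of the
   run re-pins to it), a swimming site joins the preceding run (merge —
   its constant block re-pins to the predecessor). The two toggles are
   exact reverses at the same site, so no selection-probability
   corrections arise. These moves change the *number* of hidden runs — the
   sufficient statistic of the stay probabilities — whose quenching into
   few long runs is otherwise a serious mixing trap (chains freeze at
   different run counts and the day-time `p` drifts towards 1).
5. **Transition logits + states, blocked.** Each of the 8 logits is
   sampled against the *state-marginalized* likelihood of the position
   path (the forward algorithm over the two-state chain given positions,
   numba-compiled), with two random-walk steps (per-logit adaptive
   scales — data-poor cells need order-of-magnitude larger steps) and two
   independence refreshes from the truncated-normal prior, which cross
   the wide bathtub-shaped posterior of data-poor cells quickly. The
   state path is then redrawn exactly by forward-filter backward-sampling
   (FFBS), completing a partially collapsed Gibbs block. Updating the
   logits against realized transition counts instead creates a strong
   positive feedback — few observed switches push `p` up, which
   suppresses switch creation — that mixes pathologically slowly and can
   pin chains at `p ~ 1`.
6. **Other parameters**: random-walk MH on transformed scales (log k, raw
   radius, 2-D centre, d50, log(-slope)); the movement parameters only
   re-evaluate the movement factors, the detection parameters only the
   detection factors.
7. **Prior-ancestral move** (probability 0.05): propose every parameter
   from its prior and the latents from the generative model; the ratio
   reduces to the detection-likelihood ratio. With the likelihood disabled
   (`prior_only=True`) this move is the whole sweep and always accepts, so
   a data-free run yields iid prior draws — the exact posterior for
   zero-information data, and the sanity check that the prior samplers and
   the k truncation are right.

Proposal scales adapt by Robbins-Monro (decaying gain) during burn-in
only; the kernel is fixed afterwards. Burn-in is staged: transition
logits are held at their starting values for the first third so the
latent state path can equilibrate against the data first (FFBS keeps
running throughout). Three chains are run from overdispersed
starts (centre, k, radius, logits, detection curve all jittered); default
chain settings are 1000 burn-in sweeps, thinning 10, and 10,000 kept
draws per chain, with convergence declared when every parameter's classic
Gelman-Rubin PSRF is below 1.1. Summaries are pooled-chain means with
equal-tailed 95% credibility intervals (the level is configurable).

## What the synthetic generator emulates

Defaults are the study conditions: 12-min steps, 6 emissions per step, a
14-receiver grid at 150 m pitch, `d50 = 150` m with a ~300 m detection
range, day/night in 12-h blocks, and motorboat-noise peaks on 8.5% of
steps (the observed 79-in-924 rate of boat passes in inspected 1-min
recordings). Named scenarios (shy `p=0.2/q=0.95`, intermediate `0.5/0.5`,
bold `0.95/0.2`) encode the qualitative regimes used for illustration;
they are not field estimates. Boat bursts in synthetic WAVs are 50 Hz -
10 kHz band-limited noise with the stated *total* excess over basal; the
spectral shape of real passes, tag collisions and transmission jitter are
not emulated, so passing tests say nothing about those aspects of real
data.

## Identifiability and the recovery experiment

The per-step evidence separating "hidden" from "a short swimming step" is
the ratio of the BRW density at zero displacement to the point mass,
attenuated by position uncertainty (roughly 15-20 m under the study
geometry versus a ~39 m swimming step scale). That evidence is a few nats
per step at most, so mid-range stay probabilities are only weakly
identified, and the bathtub-shaped logit prior pulls the posterior towards
extreme probabilities — a property the field fits of this model family
share (state persistence is reported close to 1 for all individuals). The
built-in recovery experiment therefore places its ground truth in the
stay-heavy regime consistent with those fits (day `p=0.95/q=0.85`, night
`p=0.75/q=0.95`): coverage there measures calibration of the posterior
where the posterior can in fact concentrate. With 1000 steps, 95% BCIs
cover about 90% of the 12 scalar parameters across seeds; the parameter
most often missed is a day-time stay probability, whose short hidden
runs the position noise fragments slightly.

Movement parameters are recovered well, with the caveat that `k` is
weakly identified: even given the true track, the log-likelihood profile
over `k` is flat within a few nats across +/-30% at 1000 steps.

## Numerical and design choices

- Detection log-likelihoods use `log(expit)` via `-log1p(exp(-x))`
  (`-logaddexp(0, -x)`) for stability at extreme distances.
- The classic PSRF is used (between/within variance ratio, no rank
  normalization or chain splitting): degenerate cases are defined as
  R-hat = 1 for identical constant chains and +inf for constant but
  different chains.
- `bin_detections` uses half-open bins aligned to a caller-supplied
  origin (the recorder duty-cycle start in the field setting); day/night
  classification is sunrise-inclusive, sunset-exclusive.
- Ties at the noise threshold flag the segment (>= comparison).
- Chain lengths for the desk-scale experiments are the package's
  reduced-length settings for a single individual: the reference fit uses
  3 chains x (1500 burn-in, 900 kept, thinning 6) so the convergence
  diagnostic is measured with adequate effective sample size, and the
  replicate fits used only for interval coverage use 3 x (800, 500,
  thinning 4). The full-length defaults mirror the original chain
  configuration (1000 burn-in, 10,000 kept, thinning 10).
- Home-range area is reported as `pi*radius^2*1e-6` km^2.

## Known limitations

- One individual per fit; no hierarchical pooling across fish.
- Continuous latent positions with single-site and block moves; a
  particle or forward-backward scheme over discretized positions would
  mix faster for very long hidden runs.
- The binomial index per step is fixed (default 6); real tags jitter
  their emission schedule, and collisions between tags are not modelled.
- Detection probability is time-invariant; sentinel-tag style
  time-varying detection is out of scope.
- The noise detector is a level threshold: any non-boat broadband event
  exceeding 1.8x basal (heavy rain, chain noise) would be flagged too.
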