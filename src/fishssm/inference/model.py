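"""Joint density of the state-space model and the forward state recursion.

The joint density factorizes along the directed graph: priors on the
parameters; an initial-position Gaussian at the stationary scale and a
uniform initial state; Markov transition factors selected by the step's
covariates; movement factors (the calibrated BRW density while swimming, a
point mass on the previous position while hidden); and independent binomial
detection likelihoods per receiver per step.

Densities are taken with respect to the natural mixed dominating measure:
Lebesgue in position for swimming steps, counting measure at the previous
position for hidden steps.  Any support violation yields -inf rather than
an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.special import gammaln

from ..behaviour import CovariateSeries, TransitionParams, select_matrix
from ..movement import BehaviourState, MovementParams, Track, swim_logpdf
from ..observation import DetectionParams, DetectionSeries, ReceiverArray

__all__ = [
    "PARAM_NAMES",
    "Priors",
    "detection_weighted_centroid",
    "log_prior",
    "joint_log_density",
    "forward_state_loglik",
    "binomial_loglik",
]

#: Canonical ordering of the sampled scalar parameters.
PARAM_NAMES = (
    "hr_x",
    "hr_y",
    "k",
    "radius",
    "p_day_noise",
    "q_day_noise",
    "p_day_silence",
    "q_day_silence",
    "p_night_noise",
    "q_night_noise",
    "p_night_silence",
    "q_night_silence",
    "d50",
    "slope",
)


@dataclass(frozen=True)
class Priors:
    """Prior distributions for all sampled parameters.

    - logit(p), logit(q): normal(mean, sd) truncated to (-bound, bound) —
      with the default sd 10 and bound 20 this is close to flat on (0, 1).
    - radius ~ U(radius_low, radius_high) metres.
    - k ~ gamma(k_shape, scale=k_scale) per second, restricted to the
      stable region k*dt < 1 (the truncation constant is omitted from the
      density — it cancels in MH ratios).
    - home-range centre uniform on a disc of centre_radius metres around
      (centre_x, centre_y), normally the detection-weighted receiver
      centroid.
    - d50 ~ U(d50_low, d50_high) metres (the inflection point may be
      negative for receivers that miss close transmissions).
    - log(-slope) ~ normal(log_neg_slope_mean, log_neg_slope_sd): weakly
      informative around the ~300 m observed detection range.
    """

    logit_mean: float = 0.0
    logit_sd: float = 10.0
    logit_bound: float = 20.0
    radius_low: float = 50.0
    radius_high: float = 1000.0
    k_shape: float = 0.1
    k_scale: float = 0.1
    d50_low: float = -1000.0
    d50_high: float = 200.0
    log_neg_slope_mean: float = float(np.log(0.02))
    log_neg_slope_sd: float = 1.0
    centre_x: float = 0.0
    centre_y: float = 0.0
    centre_radius: float = 1000.0

    def with_centre(self, x: float, y: float) -> "Priors":
        return replace(self, centre_x=float(x), centre_y=float(y))

    def logit_logpdf(self, value: float) -> float:
        a = (-self.logit_bound - self.logit_mean) / self.logit_sd
        b = (self.logit_bound - self.logit_mean) / self.logit_sd
        return float(
            stats.truncnorm.logpdf(
                value, a, b, loc=self.logit_mean, scale=self.logit_sd
            )
        )


def detection_weighted_centroid(
    detections: DetectionSeries, receivers: ReceiverArray
) -> np.ndarray:
    """Receiver centroid weighted by total detections (the prior centre)."""
    w = detections.counts.sum(axis=0).astype(float)
    if w.sum() <= 0:
        return receivers.coords.mean(axis=0)
    return (receivers.coords * w[:, None]).sum(axis=0) / w.sum()


def log_prior(
    movement: MovementParams,
    transition: TransitionParams,
    detection: DetectionParams,
    priors: Priors,
) -> float:
    """Log prior density of all scalar parameters; -inf outside support."""
    lp = 0.0
    # Home-range centre: uniform disc.
    dx = movement.hr_x - priors.centre_x
    dy = movement.hr_y - priors.centre_y
    if dx * dx + dy * dy > priors.centre_radius**2:
        return -np.inf
    lp += -np.log(np.pi * priors.centre_radius**2)
    # k: gamma, restricted to the stable region.
    if movement.k <= 0 or movement.k * movement.dt >= 1.0:
        return -np.inf
    lp += float(stats.gamma.logpdf(movement.k, priors.k_shape, scale=priors.k_scale))
    # radius: uniform.
    if not priors.radius_low <= movement.radius <= priors.radius_high:
        return -np.inf
    lp += -np.log(priors.radius_high - priors.radius_low)
    # Transition probabilities: truncated normal on the logit scale.
    for prob in transition.to_probs().values():
        if not 0.0 < prob < 1.0:
            return -np.inf
        l = np.log(prob) - np.log1p(-prob)
        if abs(l) >= priors.logit_bound:
            return -np.inf
        lp += priors.logit_logpdf(l)
    # d50: uniform.
    if not priors.d50_low <= detection.d50 <= priors.d50_high:
        return -np.inf
    lp += -np.log(priors.d50_high - priors.d50_low)
    # slope: lognormal on -slope (density with respect to slope).
    if detection.slope >= 0:
        return -np.inf
    ls = np.log(-detection.slope)
    lp += float(
        stats.norm.logpdf(ls, priors.log_neg_slope_mean, priors.log_neg_slope_sd)
    ) - ls
    return float(lp)


def binomial_loglik(
    positions: np.ndarray,
    counts: np.ndarray,
    receivers: ReceiverArray,
    detection: DetectionParams,
) -> float:
    """Binomial detection log-likelihood summed over steps and receivers."""
    positions = np.atleast_2d(np.asarray(positions, float))
    counts = np.atleast_2d(np.asarray(counts, int))
    m = detection.emissions_per_step
    if np.any(counts > m):
        return -np.inf
    d = np.linalg.norm(positions[:, None, :] - receivers.coords[None, :, :], axis=-1)
    eta = detection.slope * (d - detection.d50)
    log_pd = -np.logaddexp(0.0, -eta)
    log_1mpd = -np.logaddexp(0.0, eta)
    const = gammaln(m + 1) - gammaln(counts + 1) - gammaln(m - counts + 1)
    return float(np.sum(const + counts * log_pd + (m - counts) * log_1mpd))


def _initial_logpdf(pos0: np.ndarray, movement: MovementParams) -> float:
    """Initial position at the stationary scale around the centre; uniform state."""
    sv = movement.stationary_var
    sq = float(np.sum((pos0 - movement.centre) ** 2))
    return -np.log(2.0 * np.pi * sv) - sq / (2.0 * sv) + np.log(0.5)


def joint_log_density(
    track: Track,
    movement: MovementParams,
    transition: TransitionParams,
    detection: DetectionParams,
    detections: DetectionSeries,
    covariates: CovariateSeries,
    receivers: ReceiverArray,
    priors: Priors,
) -> float:
    """Log of prior x latent-process density x detection likelihood."""
    n = len(track)
    if detections.counts.shape[0] != n or len(covariates) != n:
        raise ValueError("track, detections and covariates must share the step grid")
    lp = log_prior(movement, transition, detection, priors)
    if not np.isfinite(lp):
        return -np.inf
    if movement.k * movement.dt >= 1.0:
        return -np.inf

    lp += _initial_logpdf(track.positions[0], movement)

    pos = track.positions
    st = track.states
    for i in range(1, n):
        mat = select_matrix(
            transition, covariates.daylight[i], covariates.noise[i]
        ).as_array()
        t = mat[st[i - 1] - 1, st[i] - 1]
        if t <= 0.0:
            return -np.inf
        lp += np.log(t)
        if st[i] == BehaviourState.HIDDEN:
            if not np.array_equal(pos[i], pos[i - 1]):
                return -np.inf
        else:
            lp += float(swim_logpdf(pos[i - 1], pos[i], movement))

    lp += binomial_loglik(pos, detections.counts, receivers, detection)
    return float(lp)


def forward_state_loglik(
    positions: np.ndarray,
    movement: MovementParams,
    transition: TransitionParams,
    covariates: CovariateSeries,
    init_probs=(0.5, 0.5),
) -> float:
    """Log-probability of a position sequence, states marginalized out.

    The forward recursion sums over all 2**N behavioural-state sequences:
    a HIDDEN step emits an indicator of zero displacement, a SWIMMING step
    emits the BRW transition density.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    n = positions.shape[0]
    if len(covariates) != n:
        raise ValueError("covariates must match the position sequence length")
    with np.errstate(divide="ignore"):
        log_alpha = np.log(np.asarray(init_probs, float))
    for i in range(1, n):
        mat = select_matrix(
            transition, covariates.daylight[i], covariates.noise[i]
        ).as_array()
        with np.errstate(divide="ignore"):
            log_t = np.log(mat)
        same = np.array_equal(positions[i], positions[i - 1])
        log_emit = np.array(
            [
                float(swim_logpdf(positions[i - 1], positions[i], movement)),
                0.0 if same else -np.inf,
            ]
        )
        log_alpha = (
            np.logaddexp.reduce(log_alpha[:, None] + log_t, axis=0) + log_emit
        )
    return float(np.logaddexp.reduce(log_alpha))
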