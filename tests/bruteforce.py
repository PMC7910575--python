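"""Independent brute-force oracles for the SSM densities.

These deliberately avoid the package's forward recursion and density
bookkeeping: state sequences are enumerated exhaustively and every factor
is recomputed from scipy primitives, so agreement is a genuine two-route
check.
"""

from itertools import product

import numpy as np
from scipy import stats


def _movement_var(movement):
    chi2_95 = stats.chi2.ppf(0.95, 2)
    stat_var = movement.radius**2 / chi2_95
    a = 1.0 - movement.k * movement.dt
    return stat_var, stat_var * (1.0 - a * a)


def _swim_logpdf(prev, cur, movement):
    _, v = _movement_var(movement)
    mean = prev + movement.k * movement.dt * (np.array([movement.hr_x, movement.hr_y]) - prev)
    return stats.norm.logpdf(cur, loc=mean, scale=np.sqrt(v)).sum()


def enumerate_state_loglik(positions, movement, transition, covariates, init=(0.5, 0.5)):
    """Sum the position density over all 2**N behavioural-state sequences."""
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    total = -np.inf
    for states in product((1, 2), repeat=n):
        lp = np.log(init[states[0] - 1])
        for i in range(1, n):
            mat = transition.matrices[
                (int(covariates.daylight[i]), int(covariates.noise[i]))
            ].as_array()
            t = mat[states[i - 1] - 1, states[i] - 1]
            if t == 0.0:
                lp = -np.inf
                break
            lp += np.log(t)
            if states[i] == 2:
                if not np.array_equal(positions[i], positions[i - 1]):
                    lp = -np.inf
                    break
            else:
                lp += _swim_logpdf(positions[i - 1], positions[i], movement)
        total = np.logaddexp(total, lp)
    return total


def joint_logdensity_oracle(
    track, movement, transition, detection, detections, covariates, receivers, priors
):
    """Recompute the joint log density factor by factor with scipy."""
    lp = 0.0
    # priors
    d = np.hypot(movement.hr_x - priors.centre_x, movement.hr_y - priors.centre_y)
    if d > priors.centre_radius:
        return -np.inf
    lp += np.log(1.0 / (np.pi * priors.centre_radius**2))
    if movement.k <= 0 or movement.k * movement.dt >= 1:
        return -np.inf
    lp += stats.gamma.logpdf(movement.k, priors.k_shape, scale=priors.k_scale)
    if not priors.radius_low <= movement.radius <= priors.radius_high:
        return -np.inf
    lp += -np.log(priors.radius_high - priors.radius_low)
    a = (-priors.logit_bound - priors.logit_mean) / priors.logit_sd
    b = (priors.logit_bound - priors.logit_mean) / priors.logit_sd
    for prob in transition.to_probs().values():
        l = np.log(prob / (1 - prob))
        if abs(l) >= priors.logit_bound:
            return -np.inf
        lp += stats.truncnorm.logpdf(l, a, b, loc=priors.logit_mean, scale=priors.logit_sd)
    if not priors.d50_low <= detection.d50 <= priors.d50_high:
        return -np.inf
    lp += -np.log(priors.d50_high - priors.d50_low)
    ls = np.log(-detection.slope)
    lp += stats.norm.logpdf(ls, priors.log_neg_slope_mean, priors.log_neg_slope_sd) - ls
    # initial position and state
    stat_var, _ = _movement_var(movement)
    lp += stats.norm.logpdf(
        track.positions[0],
        loc=[movement.hr_x, movement.hr_y],
        scale=np.sqrt(stat_var),
    ).sum()
    lp += np.log(0.5)
    # transitions and movement
    for i in range(1, len(track)):
        mat = transition.matrices[
            (int(covariates.daylight[i]), int(covariates.noise[i]))
        ].as_array()
        t = mat[track.states[i - 1] - 1, track.states[i] - 1]
        if t == 0.0:
            return -np.inf
        lp += np.log(t)
        if track.states[i] == 2:
            if not np.array_equal(track.positions[i], track.positions[i - 1]):
                return -np.inf
        else:
            lp += _swim_logpdf(track.positions[i - 1], track.positions[i], movement)
    # detections
    for i in range(len(track)):
        dist = np.hypot(
            receivers.coords[:, 0] - track.positions[i, 0],
            receivers.coords[:, 1] - track.positions[i, 1],
        )
        pd_ = 1.0 / (1.0 + np.exp(-detection.slope * (dist - detection.d50)))
        lp += stats.binom.logpmf(
            detections.counts[i], detection.emissions_per_step, pd_
        ).sum()
    return float(lp)
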