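"""Metropolis-within-Gibbs sampler for the two-state telemetry SSM.

Latent variables are the per-step fish positions and behavioural states;
parameters are the home-range centre, attraction strength k, home-range
radius, the 8 covariate-cell transition probabilities (on the logit scale)
and the detection curve (d50, log(-slope)).

Move set per sweep:

1. Joint (state, position) flips at each interior step, updated in an
   even/odd checkerboard so same-colour sites are conditionally
   independent.  A hidden->swimming proposal draws the new free position
   from the BRW transition density, whose value cancels exactly in the
   Metropolis ratio; swimming->hidden pins the position to the previous
   one.  Flips that would break a downstream hidden step's equality
   constraint have zero target density and are rejected automatically.
2. Random-walk shifts of maximal constant-position blocks (a free position
   together with the run of hidden steps copying it), again even/odd
   coloured over blocks.
3. Hidden-run left-edge moves and split/merge toggles at sites with a
   hidden predecessor: together with (1) these let hidden runs be created,
   destroyed, grown, shrunk, split and merged, so the NUMBER of runs (the
   sufficient statistic for the stay probabilities) mixes rather than
   quenching into a single configuration.
4. A blocked update of the transition logits and the state path: each
   logit is sampled against the STATE-MARGINALIZED likelihood of the
   position path (forward algorithm over the two-state chain, numba-
   compiled), with random-walk steps plus independence refreshes from the
   truncated-normal prior; the state path is then redrawn exactly by
   forward-filter backward-sampling.  Updating logits against realized
   transition counts instead is a strong positive feedback (few observed
   switches push p up, which suppresses switches) that mixes
   pathologically slowly.
5. Random-walk MH on the remaining parameters on transformed scales
   (2-D centre, log k, raw radius, d50, log(-slope)); movement parameters
   re-evaluate only the movement factors, detection parameters only the
   detection factors.
6. With small probability, a prior-ancestral independence move: propose
   all parameters from their priors and the latents from the generative
   model; the MH ratio reduces to the detection-likelihood ratio.  With
   the likelihood disabled (prior_only) this move always accepts, so a
   data-free run yields iid prior draws — the exact posterior for
   zero-information data.

Proposal scales adapt by Robbins-Monro only during burn-in; the kernel is
fixed afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.special import gammaln

from ..behaviour import CovariateSeries
from ..errors import InitializationError
from ..movement import CHI2_95_2DF
from ..observation import DetectionSeries, ReceiverArray
from .model import PARAM_NAMES, Priors, detection_weighted_centroid

__all__ = ["MCMCConfig", "PosteriorSamples", "run_mcmc"]

# Index layout of the internal transformed parameter vector:
# 0 hr_x, 1 hr_y, 2 log k, 3 radius, 4..11 logits (cell-major:
# day_noise p,q / day_silence p,q / night_noise p,q / night_silence p,q),
# 12 d50, 13 log(-slope).
_CELL_ORDER = (3, 2, 1, 0)  # cell index 2*daylight + noise, in PARAM_NAMES order


@numba.njit(cache=False)
def _forward_loglik(log_emit, logT, cells):
    """Log-likelihood of the position path with states summed out.

    log_emit[n, s]: emission log-density of step n under state s (0 =
    swimming BRW density, 1 = hidden equality indicator); the initial
    state is uniform and step 0 has no emission.
    """
    n = log_emit.shape[0]
    a0 = np.log(0.5)
    a1 = np.log(0.5)
    for i in range(1, n):
        b0 = np.logaddexp(a0 + logT[cells[i], 0, 0], a1 + logT[cells[i], 1, 0])
        b1 = np.logaddexp(a0 + logT[cells[i], 0, 1], a1 + logT[cells[i], 1, 1])
        a0 = b0 + log_emit[i, 0]
        a1 = b1 + log_emit[i, 1]
        if a0 < -1e250 and a1 < -1e250:  # path impossible
            return -np.inf
    return np.logaddexp(a0, a1)


@numba.njit(cache=False)
def _ffbs(log_emit, logT, cells, u):
    """Exact draw of the state path given positions (forward filter,
    backward sample).  ``u`` holds one uniform variate per step."""
    n = log_emit.shape[0]
    alpha = np.empty((n, 2))
    alpha[0, 0] = np.log(0.5)
    alpha[0, 1] = np.log(0.5)
    for i in range(1, n):
        for s in range(2):
            alpha[i, s] = (
                np.logaddexp(
                    alpha[i - 1, 0] + logT[cells[i], 0, s],
                    alpha[i - 1, 1] + logT[cells[i], 1, s],
                )
                + log_emit[i, s]
            )
    st = np.empty(n, np.int64)
    p1 = 1.0 / (1.0 + np.exp(alpha[n - 1, 0] - alpha[n - 1, 1]))
    st[n - 1] = 1 if u[n - 1] < p1 else 0
    for i in range(n - 2, -1, -1):
        w0 = alpha[i, 0] + logT[cells[i + 1], 0, st[i + 1]]
        w1 = alpha[i, 1] + logT[cells[i + 1], 1, st[i + 1]]
        p1 = 1.0 / (1.0 + np.exp(w0 - w1))
        st[i] = 1 if u[i] < p1 else 0
    return st


@dataclass(frozen=True)
class MCMCConfig:
    """Chain configuration: 3 chains, burn-in 1000, thin 10, 10000 kept draws."""

    n_chains: int = 3
    n_keep: int = 10000
    burn_in: int = 1000
    thin: int = 10
    seed: int = 0
    prior_move_prob: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_keep, self.burn_in, self.thin) < 1:
            raise ValueError("chain settings must be positive")
        if not 0.0 <= self.prior_move_prob <= 1.0:
            raise ValueError("prior_move_prob must be a probability")


@dataclass
class PosteriorSamples:
    """MCMC draws: (chain, iteration, parameter) plus a log-density trace."""

    draws: np.ndarray
    param_names: tuple
    log_density: np.ndarray
    config: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, float)
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.param_names):
            raise ValueError("draws must be (chain, iteration, parameter)")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("draws must be finite")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        c, k, p = self.draws.shape
        chain = np.repeat(np.arange(c), k * p)
        iteration = np.tile(np.repeat(np.arange(k), p), c)
        parameter = np.tile(np.asarray(self.param_names), c * k)
        return pd.DataFrame(
            {
                "chain": chain,
                "iteration": iteration,
                "parameter": parameter,
                "value": self.draws.reshape(-1),
            }
        )


class _Chain:
    """One MCMC chain: state, caches and the sweep kernel."""

    def __init__(
        self,
        counts: np.ndarray,
        cells: np.ndarray,
        coords: np.ndarray,
        emissions: int,
        dt: float,
        priors: Priors,
        rng: np.random.Generator,
        prior_only: bool,
        covariates: CovariateSeries,
    ) -> None:
        self.counts = counts
        self.cells = cells
        self.coords = coords
        self.m = emissions
        self.dt = dt
        self.priors = priors
        self.rng = rng
        self.prior_only = prior_only
        self.covariates = covariates
        self.n = counts.shape[0]
        # Binomial coefficient term per step (constant in everything sampled).
        cl = (
            gammaln(self.m + 1)
            - gammaln(counts + 1)
            - gammaln(self.m - counts + 1)
        )
        self.binom_const = cl.sum(axis=1)
        # Adaptive proposal scales.
        self.scales = {
            "block": 20.0,
            "centre": 20.0,
            "logk": 0.6,
            "radius": 30.0,
            "d50": 30.0,
            "lslope": 0.3,
        }
        # one adaptive scale per transition logit: rare covariate cells
        # need order-of-magnitude larger steps than data-rich ones
        for j in range(8):
            self.scales[f"logit{j}"] = 0.8
        self.adapting = True
        # While True, transition logits are held fixed: used during early
        # burn-in so the latent state path equilibrates against the data
        # before the stay probabilities react to it (an all-swimming start
        # otherwise drives p towards 1 faster than states can be created).
        self.freeze_transition = False
        self._t = 0

    # ---------------- parameter access -----------------

    def set_theta(self, theta: np.ndarray) -> None:
        self.theta = np.asarray(theta, float)
        self._refresh_movement()
        self._refresh_logT()

    def _refresh_movement(self) -> None:
        self.kdt = np.exp(self.theta[2]) * self.dt
        self.centre = self.theta[:2].copy()
        self.stat_var = self.theta[3] ** 2 / CHI2_95_2DF
        # kdt*(2-kdt) == 1-(1-kdt)^2, stable at tiny k
        self.step_var = self.stat_var * self.kdt * (2.0 - self.kdt)

    def _refresh_logT(self) -> None:
        # logT[cell, from, to]; 0 = swimming, 1 = hidden.
        logits = self.theta[4:12]
        self.logT = np.empty((4, 2, 2))
        for pos, cell in enumerate(_CELL_ORDER):
            lp, lq = logits[2 * pos], logits[2 * pos + 1]
            self.logT[cell, 0, 0] = -np.logaddexp(0.0, -lp)
            self.logT[cell, 0, 1] = -np.logaddexp(0.0, lp)
            self.logT[cell, 1, 1] = -np.logaddexp(0.0, -lq)
            self.logT[cell, 1, 0] = -np.logaddexp(0.0, lq)

    def natural_params(self) -> np.ndarray:
        """Map the transformed vector to PARAM_NAMES order on natural scale."""
        t = self.theta
        probs = 1.0 / (1.0 + np.exp(-t[4:12]))
        return np.concatenate(
            [[t[0], t[1], np.exp(t[2]), t[3]], probs, [t[12], -np.exp(t[13])]]
        )

    # ---------------- likelihood pieces -----------------

    def det_ll(self, pos: np.ndarray, idx=None) -> np.ndarray:
        """Per-step detection log-likelihood at the given positions."""
        if self.prior_only:
            return np.zeros(pos.shape[0] if pos.ndim == 2 else 1)
        counts = self.counts if idx is None else self.counts[idx]
        const = self.binom_const if idx is None else self.binom_const[idx]
        d50, lslope = self.theta[12], self.theta[13]
        slope = -np.exp(lslope)
        d = np.sqrt(
            ((pos[:, None, :] - self.coords[None, :, :]) ** 2).sum(axis=-1)
        )
        eta = slope * (d - d50)
        log_pd = -np.logaddexp(0.0, -eta)
        log_1mpd = -np.logaddexp(0.0, eta)
        return const + (counts * log_pd + (self.m - counts) * log_1mpd).sum(axis=1)

    def swim_ll(self, frm: np.ndarray, to: np.ndarray) -> np.ndarray:
        mean = frm + self.kdt * (self.centre - frm)
        sq = ((to - mean) ** 2).sum(axis=-1)
        return -np.log(2.0 * np.pi * self.step_var) - sq / (2.0 * self.step_var)

    def r0_ll(self, pos0: np.ndarray) -> float:
        sq = float(((pos0 - self.centre) ** 2).sum())
        return (
            -np.log(2.0 * np.pi * self.stat_var)
            - sq / (2.0 * self.stat_var)
            + np.log(0.5)
        )

    def mov_total(self) -> float:
        sw = np.flatnonzero(self.st[1:] == 0) + 1
        tot = self.r0_ll(self.pos[0])
        if sw.size:
            tot += float(self.swim_ll(self.pos[sw - 1], self.pos[sw]).sum())
        return tot

    def trans_counts(self) -> np.ndarray:
        """Transition counts c[cell, from, to] over the current state path."""
        idx = (
            self.cells[1:] * 4 + self.st[:-1] * 2 + self.st[1:]
        )
        return np.bincount(idx, minlength=16).reshape(4, 2, 2)

    def trans_total(self) -> float:
        return float((self.trans_counts() * self.logT).sum())

    def log_prior_theta(self, theta=None) -> float:
        """Unnormalized log prior on the transformed scale (with Jacobians)."""
        t = self.theta if theta is None else theta
        p = self.priors
        dx, dy = t[0] - p.centre_x, t[1] - p.centre_y
        if dx * dx + dy * dy > p.centre_radius**2:
            return -np.inf
        k = np.exp(t[2])
        if k * self.dt >= 1.0:
            return -np.inf
        lp = p.k_shape * t[2] - k / p.k_scale  # gamma density * k jacobian
        if not p.radius_low <= t[3] <= p.radius_high:
            return -np.inf
        logits = t[4:12]
        if np.any(np.abs(logits) >= p.logit_bound):
            return -np.inf
        lp += float(-((logits - p.logit_mean) ** 2).sum() / (2.0 * p.logit_sd**2))
        if not p.d50_low <= t[12] <= p.d50_high:
            return -np.inf
        lp += -((t[13] - p.log_neg_slope_mean) ** 2) / (2.0 * p.log_neg_slope_sd**2)
        return float(lp)

    def log_density(self) -> float:
        """Unnormalized joint log density of the current chain state."""
        det = 0.0 if self.prior_only else float(self.det_ll_step.sum())
        return (
            self.log_prior_theta() + self.trans_total() + self.mov_total() + det
        )

    # ---------------- latent initialization -----------------

    def init_latents(self) -> None:
        """Positions at per-step detection-weighted centroids, all swimming."""
        w = self.counts.astype(float)
        tot = w.sum(axis=1)
        pos = np.full((self.n, 2), np.nan)
        ok = tot > 0
        if ok.any():
            pos[ok] = (w[ok, :, None] * self.coords[None, :, :]).sum(axis=1) / tot[
                ok, None
            ]
        df = pd.DataFrame(pos).ffill().bfill()
        pos = df.to_numpy()
        if np.any(np.isnan(pos)):
            pos = np.tile(self.coords.mean(axis=0), (self.n, 1))
        pos = pos + self.rng.normal(0.0, 5.0, size=pos.shape)
        self.pos = pos
        self.st = np.zeros(self.n, int)  # all swimming: no equality constraints
        self.det_ll_step = self.det_ll(self.pos)

    def sample_ancestral(self, theta: np.ndarray):
        """Simulate states and positions from the model under ``theta``."""
        kdt = np.exp(theta[2]) * self.dt
        stat_var = theta[3] ** 2 / CHI2_95_2DF
        step_var = stat_var * kdt * (2.0 - kdt)
        centre = theta[:2]
        logits = theta[4:12]
        stay = np.empty((4, 2))
        for pos_i, cell in enumerate(_CELL_ORDER):
            stay[cell, 0] = 1.0 / (1.0 + np.exp(-logits[2 * pos_i]))
            stay[cell, 1] = 1.0 / (1.0 + np.exp(-logits[2 * pos_i + 1]))
        n = self.n
        st = np.empty(n, int)
        st[0] = self.rng.integers(2)
        u = self.rng.random(n)
        cells = self.cells
        for i in range(1, n):
            st[i] = st[i - 1] if u[i] < stay[cells[i], st[i - 1]] else 1 - st[i - 1]
        noise = self.rng.normal(0.0, 1.0, size=(n, 2))
        pos = np.empty((n, 2))
        pos[0] = centre + noise[0] * np.sqrt(stat_var)
        sd = np.sqrt(step_var)
        for i in range(1, n):
            if st[i] == 1:
                pos[i] = pos[i - 1]
            else:
                pos[i] = pos[i - 1] + kdt * (centre - pos[i - 1]) + noise[i] * sd
        return st, pos

    def sample_theta_from_prior(self) -> np.ndarray:
        p = self.priors
        rng = self.rng
        theta = np.empty(14)
        r = p.centre_radius * np.sqrt(rng.random())
        phi = 2.0 * np.pi * rng.random()
        theta[0] = p.centre_x + r * np.cos(phi)
        theta[1] = p.centre_y + r * np.sin(phi)
        while True:  # k truncated to the stable region
            k = rng.gamma(p.k_shape, p.k_scale)
            if 0.0 < k * self.dt < 1.0:
                break
        theta[2] = np.log(k)
        theta[3] = rng.uniform(p.radius_low, p.radius_high)
        while True:
            logits = rng.normal(p.logit_mean, p.logit_sd, size=8)
            if np.all(np.abs(logits) < p.logit_bound):
                break
        theta[4:12] = logits
        theta[12] = rng.uniform(p.d50_low, p.d50_high)
        theta[13] = rng.normal(p.log_neg_slope_mean, p.log_neg_slope_sd)
        return theta

    # ---------------- moves -----------------

    def _accept_rate(self, key: str, accepted: float, proposed: float) -> None:
        if not self.adapting or proposed == 0:
            return
        target = 0.3 if key in ("block", "centre") else 0.44
        rate = accepted / proposed
        gamma = 2.0 / np.sqrt(1.0 + self._t)
        self.scales[key] *= float(np.exp(gamma * (rate - target)))
        self.scales[key] = float(np.clip(self.scales[key], 1e-4, 1e4))

    def update_blocks(self) -> None:
        """Random-walk shift of constant-position blocks, even/odd coloured."""
        acc_n = 0
        prop_n = 0
        for parity in (0, 1):
            free = self.st == 0
            free[0] = True
            bid = np.cumsum(free) - 1
            nb = bid[-1] + 1
            starts = np.flatnonzero(free)
            ends = np.append(starts[1:] - 1, self.n - 1)
            delta = self.rng.normal(0.0, self.scales["block"], size=(nb, 2))
            mask_b = (np.arange(nb) % 2) == parity
            delta[~mask_b] = 0.0
            newpos = self.pos + delta[bid]
            # detection terms only change on this parity's steps
            idx_mv = np.flatnonzero(mask_b[bid])
            new_det = self.det_ll_step.copy()
            new_det[idx_mv] = self.det_ll(newpos[idx_mv], idx=idx_mv)
            logr_det = np.bincount(
                bid[idx_mv],
                weights=new_det[idx_mv] - self.det_ll_step[idx_mv],
                minlength=nb,
            )
            # movement into each block start
            logr_in = np.zeros(nb)
            s_in = starts[1:]  # block 0 starts at step 0
            logr_in[1:] = self.swim_ll(self.pos[s_in - 1], newpos[s_in]) - self.swim_ll(
                self.pos[s_in - 1], self.pos[s_in]
            )
            logr_in[0] = self.r0_ll(newpos[0]) - self.r0_ll(self.pos[0])
            # movement out of each block end into the next block's start
            logr_out = np.zeros(nb)
            e = ends[:-1]
            nxt = starts[1:]
            logr_out[:-1] = self.swim_ll(newpos[e], self.pos[nxt]) - self.swim_ll(
                self.pos[e], self.pos[nxt]
            )
            logr = logr_det + logr_in + logr_out
            u = np.log(self.rng.random(nb))
            acc = mask_b & (u < logr)
            if acc.any():
                step_acc = acc[bid]
                self.pos[step_acc] = newpos[step_acc]
                self.det_ll_step[step_acc] = new_det[step_acc]
            acc_n += int(acc.sum())
            prop_n += int(mask_b.sum())
        self._accept_rate("block", acc_n, prop_n)

    def update_states(self) -> None:
        """Joint (state, position) flip at each interior step."""
        n = self.n
        sd = np.sqrt(self.step_var)
        for parity in (1, 0):
            idx = np.arange(1, n)
            idx = idx[idx % 2 == parity]
            if idx.size == 0:
                continue
            s_old = self.st[idx]
            s_new = 1 - s_old
            prevpos = self.pos[idx - 1]
            mean = prevpos + self.kdt * (self.centre - prevpos)
            noise = self.rng.normal(0.0, sd, size=(idx.size, 2))
            # hidden->swim draws from the BRW density (cancels in the ratio);
            # swim->hidden pins to the previous position.
            prop = np.where((s_old == 1)[:, None], mean + noise, prevpos)
            logr = (
                self.logT[self.cells[idx], self.st[idx - 1], s_new]
                - self.logT[self.cells[idx], self.st[idx - 1], s_old]
            )
            has_next = idx < n - 1
            nxt = np.minimum(idx + 1, n - 1)
            s_next = self.st[nxt]
            logr += np.where(
                has_next,
                self.logT[self.cells[nxt], s_new, s_next]
                - self.logT[self.cells[nxt], s_old, s_next],
                0.0,
            )
            # a hidden successor pins its position to ours: any change breaks it
            blocked = has_next & (s_next == 1)
            swim_next = has_next & (s_next == 0)
            if swim_next.any():
                j = np.flatnonzero(swim_next)
                logr[j] += self.swim_ll(prop[j], self.pos[nxt[j]]) - self.swim_ll(
                    self.pos[idx[j]], self.pos[nxt[j]]
                )
            new_det = self.det_ll(prop, idx=idx)
            logr += new_det - self.det_ll_step[idx]
            logr[blocked] = -np.inf
            acc = np.log(self.rng.random(idx.size)) < logr
            if acc.any():
                j = idx[acc]
                self.st[j] = s_new[acc]
                self.pos[j] = prop[acc]
                self.det_ll_step[j] = new_det[acc]
        # Gibbs draw for the initial state (uniform prior, one transition term).
        if n > 1:
            lt = self.logT[self.cells[1], :, self.st[1]]
            pr = np.exp(lt - np.logaddexp(lt[0], lt[1]))
            self.st[0] = int(self.rng.random() < pr[1])

    def update_run_edges(self) -> None:
        """Move the LEFT boundary of maximal hidden runs.

        Single-site flips can only create runs and move their right edge (a
        change upstream of a hidden step would break its equality
        constraint), so without this move the left edge of a hidden run of
        length >= 2 is frozen.  Per run, with probability 1/2 each, either
        the preceding swimming step joins the run (its position collapses
        onto the run's new pinned value) or the first hidden step leaves it
        (a fresh free position is drawn from the BRW density, whose value
        cancels in the ratio; the downstream run re-pins to it).  Adjacent
        runs share a boundary site, so runs are updated in an even/odd
        colouring.
        """
        n = self.n
        for parity in (0, 1):
            hid = self.st == 1
            if not hid.any():
                return
            prev_hid = np.concatenate(([False], hid[:-1]))
            next_hid = np.concatenate((hid[1:], [False]))
            starts = np.flatnonzero(hid & ~prev_hid)
            ends = np.flatnonzero(hid & ~next_hid)
            keep = starts >= 1  # runs touching step 0 are handled elsewhere
            starts, ends = starts[keep], ends[keep]
            if starts.size == 0:
                return
            sel = (np.arange(starts.size) % 2) == parity
            starts, ends = starts[sel], ends[sel]
            if starts.size == 0:
                continue
            choose_extend = self.rng.random(starts.size) < 0.5
            newpos = self.pos.copy()
            new_st = self.st.copy()
            run_id = np.full(n, -1)
            sd = np.sqrt(self.step_var)
            flip_site = np.empty(starts.size, int)
            valid = np.zeros(starts.size, bool)
            logr_t = np.zeros(starts.size)
            for r, (s, e) in enumerate(zip(starts, ends)):
                if choose_extend[r]:
                    m = s - 1  # swimming predecessor joins the run
                    # needs a swimming step before it, else the move would
                    # merge two runs and the reverse proposal differs
                    if m < 1 or self.st[m - 1] != 0:
                        continue
                    w = self.pos[m - 1]
                    newpos[m : e + 1] = w
                    new_st[m] = 1
                    flip_site[r] = m
                    logr_t[r] = (
                        self.logT[self.cells[m], self.st[m - 1], 1]
                        - self.logT[self.cells[m], self.st[m - 1], 0]
                        + self.logT[self.cells[m + 1], 1, 1]
                        - self.logT[self.cells[m + 1], 0, 1]
                    )
                    run_id[m : e + 1] = r
                    valid[r] = True
                else:
                    # first hidden step leaves the run; downstream re-pins
                    w = self.pos[s - 1]
                    mean = w + self.kdt * (self.centre - w)
                    z = mean + self.rng.normal(0.0, sd, size=2)
                    newpos[s : e + 1] = z
                    new_st[s] = 0
                    flip_site[r] = s
                    to_next = self.st[s + 1] if s + 1 < n else None
                    logr_t[r] = (
                        self.logT[self.cells[s], self.st[s - 1], 0]
                        - self.logT[self.cells[s], self.st[s - 1], 1]
                    )
                    if to_next is not None:
                        logr_t[r] += (
                            self.logT[self.cells[s + 1], 0, to_next]
                            - self.logT[self.cells[s + 1], 1, to_next]
                        )
                    run_id[s : e + 1] = r
                    valid[r] = True
            if not valid.any():
                continue
            touched = run_id >= 0
            idx_t = np.flatnonzero(touched)
            new_det = self.det_ll_step.copy()
            new_det[idx_t] = self.det_ll(newpos[idx_t], idx=idx_t)
            logr = logr_t.copy()
            np.add.at(
                logr, run_id[idx_t], (new_det - self.det_ll_step)[idx_t]
            )
            # movement out of the run end into the next (swimming) step
            after = ends + 1
            has_after = after <= n - 1
            ia = np.flatnonzero(has_after & valid)
            if ia.size:
                e_a = ends[ia]
                logr[ia] += self.swim_ll(
                    newpos[e_a], self.pos[after[ia]]
                ) - self.swim_ll(self.pos[e_a], self.pos[after[ia]])
            acc = valid & (np.log(self.rng.random(starts.size)) < logr)
            if acc.any():
                step_acc = np.isin(run_id, np.flatnonzero(acc)) & touched
                self.pos[step_acc] = newpos[step_acc]
                self.det_ll_step[step_acc] = new_det[step_acc]
                for r in np.flatnonzero(acc):
                    self.st[flip_site[r]] = new_st[flip_site[r]]

    def update_split_merge(self, n_anchors: int = 160) -> None:
        """Split a hidden run at an interior site, or merge across one.

        Anchor sites are steps whose PREDECESSOR is hidden.  A hidden
        anchor leaves its run (split: fresh position from the BRW density,
        the downstream remainder re-pins to it); a swimming anchor joins
        the preceding run (merge: its whole constant block re-pins to the
        predecessor).  These toggles change the NUMBER of hidden runs,
        which the edge moves cannot, and are each other's exact reverses
        at the same site, so no selection-probability corrections arise.
        Anchors are drawn uniformly and processed sequentially.
        """
        n = self.n
        anchors = self.rng.integers(1, n, size=n_anchors)
        u_all = np.log(self.rng.random(n_anchors))
        noise = self.rng.normal(0.0, np.sqrt(self.step_var), size=(n_anchors, 2))
        st = self.st
        pos = self.pos
        logT = self.logT
        cells = self.cells
        d50, lslope = self.theta[12], self.theta[13]
        slope = -np.exp(lslope)
        two_pi_v = 2.0 * np.pi * self.step_var
        kdt, centre = self.kdt, self.centre

        def det_at(value, span):
            """Detection log-lik of a constant position over a step span."""
            if self.prior_only:
                return np.zeros(len(span))
            d = np.sqrt(((value - self.coords) ** 2).sum(axis=1))
            eta = slope * (d - d50)
            log_pd = -np.logaddexp(0.0, -eta)
            log_1mpd = -np.logaddexp(0.0, eta)
            c = self.counts[span]
            return (
                self.binom_const[span]
                + c @ log_pd
                + (self.m - c) @ log_1mpd
            )

        def swim1(frm, to):
            mean = frm + kdt * (centre - frm)
            return -np.log(two_pi_v) - ((to - mean) ** 2).sum() / (
                2.0 * self.step_var
            )

        for a_i in range(n_anchors):
            site = int(anchors[a_i])
            if st[site - 1] != 1:
                continue
            s_old = st[site]
            s_new = 1 - s_old
            w = pos[site - 1]
            # end of the constant-position block starting at `site`
            e = site
            while e + 1 < n and st[e + 1] == 1:
                e += 1
            if s_old == 1:  # split: site leaves the run
                newval = w + kdt * (centre - w) + noise[a_i]
            else:  # merge: site's block joins the preceding run
                newval = w
            logr = logT[cells[site], 1, s_new] - logT[cells[site], 1, s_old]
            if site + 1 <= e:
                logr += (
                    logT[cells[site + 1], s_new, 1]
                    - logT[cells[site + 1], s_old, 1]
                )
            elif site + 1 < n:
                nxt = st[site + 1]
                logr += (
                    logT[cells[site + 1], s_new, nxt]
                    - logT[cells[site + 1], s_old, nxt]
                )
            span = slice(site, e + 1)
            new_det = det_at(newval, span)
            logr += new_det.sum() - self.det_ll_step[span].sum()
            if e + 1 < n and st[e + 1] == 0:
                logr += swim1(newval, pos[e + 1]) - swim1(pos[e], pos[e + 1])
            if u_all[a_i] < logr:
                st[site] = s_new
                pos[span] = newval
                self.det_ll_step[span] = new_det

    def _mh_scalar(self, indices, scale_key: str, mov_dependent: bool) -> None:
        """Random-walk MH on a subset of theta (movement or detection params)."""
        cur_prior = self.log_prior_theta()
        if mov_dependent:
            cur_lik = self.mov_total()
        else:
            cur_lik = 0.0 if self.prior_only else float(self.det_ll_step.sum())
        theta_new = self.theta.copy()
        step = self.rng.normal(0.0, self.scales[scale_key], size=len(indices))
        for j, i in enumerate(indices):
            theta_new[i] = self.theta[i] + step[j]
        new_prior = self.log_prior_theta(theta_new)
        accepted = False
        if np.isfinite(new_prior):
            old_theta = self.theta
            self.theta = theta_new
            self._refresh_movement()
            if mov_dependent:
                new_lik = self.mov_total()
                new_det = None
            else:
                new_det = self.det_ll(self.pos)
                new_lik = 0.0 if self.prior_only else float(new_det.sum())
            logr = (new_prior + new_lik) - (cur_prior + cur_lik)
            if np.log(self.rng.random()) < logr:
                accepted = True
                if new_det is not None and not self.prior_only:
                    self.det_ll_step = new_det
            else:
                self.theta = old_theta
                self._refresh_movement()
        self._accept_rate(scale_key, float(accepted), 1.0)

    def update_movement_params(self) -> None:
        self._mh_scalar([0, 1], "centre", mov_dependent=True)
        self._mh_scalar([2], "logk", mov_dependent=True)
        self._mh_scalar([3], "radius", mov_dependent=True)

    def update_detection_params(self) -> None:
        self._mh_scalar([12], "d50", mov_dependent=False)
        self._mh_scalar([13], "lslope", mov_dependent=False)

    def _state_marginal_emissions(self) -> np.ndarray:
        """Per-step emission log-densities of the two states given positions:
        column 0 the BRW swimming density, column 1 the zero-displacement
        indicator of a hidden step.  Step 0 has no emission."""
        le = np.zeros((self.n, 2))
        eq = np.all(self.pos[1:] == self.pos[:-1], axis=1)
        le[1:, 0] = self.swim_ll(self.pos[:-1], self.pos[1:])
        le[1:, 1] = np.where(eq, 0.0, -np.inf)
        return le

    @staticmethod
    def _cand_logT(logT, cell, which, l):
        out = logT.copy()
        stay = -np.logaddexp(0.0, -l)
        switch = -np.logaddexp(0.0, l)
        out[cell, which, which] = stay
        out[cell, which, 1 - which] = switch
        return out

    def update_transition_params(self) -> None:
        """Blocked update of the transition logits and the state path.

        Each logit is sampled against the STATE-MARGINALIZED likelihood of
        the position path (forward algorithm over the two-state chain), so
        the stay probabilities are decoupled from the current state
        labelling — updating them against realized transition counts is a
        strong positive feedback (few observed switches push p up, which
        suppresses switches) that mixes pathologically slowly.  The state
        path is then redrawn exactly by forward-filter backward-sampling,
        completing a partially collapsed Gibbs block.
        """
        le = self._state_marginal_emissions()
        p = self.priors
        if not self.freeze_transition:
            cur = _forward_loglik(le, self.logT, self.cells)
            for pos_i, cell in enumerate(_CELL_ORDER):
                for which in (0, 1):  # 0: p (from swimming), 1: q (hidden)
                    i = 4 + 2 * pos_i + which
                    key = f"logit{2 * pos_i + which}"
                    # random-walk steps
                    for _ in range(2):
                        l = self.theta[i]
                        lnew = l + self.rng.normal(0.0, self.scales[key])
                        if abs(lnew) >= p.logit_bound:
                            self._accept_rate(key, 0.0, 1.0)
                            continue
                        cand = self._cand_logT(self.logT, cell, which, lnew)
                        new = _forward_loglik(le, cand, self.cells)
                        logr = (
                            new
                            - cur
                            - (lnew - p.logit_mean) ** 2 / (2.0 * p.logit_sd**2)
                            + (l - p.logit_mean) ** 2 / (2.0 * p.logit_sd**2)
                        )
                        acc = np.log(self.rng.random()) < logr
                        if acc:
                            self.theta[i] = lnew
                            self.logT = cand
                            cur = new
                        self._accept_rate(key, float(acc), 1.0)
                    # independence refreshes from the truncated-normal
                    # prior (prior terms cancel): they cross the wide
                    # bathtub-shaped posterior of data-poor cells quickly
                    for _ in range(2):
                        while True:
                            lind = self.rng.normal(p.logit_mean, p.logit_sd)
                            if abs(lind) < p.logit_bound:
                                break
                        cand = self._cand_logT(self.logT, cell, which, lind)
                        new = _forward_loglik(le, cand, self.cells)
                        if np.log(self.rng.random()) < new - cur:
                            self.theta[i] = lind
                            self.logT = cand
                            cur = new
        # exact redraw of the state path given positions and logits
        u = self.rng.random(self.n)
        self.st = np.asarray(_ffbs(le, self.logT, self.cells, u), int)

    def prior_ancestral_move(self) -> None:
        theta_new = self.sample_theta_from_prior()
        st_new, pos_new = self.sample_ancestral(theta_new)
        if self.prior_only:
            logr = 0.0
            new_det = np.zeros(self.n)
        else:
            old_theta = self.theta
            self.theta = theta_new  # det_ll uses theta[12:14]
            new_det = self.det_ll(pos_new)
            self.theta = old_theta
            logr = float(new_det.sum() - self.det_ll_step.sum())
        if np.log(self.rng.random()) < logr:
            self.set_theta(theta_new)
            self.st = st_new
            self.pos = pos_new
            self.det_ll_step = new_det

    def sweep(self) -> None:
        self._t += 1
        if self.prior_only:
            self.prior_ancestral_move()
            return
        self.update_blocks()
        self.update_states()
        self.update_run_edges()
        self.update_split_merge()
        self.update_movement_params()
        self.update_transition_params()
        self.update_detection_params()
        if self.rng.random() < self.prior_move_prob_eff:
            self.prior_ancestral_move()


def _init_chain(
    chain: _Chain, base_theta: np.ndarray, rng: np.random.Generator
) -> None:
    """Overdispersed start: jitter around data-driven values, retry on -inf."""
    for _ in range(10):
        theta = base_theta.copy()
        theta[0] += rng.normal(0.0, 60.0)
        theta[1] += rng.normal(0.0, 60.0)
        theta[2] += rng.normal(0.0, 0.5)
        theta[3] = np.clip(
            theta[3] * np.exp(rng.normal(0.0, 0.4)),
            chain.priors.radius_low + 1.0,
            chain.priors.radius_high - 1.0,
        )
        theta[4:12] = rng.normal(0.0, 1.0, size=8)
        theta[12] = np.clip(
            theta[12] + rng.normal(0.0, 25.0),
            chain.priors.d50_low + 1.0,
            chain.priors.d50_high - 1.0,
        )
        theta[13] += rng.normal(0.0, 0.2)
        if np.exp(theta[2]) * chain.dt >= 1.0:
            continue
        chain.set_theta(theta)
        chain.init_latents()
        if np.isfinite(chain.log_density()):
            return
    raise InitializationError("no finite-density starting point after 10 attempts")


def run_mcmc(
    detections: DetectionSeries,
    covariates: CovariateSeries,
    receivers: ReceiverArray,
    priors: Priors | None = None,
    config: MCMCConfig | None = None,
    prior_only: bool = False,
    dt: float | None = None,
    emissions_per_step: int = 6,
) -> PosteriorSamples:
    """Sample the joint posterior of all SSM parameters for one individual.

    Latent positions and states are sampled alongside the parameters and
    marginalized by discarding.  Burn-in draws are dropped, the remainder
    thinned; ``config.n_keep`` draws are retained per chain.  Fully
    reproducible given ``config.seed``.
    """
    config = config or MCMCConfig()
    counts = detections.counts
    n, j = counts.shape
    if j < 2:
        raise ValueError("need at least 2 receivers")
    if n < 50:
        raise ValueError("need at least 50 time steps")
    if len(covariates) != n:
        raise ValueError("covariates must match the detection series length")
    if np.any(counts > emissions_per_step):
        raise ValueError("counts exceed emissions_per_step")
    dt = float(dt if dt is not None else detections.step_duration)

    if priors is None:
        cx, cy = detection_weighted_centroid(detections, receivers)
        priors = Priors(centre_x=float(cx), centre_y=float(cy))

    n_params = len(PARAM_NAMES)
    draws = np.empty((config.n_chains, config.n_keep, n_params))
    logdens = np.empty((config.n_chains, config.n_keep))

    # Data-driven central starting vector (prior medians elsewhere).
    cx, cy = detection_weighted_centroid(detections, receivers)
    base_theta = np.array(
        [
            cx,
            cy,
            np.log(0.5 / dt),
            200.0,
            *([0.0] * 8),
            min(150.0, priors.d50_high - 10.0),
            priors.log_neg_slope_mean,
        ]
    )

    for c in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, c]))
        chain = _Chain(
            counts=counts,
            cells=covariates.cell_index,
            coords=receivers.coords,
            emissions=emissions_per_step,
            dt=dt,
            priors=priors,
            rng=rng,
            prior_only=prior_only,
            covariates=covariates,
        )
        chain.prior_move_prob_eff = config.prior_move_prob
        _init_chain(chain, base_theta, rng)
        chain.adapting = True
        warm = 0 if prior_only else config.burn_in // 3
        chain.freeze_transition = warm > 0
        for it in range(config.burn_in):
            if it == warm:
                chain.freeze_transition = False
            chain.sweep()
        chain.freeze_transition = False
        chain.adapting = False
        kept = 0
        while kept < config.n_keep:
            for _ in range(config.thin):
                chain.sweep()
            draws[c, kept] = chain.natural_params()
            logdens[c, kept] = chain.log_density()
            kept += 1

    return PosteriorSamples(
        draws=draws,
        param_names=PARAM_NAMES,
        log_density=logdens,
        config=config,
    )
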