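"""Hierarchical Bayesian cue-reweighting model, fit by MCMC.

The lower layer models each response on audio-visual trials as a weighted
average of the two cue placements plus Gaussian noise (precision
parameterization throughout this module, the convention of the original
model specification):

    Y_ijk ~ Normal(W_ij * V_ijk + (1 - W_ij) * A_ijk,  precision tau_ij)

where i = participant, j = session (3 or 5), k = trial, Y = ln response,
V = ln visual-distribution center, A = ln audio-signaled distance (the
audio cue signals the target exactly).  The upper layer links each
participant's Session-5 weight to their Session-3 weight on the probit
scale through a reweighting effect R_i, whose sign is oriented by the
direction of that participant's reliability change:

    W_i5 = Phi(Phi^-1(W_i3) - R_i)   visual reliability decreased
    W_i5 = Phi(Phi^-1(W_i3) + R_i)   visual reliability increased
    R_i  ~ Normal(M, precision T)

A positive population mean M fits reliability-sensitive reweighting; M = 0
fits a static (rote) weighting.  Priors: W_i3 ~ Uniform(0,1) independently
per participant (no pooling on the Session-3 weights), tau_ij ~
Exponential(rate 0.001), M ~ Normal(0, precision 1), T ~ Exponential(rate
0.001) (prior mean 1000 — extremely vague).

The sampler is Metropolis-within-Gibbs: tau_ij, M and T have conjugate
updates (the exponential priors are Gamma(1, 0.001)); W_i3 (on the probit
scale, with the Jacobian making the implied prior flat on (0,1)) and R_i
use adaptive random-walk Metropolis, with proposal scales frozen at the
end of burn-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from ._streams import substream

log = logging.getLogger(__name__)

__all__ = [
    "PRIORS",
    "ReweightingData",
    "McmcConfig",
    "ReweightingPosterior",
    "log_posterior",
    "fit_reweighting",
    "summarize_reweighting",
    "label_swap_check",
]

#: Prior distributions (scipy frozen form; note Exponential(rate 0.001)
#: has mean 1000).
PRIORS = {
    "W3": stats.uniform(0, 1),
    "tau": stats.expon(scale=1000.0),
    "M": stats.norm(0, 1),
    "T": stats.expon(scale=1000.0),
}
_EXP_RATE = 0.001

_Phi = stats.norm.cdf
_Phi_inv = stats.norm.ppf


@dataclass
class _CellStats:
    """Sufficient statistics of one participant-session likelihood.

    With E = Y - A and D = V - A the residual sum of squares at weight W is
    SSR(W) = SEE - 2 W SED + W^2 SDD, so every likelihood evaluation is
    O(1) regardless of trial count.
    """

    n: int
    see: float
    sed: float
    sdd: float

    def ssr(self, w):
        return self.see - 2.0 * w * self.sed + w * w * self.sdd


@dataclass
class ReweightingData:
    """Audio-visual trials of Sessions 3 and 5, grouped by participant."""

    participants: list[str]
    signs: np.ndarray          # +1 reliability increased, -1 decreased
    s3: list[_CellStats]
    s5: list[_CellStats]

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def direction(self, i: int) -> str:
        return "increased" if self.signs[i] > 0 else "decreased"

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   directions: dict[str, str]) -> "ReweightingData":
        """Build from a trial table and a participant -> direction map.

        ``directions`` values are ``'decreased'`` or ``'increased'``
        (visual reliability from Session 3 to Session 5).
        """
        df = table[(table["phase"] == "main")
                   & (table["trial_type"] == "audiovisual")
                   & (table["session"].isin((3, 5)))]
        participants = sorted(directions)
        missing = set(participants) - set(df["participant_id"])
        if missing:
            raise ValueError(f"no audio-visual trials for {sorted(missing)}")
        signs = []
        cells: dict[int, list[_CellStats]] = {3: [], 5: []}
        for pid in participants:
            d = directions[pid]
            if d not in ("decreased", "increased"):
                raise ValueError(f"direction for {pid} must be 'decreased' or "
                                 f"'increased', got {d!r}")
            signs.append(1.0 if d == "increased" else -1.0)
            for j in (3, 5):
                sub = df[(df["participant_id"] == pid) & (df["session"] == j)]
                if len(sub) < 2:
                    raise ValueError(f"{pid} has {len(sub)} audio-visual "
                                     f"trials in session {j}; need >= 2")
                y = np.log(sub["response_m"].to_numpy(float))
                a = np.log(sub["target_m"].to_numpy(float))
                v = np.log(sub["visual_center_m"].to_numpy(float))
                if np.ptp(y) == 0:
                    raise ValueError(f"constant responses for {pid} session {j}")
                e, dd = y - a, v - a
                cells[j].append(_CellStats(len(y), float(e @ e),
                                           float(e @ dd), float(dd @ dd)))
        return cls(participants, np.asarray(signs), cells[3], cells[5])

    def _arrays(self):
        def unpack(celllist):
            return (np.array([c.n for c in celllist], float),
                    np.array([c.see for c in celllist]),
                    np.array([c.sed for c in celllist]),
                    np.array([c.sdd for c in celllist]))
        return unpack(self.s3), unpack(self.s5)


@dataclass
class McmcConfig:
    """Chain settings.  Defaults follow the original fit: 6 chains of
    25,000 retained samples after 5,000 burn-in each (150,000 total)."""

    n_chains: int = 6
    n_samples: int = 25_000
    n_burnin: int = 5_000
    seed: int = 0
    probit_sampling: bool = True   # sample W_i3 on the probit scale
    target_accept: float = 0.44
    init_proposal_scale: float = 0.3

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_burnin <= 0:
            raise ValueError("n_samples and n_burnin must be positive")


@dataclass
class ReweightingPosterior:
    """Pooled posterior draws plus chain diagnostics.

    ``draws`` arrays are shaped (n_chains, n_samples[, n_participants]).
    W5 draws are deterministic transforms of (W3, R, direction).
    """

    draws: dict[str, np.ndarray]
    participants: list[str]
    signs: np.ndarray
    config: McmcConfig
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def m_interval(self, prob: float = 0.95) -> tuple[float, float]:
        """Central credible interval for the mean reweighting M."""
        lo = 100 * (1 - prob) / 2
        m = self.flat("M")
        return float(np.percentile(m, lo)), float(np.percentile(m, 100 - lo))


def _loglik_terms(w, tau, n, see, sed, sdd):
    ssr = see - 2.0 * w * sed + w * w * sdd
    return 0.5 * n * np.log(tau) - 0.5 * tau * ssr


def log_posterior(params: dict, data: ReweightingData) -> float:
    """Joint log density of Eqs.-style model at ``params``.

    ``params`` holds W3 (per participant, in (0,1)), R, tau3, tau5, M, T.
    Returns -inf outside the support.
    """
    w3 = np.asarray(params["W3"], float)
    r = np.asarray(params["R"], float)
    tau3 = np.asarray(params["tau3"], float)
    tau5 = np.asarray(params["tau5"], float)
    m, t = float(params["M"]), float(params["T"])
    if (np.any(w3 <= 0) or np.any(w3 >= 1) or np.any(tau3 <= 0)
            or np.any(tau5 <= 0) or t <= 0):
        return -np.inf
    (n3, see3, sed3, sdd3), (n5, see5, sed5, sdd5) = data._arrays()
    w5 = _Phi(_Phi_inv(w3) + data.signs * r)
    lp = 0.0
    lp += np.sum(_loglik_terms(w3, tau3, n3, see3, sed3, sdd3))
    lp += np.sum(_loglik_terms(w5, tau5, n5, see5, sed5, sdd5))
    lp -= 0.5 * np.log(2 * np.pi) * np.sum(n3 + n5)
    # priors
    lp += np.sum(np.log(_EXP_RATE) - _EXP_RATE * tau3)
    lp += np.sum(np.log(_EXP_RATE) - _EXP_RATE * tau5)
    lp += -0.5 * m * m - 0.5 * np.log(2 * np.pi)
    lp += np.log(_EXP_RATE) - _EXP_RATE * t
    lp += np.sum(0.5 * np.log(t / (2 * np.pi)) - 0.5 * t * (r - m) ** 2)
    return float(lp)


def _run_chain(data: ReweightingData, config: McmcConfig,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    P = data.n_participants
    (n3, see3, sed3, sdd3), (n5, see5, sed5, sdd5) = data._arrays()
    signs = data.signs

    # initial state from the priors (W3 mildly centered to avoid the tails)
    z = _Phi_inv(rng.uniform(0.2, 0.8, size=P))
    r = rng.normal(0, 0.5, size=P)
    tau3 = rng.exponential(100.0, size=P) + 1.0
    tau5 = rng.exponential(100.0, size=P) + 1.0
    m = rng.normal(0, 1)
    t = rng.exponential(1.0) + 0.5

    scale_z = np.full(P, config.init_proposal_scale)
    scale_r = np.full(P, config.init_proposal_scale)
    scale_m = config.init_proposal_scale
    scale_t = 1.0
    acc_z = np.zeros(P)
    acc_r = np.zeros(P)
    acc_m = 0.0
    acc_t = 0.0
    adapt_every = 50

    n_iter = config.n_burnin + config.n_samples
    keep = config.n_samples
    out = {
        "W3": np.empty((keep, P)), "W5": np.empty((keep, P)),
        "R": np.empty((keep, P)), "tau3": np.empty((keep, P)),
        "tau5": np.empty((keep, P)), "M": np.empty(keep), "T": np.empty(keep),
    }

    def lik5(z_, r_, tau_):
        w5 = _Phi(z_ + signs * r_)
        return -0.5 * tau_ * (see5 - 2 * w5 * sed5 + w5 * w5 * sdd5)

    def lik3(z_, tau_):
        w3 = _Phi(z_)
        return -0.5 * tau_ * (see3 - 2 * w3 * sed3 + w3 * w3 * sdd3)

    for it in range(n_iter):
        # --- W3 block (probit-scale random walk, per participant) --------
        if config.probit_sampling:
            z_prop = z + scale_z * rng.standard_normal(P)
            logr = (lik3(z_prop, tau3) + lik5(z_prop, r, tau5)
                    - 0.5 * z_prop**2
                    - lik3(z, tau3) - lik5(z, r, tau5) + 0.5 * z**2)
            accept = np.log(rng.uniform(size=P)) < logr
            z = np.where(accept, z_prop, z)
        else:
            w_now = _Phi(z)
            w_prop = w_now + scale_z * rng.standard_normal(P)
            ok = (w_prop > 0) & (w_prop < 1)
            w_prop = np.where(ok, w_prop, w_now)
            z_prop = _Phi_inv(w_prop)
            logr = (lik3(z_prop, tau3) + lik5(z_prop, r, tau5)
                    - lik3(z, tau3) - lik5(z, r, tau5))
            accept = ok & (np.log(rng.uniform(size=P)) < logr)
            z = np.where(accept, z_prop, z)
        acc_z += accept

        # --- R block ------------------------------------------------------
        r_prop = r + scale_r * rng.standard_normal(P)
        logr = (lik5(z, r_prop, tau5) - 0.5 * t * (r_prop - m) ** 2
                - lik5(z, r, tau5) + 0.5 * t * (r - m) ** 2)
        accept = np.log(rng.uniform(size=P)) < logr
        r = np.where(accept, r_prop, r)
        acc_r += accept

        # --- conjugate Gibbs blocks ---------------------------------------
        w3 = _Phi(z)
        w5 = _Phi(z + signs * r)
        ssr3 = see3 - 2 * w3 * sed3 + w3 * w3 * sdd3
        ssr5 = see5 - 2 * w5 * sed5 + w5 * w5 * sdd5
        tau3 = rng.gamma(1.0 + 0.5 * n3, 1.0 / (_EXP_RATE + 0.5 * ssr3))
        tau5 = rng.gamma(1.0 + 0.5 * n5, 1.0 / (_EXP_RATE + 0.5 * ssr5))
        prec_m = 1.0 + t * P
        m = rng.normal(t * r.sum() / prec_m, 1.0 / np.sqrt(prec_m))
        t = rng.gamma(1.0 + 0.5 * P,
                      1.0 / (_EXP_RATE + 0.5 * np.sum((r - m) ** 2)))

        # --- interleaved non-centered moves for M and T -------------------
        # Holding the standardized deviations eta = (R - M) sqrt(T) fixed
        # breaks the funnel coupling between the group scale and the
        # effects when T is large (homogeneous reweighting).
        eta = (r - m) * np.sqrt(t)
        lik5_now = lik5(z, r, tau5).sum()
        m_prop = m + scale_m * rng.standard_normal()
        r_prop = m_prop + eta / np.sqrt(t)
        logr = (lik5(z, r_prop, tau5).sum() - lik5_now
                - 0.5 * m_prop**2 + 0.5 * m * m)
        if np.log(rng.uniform()) < logr:
            m, r = m_prop, r_prop
            lik5_now = lik5(z, r, tau5).sum()
            acc_m += 1.0

        lt_prop = np.log(t) + scale_t * rng.standard_normal()
        t_prop = np.exp(lt_prop)
        r_prop = m + eta / np.sqrt(t_prop)
        logr = (lik5(z, r_prop, tau5).sum() - lik5_now
                - _EXP_RATE * (t_prop - t) + (lt_prop - np.log(t)))
        if np.log(rng.uniform()) < logr:
            t, r = t_prop, r_prop
            acc_t += 1.0

        # --- proposal adaptation, burn-in only ----------------------------
        if it < config.n_burnin and (it + 1) % adapt_every == 0:
            scale_z *= np.exp(0.6 * (acc_z / adapt_every - config.target_accept))
            scale_r *= np.exp(0.6 * (acc_r / adapt_every - config.target_accept))
            scale_m *= np.exp(0.6 * (acc_m / adapt_every - config.target_accept))
            scale_t *= np.exp(0.6 * (acc_t / adapt_every - config.target_accept))
            acc_z[:] = 0.0
            acc_r[:] = 0.0
            acc_m = 0.0
            acc_t = 0.0

        k = it - config.n_burnin
        if k >= 0:
            out["W3"][k] = w3
            out["W5"][k] = _Phi(z + signs * r)
            out["R"][k] = r
            out["tau3"][k] = tau3
            out["tau5"][k] = tau5
            out["M"][k] = m
            out["T"][k] = t
    return out


def fit_reweighting(data: ReweightingData,
                    config: McmcConfig | None = None) -> ReweightingPosterior:
    """Fit the two-layer reweighting model by Metropolis-within-Gibbs.

    Burn-in is discarded per chain before pooling; no thinning.  Split
    R-hat and effective sample size are computed for every parameter and a
    warning is raised if R-hat exceeds 1.05 or the ESS of M falls below
    1000 (run longer chains or more of them if so).
    """
    if config is None:
        config = McmcConfig()
    chains = []
    for c in range(config.n_chains):
        rng = substream(config.seed, "reweighting_chain", c)
        chains.append(_run_chain(data, config, rng))
    draws = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}

    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {k: float(np.max(rhat_ds[k].values)) for k in draws}
    ess = {k: float(np.min(ess_ds[k].values)) for k in draws}
    bad = {k: v for k, v in rhat.items() if v > 1.05}
    if bad:
        log.warning("split R-hat above 1.05 for %s; increase n_samples or "
                    "n_chains", bad)
    if ess["M"] < 1000:
        log.warning("effective sample size for M is %.0f (< 1000); "
                    "interval endpoints may be unstable", ess["M"])
    return ReweightingPosterior(draws, data.participants, data.signs.copy(),
                                config, rhat, ess)


def summarize_reweighting(post: ReweightingPosterior) -> dict:
    """Posterior summaries: per-participant weights and effects, the
    central 95% interval for M, and the count of participants whose
    posterior-mean reweighting goes in the predicted direction."""
    rows = []
    for i, pid in enumerate(post.participants):
        w3 = post.flat("W3")[:, i]
        w5 = post.flat("W5")[:, i]
        r = post.flat("R")[:, i]
        rows.append({
            "participant_id": pid,
            "direction": "increased" if post.signs[i] > 0 else "decreased",
            "W3_mean": w3.mean(), "W3_lo": np.percentile(w3, 2.5),
            "W3_hi": np.percentile(w3, 97.5),
            "W5_mean": w5.mean(), "W5_lo": np.percentile(w5, 2.5),
            "W5_hi": np.percentile(w5, 97.5),
            "R_mean": r.mean(), "R_lo": np.percentile(r, 2.5),
            "R_hi": np.percentile(r, 97.5),
        })
    per = pd.DataFrame(rows)
    m = post.flat("M")
    lo, hi = post.m_interval()
    return {
        "participants": per,
        "M_mean": float(m.mean()),
        "M_interval": (lo, hi),
        "M_excludes_zero": bool(lo > 0 or hi < 0),
        "n_predicted_direction": int((per["R_mean"] > 0).sum()),
        "n_participants": len(per),
        "rhat": post.rhat,
        "ess": post.ess,
    }


def label_swap_check(data: ReweightingData,
                     config: McmcConfig | None = None,
                     swap: tuple[list[str], list[str]] | None = None) -> dict:
    """Diagnostic refit after exchanging direction labels across groups.

    By default the latter half of each direction group swaps labels with
    the other.  On direction-consistent data the swapped fit's interval
    for M should include zero while the original excludes it.  Requires at
    least 6 participants per direction group for a meaningful swap.
    """
    groups = {+1: [], -1: []}
    for pid, s in zip(data.participants, data.signs):
        groups[int(s)].append(pid)
    if swap is None:
        if min(len(groups[1]), len(groups[-1])) < 6:
            raise ValueError("need >= 6 participants per direction group")
        half = len(groups[1]) // 2
        swap = (groups[1][half:], groups[-1][half:])
    swap_set = set(swap[0]) | set(swap[1])
    signs = np.array([-s if p in swap_set else s
                      for p, s in zip(data.participants, data.signs)])
    swapped = ReweightingData(data.participants, signs, data.s3, data.s5)
    post0 = fit_reweighting(data, config)
    post1 = fit_reweighting(swapped, config)
    return {
        "original": summarize_reweighting(post0),
        "swapped": summarize_reweighting(post1),
        "swapped_participants": sorted(swap_set),
    }
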