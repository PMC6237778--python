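"""Simulated observers: the synthetic-data generator for the pipeline.

An observer forms a noisy audio percept of the target (Gaussian on the
natural-log distance scale, since echo delays become harder to discriminate
as they lengthen), reads the visual distribution's center exactly (the
visual cue carries external noise by design), and answers according to a
weighting policy — reliability-weighted averaging (ideal), a fixed weight,
trial-by-trial cue switching, single-cue strategies, or no strategy at all
(the untrained control).  A multiplicative bias and log-scale motor noise
are added before the response is clamped to the response line.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._streams import substream
from .design import ParticipantAssignment, log_spaced_targets
from .stimuli import RESPONSE_RANGE

__all__ = [
    "ObserverParams",
    "ideal_weight",
    "simulate_response",
    "simulate_experiment",
    "untrained_baseline_ve",
    "make_cohort",
    "effective_audio_sd",
]

POLICIES = ("ideal", "fixed", "switch", "audio_only", "visual_only", "none")


def ideal_weight(sigma_audio_sq: float, sigma_visual_sq: float) -> float:
    """Reliability weight on vision: sigma_a^2 / (sigma_a^2 + sigma_v^2).

    This is the precision-weighting of the visual cue — the weight a
    minimum-variance (Bayes-optimal) averager gives it.
    """
    sa, sv = np.asarray(sigma_audio_sq, float), np.asarray(sigma_visual_sq, float)
    if np.any(sa <= 0) or np.any(sv <= 0):
        raise ValueError("variances must be positive")
    return sa / (sa + sv)


@dataclass(frozen=True)
class ObserverParams:
    """Generative model of one simulated participant.

    Parameters
    ----------
    sigma_audio_log : float
        SD of internal audio-percept noise, natural-log distance units.
    weighting_policy : str
        One of ``ideal | fixed | switch | audio_only | visual_only | none``.
    w_visual : float, optional
        Weight on vision for the ``fixed`` policy, in [0, 1].
    p_visual : float, optional
        Probability of choosing the visual cue for the ``switch`` policy.
    bias_log : float
        Additive constant error on the log scale (multiplicative in meters).
    motor_sd_log : float
        Extra response noise SD on the log scale, applied to every trial.
    sigma_visual_internal_log : float
        Internal visual noise SD (default 0; the visual cue's noise is
        external, carried by the displayed distribution).
    reliability_known : bool
        Whether ideal weights track each trial's true visual spread; if
        False the observer keeps using ``assumed_visual_sd_log`` (a rote
        learner that does not reweight).
    assumed_visual_sd_log : float, optional
        The visual spread a rote learner assumes (e.g. Session 3's value).
    """

    sigma_audio_log: float = 0.12
    weighting_policy: str = "ideal"
    w_visual: float | None = None
    p_visual: float | None = None
    bias_log: float = 0.0
    motor_sd_log: float = 0.0
    sigma_visual_internal_log: float = 0.0
    reliability_known: bool = True
    assumed_visual_sd_log: float | None = None

    def __post_init__(self):
        if self.weighting_policy not in POLICIES:
            raise ValueError(f"unknown weighting_policy {self.weighting_policy!r}")
        if self.sigma_audio_log <= 0:
            raise ValueError("sigma_audio_log must be positive")
        if self.weighting_policy == "fixed":
            if self.w_visual is None or not (0 <= self.w_visual <= 1):
                raise ValueError("fixed policy needs w_visual in [0, 1]")
        if self.weighting_policy == "switch":
            if self.p_visual is None or not (0 <= self.p_visual <= 1):
                raise ValueError("switch policy needs p_visual in [0, 1]")


def effective_audio_sd(obs: ObserverParams) -> float:
    """SD of the observer's audio-only log response errors (percept + motor)."""
    return float(np.hypot(obs.sigma_audio_log, obs.motor_sd_log))


def _weights_on_vision(obs: ObserverParams, visual_sd_log: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-trial weight on the visual cue for audio-visual trials."""
    n = len(visual_sd_log)
    policy = obs.weighting_policy
    if policy == "ideal":
        sv = visual_sd_log if obs.reliability_known else np.full(
            n, obs.assumed_visual_sd_log
            if obs.assumed_visual_sd_log is not None else np.nan)
        if np.any(~np.isfinite(sv)):
            raise ValueError("reliability_known=False requires assumed_visual_sd_log")
        sv_eff = np.hypot(sv, obs.sigma_visual_internal_log)
        return ideal_weight(obs.sigma_audio_log**2, sv_eff**2)
    if policy == "fixed":
        return np.full(n, float(obs.w_visual))
    if policy == "switch":
        return (rng.uniform(size=n) < obs.p_visual).astype(float)
    if policy == "audio_only":
        return np.zeros(n)
    if policy == "visual_only":
        return np.ones(n)
    raise AssertionError(policy)


def _respond_block(obs: ObserverParams, trials: pd.DataFrame,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized responses (meters) for one participant-session block."""
    lo, hi = RESPONSE_RANGE
    n = len(trials)
    ttype = trials["trial_type"].to_numpy()
    log_t = np.log(trials["target_m"].to_numpy(float))
    resp = np.empty(n)

    a_hat = log_t + rng.normal(0.0, obs.sigma_audio_log, size=n)
    with np.errstate(invalid="ignore"):
        v_center = np.log(trials["visual_center_m"].to_numpy(float))
    if obs.sigma_visual_internal_log > 0:
        v_hat = v_center + rng.normal(0.0, obs.sigma_visual_internal_log, size=n)
    else:
        v_hat = v_center

    is_afc = np.char.startswith(ttype.astype(str), "afc")
    is_audio = ttype == "audio"
    is_visual = ttype == "visual"
    is_av = ttype == "audiovisual"

    if obs.weighting_policy == "none":
        resp[:] = rng.uniform(np.log(lo), np.log(hi), size=n)
    else:
        if obs.weighting_policy == "visual_only" and np.any(is_audio | is_afc):
            raise ValueError("visual_only policy cannot answer audio-only trials")
        if obs.weighting_policy == "audio_only" and np.any(is_visual):
            raise ValueError("audio_only policy cannot answer visual-only trials")
        resp[is_audio] = a_hat[is_audio]
        resp[is_visual] = v_hat[is_visual]
        if np.any(is_av):
            w = _weights_on_vision(obs, trials.loc[is_av, "visual_sd_log"]
                                   .to_numpy(float), rng)
            resp[is_av] = w * v_hat[is_av] + (1 - w) * a_hat[is_av]
        if np.any(is_afc):
            resp[is_afc] = a_hat[is_afc]

    resp = resp + obs.bias_log
    if obs.motor_sd_log > 0:
        resp = resp + rng.normal(0.0, obs.motor_sd_log, size=n)

    out = np.exp(np.clip(resp, np.log(lo), np.log(hi)))

    # forced-choice trials snap to the nearest option on the log grid
    if np.any(is_afc):
        for n_alt in (2, 3, 5):
            mask = ttype == f"afc{n_alt}"
            if not np.any(mask):
                continue
            options = log_spaced_targets(n_alt)
            idx = np.argmin(np.abs(np.log(out[mask])[:, None]
                                   - np.log(options)[None, :]), axis=1)
            out[mask] = options[idx]
    return out


def simulate_response(obs: ObserverParams, trial: dict,
                      rng: np.random.Generator) -> float:
    """Response (meters) to a single trial specification.

    ``trial`` needs ``trial_type`` and ``target_m``, plus
    ``visual_center_m``/``visual_sd_log`` for trials with a visual cue.
    """
    ttype = trial["trial_type"]
    if ttype in ("visual", "audiovisual") and not np.isfinite(
            trial.get("visual_center_m", np.nan)):
        raise ValueError(f"{ttype} trial is missing its visual cue fields")
    row = pd.DataFrame([{
        "trial_type": ttype,
        "target_m": trial["target_m"],
        "visual_center_m": trial.get("visual_center_m", np.nan),
        "visual_sd_log": trial.get("visual_sd_log", np.nan),
    }])
    return float(_respond_block(obs, row, rng)[0])


def _resolve(observers, pid: str, session: int) -> ObserverParams:
    entry = observers[pid]
    if isinstance(entry, ObserverParams):
        return entry
    return entry[session]


def simulate_experiment(observers: dict, design: pd.DataFrame,
                        seed: int = 0) -> pd.DataFrame:
    """Attach a simulated ``response_m`` to every trial of ``design``.

    ``observers`` maps participant_id to an :class:`ObserverParams`, or to
    a ``{session: ObserverParams}`` dict when policies change across
    sessions (e.g. a rote learner in Session 5).  Fully reproducible under
    ``seed``; each participant-session uses its own named substream.
    """
    missing = set(design["participant_id"]) - set(observers)
    if missing:
        raise ValueError(f"no ObserverParams for participants {sorted(missing)}")
    table = design.copy()
    table["response_m"] = np.nan
    for (pid, session), idx in table.groupby(
            ["participant_id", "session"], sort=True).groups.items():
        obs = _resolve(observers, pid, int(session))
        rng = substream(seed, "observer", pid, int(session))
        table.loc[idx, "response_m"] = _respond_block(obs, table.loc[idx], rng)
    return table


def untrained_baseline_ve(targets) -> float:
    """Mean variable error of a responder who always answers the log
    midpoint of the response line (sqrt(10 * 35) m).

    The untrained-control benchmark: performance worse than this indicates
    the responses carry no distance information at all.
    """
    t = np.asarray(targets, dtype=float)
    if t.size == 0:
        raise ValueError("targets must be non-empty")
    lo, hi = RESPONSE_RANGE
    log_err = 0.5 * (np.log(lo) + np.log(hi)) - np.log(t)
    ce = log_err.mean()
    return float(np.mean((log_err - ce) ** 2))


def make_cohort(
    assignments: list[ParticipantAssignment],
    seed: int = 0,
    mean_sigma_audio: float = 0.12,
    sigma_audio_spread: float = 0.15,
    bias_mean: float = -0.024,
    bias_sd: float = 0.06,
    motor_sd_log: float = 0.045,
    policy: str = "ideal",
    **policy_kwargs,
) -> dict[str, ObserverParams]:
    """Draw a heterogeneous cohort of observers.

    Audio noise varies across participants (log-normal around
    ``mean_sigma_audio``), emulating individual differences in how well the
    echo cue was learned; biases are small and slightly negative
    (underestimation), with the spread seen in trained adults.
    """
    rng = substream(seed, "cohort")
    cohort = {}
    for a in assignments:
        sigma = float(np.exp(rng.normal(np.log(mean_sigma_audio),
                                        sigma_audio_spread)))
        bias = float(rng.normal(bias_mean, bias_sd))
        cohort[a.participant_id] = ObserverParams(
            sigma_audio_log=sigma,
            weighting_policy=policy,
            bias_log=bias,
            motor_sd_log=motor_sd_log,
            **policy_kwargs,
        )
    return cohort


def calibrated_assignments(cohort: dict[str, ObserverParams],
                           assignments: list[ParticipantAssignment]
                           ) -> list[ParticipantAssignment]:
    """Set each assignment's audio_sd_log to the observer's true effective
    audio error (percept + motor), as a noiseless stand-in for the
    Session-2 calibration."""
    return [replace(a, audio_sd_log=effective_audio_sd(cohort[a.participant_id]))
            for a in assignments]
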