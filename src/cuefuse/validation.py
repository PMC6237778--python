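"""Simulation studies certifying the analysis pipeline.

Three batteries: (1) type-I error of the matched-pair variable-error
procedure under a sharp no-integration null, (2) parameter recovery for
the reweighting model across generative observer families, and (3) the
per-cell gap between observed audio-visual precision and the
perfect-integrator prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._streams import substream, substream_seed
from . import errors as err
from .design import default_assignments, make_session_design
from .observer import (ObserverParams, effective_audio_sd, ideal_weight,
                       make_cohort, simulate_experiment)
from .reweighting import (McmcConfig, ReweightingData, fit_reweighting,
                          summarize_reweighting)

log = logging.getLogger(__name__)

__all__ = [
    "SimulationReport",
    "type1_error_sim",
    "recovery_battery",
    "optimality_gap",
    "simulate_cohort_table",
]


@dataclass
class SimulationReport:
    """Replicate-level outcomes plus aggregates for one scenario."""

    scenario: str
    n_replicates: int
    outcomes: pd.DataFrame = field(repr=False)
    aggregate: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for k, v in self.aggregate.items():
            if k.startswith("frac_") and not (0 <= v <= 1):
                raise ValueError(f"aggregate fraction {k}={v} outside [0, 1]")


def _null_observers(cohort: dict[str, ObserverParams],
                    assignments) -> dict[str, ObserverParams]:
    """Observers whose audio-visual responses come from the best single
    cue's response process (no integration benefit): weight 1 on whichever
    cue has the lower generative error."""
    out = {}
    by_pid = {a.participant_id: a for a in assignments}
    for pid, obs in cohort.items():
        ratio = by_pid[pid].sd_ratio(3)
        visual_best = ratio < 1.0  # visual sd = ratio * audio error
        out[pid] = ObserverParams(
            sigma_audio_log=obs.sigma_audio_log,
            weighting_policy="fixed",
            w_visual=1.0 if visual_best else 0.0,
            bias_log=obs.bias_log,
            motor_sd_log=obs.motor_sd_log,
        )
    return out


def type1_error_sim(n_replicates: int = 1000, cohort_size: int = 12,
                    triplets_per_session: int = 83, seed: int = 0,
                    alphas: tuple[float, ...] = (0.05, 0.01)
                    ) -> SimulationReport:
    """Type-I error of pairing + sign-rank under the no-integration null.

    Each replicate simulates one session of matched triplets for a
    heterogeneous cohort whose audio-visual responses are drawn from the
    best single cue's response process, runs the full error decomposition,
    best-single-cue pairing and two-tailed sign-rank test, and records the
    p-value.  The aggregate reports the fraction of replicates significant
    at each alpha.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    ps = np.empty(n_replicates)
    zs = np.empty(n_replicates)
    for rep in range(n_replicates):
        rep_seed = substream_seed(seed, "type1", rep)
        assignments = default_assignments(cohort_size)
        cohort = make_cohort(assignments, seed=rep_seed)
        for a in assignments:
            a.audio_sd_log = effective_audio_sd(cohort[a.participant_id])
        null_obs = _null_observers(cohort, assignments)
        frames = [make_session_design(3, a, seed=rep_seed,
                                      triplet_counts={3: triplets_per_session}
                                      ).trials
                  for a in assignments]
        table = simulate_experiment(null_obs, pd.concat(frames,
                                                        ignore_index=True),
                                    seed=rep_seed)
        pairs = err.pair_av_vs_best(err.add_log_errors(table))
        res = err.signrank_test(pairs["ref_ve"].to_numpy()
                                - pairs["av_ve"].to_numpy())
        ps[rep], zs[rep] = res.p, res.z
    outcomes = pd.DataFrame({"replicate": np.arange(n_replicates),
                             "p": ps, "z": zs})
    aggregate = {f"frac_p_below_{a}": float(np.mean(ps < a)) for a in alphas}
    return SimulationReport("type1_no_integration", n_replicates, outcomes,
                            aggregate, seed)


def simulate_cohort_table(policy: str = "ideal", n_participants: int = 12,
                          sessions: tuple[int, ...] = (3, 4, 5),
                          triplet_counts: dict[int, int] | None = None,
                          seed: int = 0, motor_sd_log: float = 0.045,
                          **policy_kwargs):
    """Convenience: design + simulate Sessions 3-5 for one observer family.

    Returns ``(table, cohort, assignments)``.
    """
    assignments = default_assignments(n_participants)
    cohort = make_cohort(assignments, seed=seed, policy=policy,
                         motor_sd_log=motor_sd_log, **policy_kwargs)
    for a in assignments:
        a.audio_sd_log = effective_audio_sd(cohort[a.participant_id])
    frames = [make_session_design(s, a, seed=seed,
                                  triplet_counts=triplet_counts).trials
              for a in assignments for s in sessions]
    table = simulate_experiment(cohort, pd.concat(frames, ignore_index=True),
                                seed=seed)
    return table, cohort, assignments


_SCENARIOS = {
    "ideal": dict(policy="ideal"),
    "fixed_0.1": dict(policy="fixed", w_visual=0.1),
    "fixed_0.3": dict(policy="fixed", w_visual=0.3),
    "fixed_0.5": dict(policy="fixed", w_visual=0.5),
    "fixed_0.7": dict(policy="fixed", w_visual=0.7),
    "fixed_0.9": dict(policy="fixed", w_visual=0.9),
    "switch_0.5": dict(policy="switch", p_visual=0.5),
    "w0": dict(policy="fixed", w_visual=0.0),
}


def _generative_w3(cohort, assignments) -> dict[str, float]:
    """The weight each generative observer actually places on vision in
    Session 3 (expected value for the switch policy)."""
    out = {}
    for a in assignments:
        obs = cohort[a.participant_id]
        if obs.weighting_policy == "fixed":
            out[a.participant_id] = obs.w_visual
        elif obs.weighting_policy == "switch":
            out[a.participant_id] = obs.p_visual
        else:
            sv = a.sd_ratio(3) * a.audio_sd_log
            out[a.participant_id] = float(ideal_weight(obs.sigma_audio_log**2,
                                                       sv**2))
    return out


def recovery_battery(scenarios=("ideal", "fixed_0.3", "fixed_0.7",
                                "switch_0.5", "w0"),
                     seed: int = 0, n_participants: int = 12,
                     triplets: int = 83,
                     mcmc: McmcConfig | None = None) -> SimulationReport:
    """Parameter recovery and contrast behavior per generative scenario.

    For each observer family: simulate Sessions 3 and 5, fit the
    reweighting model, and compare inferred Session-3 weights with the
    generative ones (bias, RMSE, coverage of the 95% intervals); also run
    both paired contrasts.
    """
    if mcmc is None:
        mcmc = McmcConfig(n_chains=3, n_samples=4000, n_burnin=1500, seed=seed)
    rows = []
    for scen in scenarios:
        kwargs = dict(_SCENARIOS[scen])
        policy = kwargs.pop("policy")
        scen_seed = substream_seed(seed, "recovery", scen)
        table, cohort, assignments = simulate_cohort_table(
            policy=policy, n_participants=n_participants,
            sessions=(3, 5), triplet_counts={3: triplets, 5: triplets},
            seed=scen_seed, **kwargs)
        directions = {a.participant_id: a.direction for a in assignments}
        data = ReweightingData.from_table(table, directions)
        post = fit_reweighting(data, McmcConfig(
            n_chains=mcmc.n_chains, n_samples=mcmc.n_samples,
            n_burnin=mcmc.n_burnin, seed=scen_seed))
        summary = summarize_reweighting(post)
        truth = _generative_w3(cohort, assignments)
        per = summary["participants"].set_index("participant_id")
        errs = np.array([per.loc[p, "W3_mean"] - truth[p] for p in truth])
        covered = np.mean([
            per.loc[p, "W3_lo"] <= truth[p] <= per.loc[p, "W3_hi"]
            for p in truth])
        best = err.paired_contrast(table, "best", n_boot=1000, seed=scen_seed)
        opt = err.paired_contrast(table, "optimal", n_boot=1000,
                                  seed=scen_seed)
        rows.append({
            "scenario": scen,
            "w3_bias": float(errs.mean()),
            "w3_rmse": float(np.sqrt(np.mean(errs**2))),
            "w3_coverage": float(covered),
            "M_mean": summary["M_mean"],
            "M_lo": summary["M_interval"][0],
            "M_hi": summary["M_interval"][1],
            "best_p": best.p, "best_effect_pct": best.ve_change_pct,
            "best_z": best.z,
            "optimal_p": opt.p, "optimal_effect_pct": opt.ve_change_pct,
        })
    outcomes = pd.DataFrame(rows)
    aggregate = {"max_w3_rmse": float(outcomes["w3_rmse"].max())}
    return SimulationReport("recovery_battery", len(rows), outcomes,
                            aggregate, seed)


def optimality_gap(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell ratio of audio-visual mean VE to the perfect-integrator
    prediction (1 = optimal; > 1 = falling short).  Cells missing a trial
    type are skipped."""
    summaries = err.summarize_errors(table)
    wide = summaries.pivot_table(index=["participant_id", "session"],
                                 columns="trial_type",
                                 values="mean_variable_error")
    missing = wide.isna().any(axis=1)
    if missing.any():
        log.warning("skipping %d cells missing a trial type",
                    int(missing.sum()))
        wide = wide.loc[~missing]
    pred = err.optimal_variance(wide["audio"].to_numpy(),
                                wide["visual"].to_numpy())
    out = wide.reset_index()[["participant_id", "session"]]
    out["av_ve"] = wide["audiovisual"].to_numpy()
    out["optimal_ve"] = pred
    out["ratio"] = out["av_ve"] / out["optimal_ve"]
    return out
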