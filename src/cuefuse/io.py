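"""Trial-table I/O, run configuration, and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import errors as err
from . import validation
from ._streams import substream_seed
from .design import TRIAL_COLUMNS, default_assignments, make_session_design
from .observer import effective_audio_sd, make_cohort, simulate_experiment
from .reweighting import (McmcConfig, ReweightingData, fit_reweighting,
                          summarize_reweighting)
from .stimuli import RESPONSE_RANGE

log = logging.getLogger(__name__)

__all__ = [
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "RunConfig",
    "run_pipeline",
]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


class TrialValidationError(ValueError):
    """Raised when a trial table violates the dialect; lists offending rows."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        shown = "\n  ".join(problems[:20])
        extra = "" if len(problems) <= 20 else f"\n  ... {len(problems) - 20} more"
        super().__init__(f"invalid trial table:\n  {shown}{extra}")


def _validate_trials(df: pd.DataFrame) -> None:
    problems: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError([f"missing columns: {missing}"])
    lo, hi = RESPONSE_RANGE
    bad_t = ~df["target_m"].between(lo, hi)
    for i in df.index[bad_t]:
        problems.append(f"row {i}: target_m {df.at[i, 'target_m']} outside "
                        f"[{lo}, {hi}]")
    if "response_m" in df.columns:
        resp = df["response_m"]
        bad_r = resp.notna() & ~resp.between(lo, hi)
        for i in df.index[bad_r]:
            problems.append(f"row {i}: response_m {resp[i]} outside "
                            f"[{lo}, {hi}]")
    # visual fields present iff the trial has a visual cue
    has_vis = df["trial_type"].isin(("visual", "audiovisual"))
    for i in df.index[has_vis & df["visual_center_m"].isna()]:
        problems.append(f"row {i}: {df.at[i, 'trial_type']} trial without "
                        "visual_center_m")
    for i in df.index[~has_vis & df["visual_center_m"].notna()]:
        problems.append(f"row {i}: {df.at[i, 'trial_type']} trial carries "
                        "visual_center_m")
    # triplets of main trials must have their three members
    main = df[(df["phase"] == "main") & (df["triplet_id"] != "")]
    if len(main):
        counts = main.groupby(["participant_id", "session",
                               "triplet_id"]).size()
        for key, n in counts[counts != 3].items():
            problems.append(f"triplet {key} has {n} members (expected 3)")
    if problems:
        raise TrialValidationError(problems)


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table in the package's CSV dialect (UTF-8, header)."""
    cols = TRIAL_COLUMNS + (["response_m"] if "response_m" in table.columns
                            else [])
    out = table[cols].copy()
    out["triplet_id"] = out["triplet_id"].fillna("")
    out.to_csv(path, index=False, float_format="%.10g")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; violations raise with row numbers."""
    df = pd.read_csv(path, dtype={"participant_id": str, "triplet_id": str,
                                  "phase": str, "trial_type": str},
                     keep_default_na=True)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError([f"missing columns: {missing}"])
    df["triplet_id"] = df["triplet_id"].fillna("")
    if df["feedback"].dtype == object:
        df["feedback"] = (df["feedback"].astype(str).str.lower()
                          .map(_BOOL_MAP).astype(bool))
    else:
        df["feedback"] = df["feedback"].astype(bool)
    df["session"] = df["session"].astype(int)
    _validate_trials(df)
    return df


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; YAML round-trippable.

    Every stochastic stage derives its stream from ``seed`` via named
    substreams, so a config + seed pair pins the whole run.
    """

    seed: int = 0
    n_participants: int = 12
    sessions: tuple = (1, 2, 3, 4, 5)
    triplet_counts: dict = field(default_factory=lambda: {3: 83, 4: 62, 5: 83})
    afc_counts: dict = field(default_factory=lambda: {2: 50, 3: 100, 5: 150})
    ratio_applies_to: str = "sd"
    # synthetic-cohort parameters
    mean_sigma_audio: float = 0.12
    sigma_audio_spread: float = 0.15
    bias_mean: float = -0.024
    bias_sd: float = 0.06
    motor_sd_log: float = 0.045
    policy: str = "ideal"
    # analysis options
    n_boot: int = 10_000
    calibration: str = "bias_corrected"   # or "raw"
    # MCMC settings (pipeline default is a lighter fit than the 6 x 25k
    # reference configuration; override for publication-scale runs)
    mcmc_chains: int = 4
    mcmc_samples: int = 6000
    mcmc_burnin: int = 2000
    # validation stages
    n_type1_replicates: int = 0   # 0 skips the type-I study
    out_dir: str = "cuefuse_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.triplet_counts = {int(k): int(v)
                              for k, v in cfg.triplet_counts.items()}
        cfg.afc_counts = {int(k): int(v) for k, v in cfg.afc_counts.items()}
        cfg.sessions = tuple(cfg.sessions)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sessions"] = list(self.sessions)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _calibrate_audio_sd(table: pd.DataFrame, method: str) -> dict[str, float]:
    """Per-participant audio error from Session 2's continuous trials.

    ``bias_corrected`` uses the SD of log errors around the participant's
    own mean; ``raw`` uses the root mean square log error.
    """
    s2 = table[(table["session"] == 2) & (table["phase"] == "main")
               & (table["trial_type"] == "audio")]
    out = {}
    for pid, sub in s2.groupby("participant_id"):
        e = np.log(sub["response_m"].to_numpy(float)) \
            - np.log(sub["target_m"].to_numpy(float))
        out[pid] = float(np.std(e, ddof=1) if method == "bias_corrected"
                         else np.sqrt(np.mean(e**2)))
    return out


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Simulate (or analyze) end to end and write the report bundle.

    Stages: simulate Sessions 1-2 and calibrate each participant's audio
    error -> build and simulate Sessions 3-5 -> error summaries -> both
    paired contrasts (omnibus and per session) -> visual-reliance and
    manipulation checks -> reweighting fit -> validation summaries.  All
    artifacts, the log, and a config snapshot land in ``out_dir``.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                      "%(name)s: %(message)s"))
    root = logging.getLogger("cuefuse")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    results: dict = {}
    try:
        config.to_yaml(out / "config.yaml")
        stage = "simulate_training"
        assignments = default_assignments(config.n_participants)
        cohort = make_cohort(
            assignments, seed=config.seed,
            mean_sigma_audio=config.mean_sigma_audio,
            sigma_audio_spread=config.sigma_audio_spread,
            bias_mean=config.bias_mean, bias_sd=config.bias_sd,
            motor_sd_log=config.motor_sd_log, policy=config.policy)
        train_sessions = tuple(s for s in config.sessions if s in (1, 2))
        if train_sessions:
            frames = [make_session_design(
                s, a, seed=config.seed, afc_counts=config.afc_counts,
                ratio_applies_to=config.ratio_applies_to).trials
                for a in assignments for s in train_sessions]
            training = simulate_experiment(
                cohort, pd.concat(frames, ignore_index=True),
                seed=config.seed)
            sd_hat = _calibrate_audio_sd(training, config.calibration)
            for a in assignments:
                a.audio_sd_log = sd_hat[a.participant_id]
            write_trials(training, out / "training_trials.csv")
        else:
            for a in assignments:
                a.audio_sd_log = effective_audio_sd(cohort[a.participant_id])

        stage = "simulate_main"
        main_sessions = tuple(s for s in config.sessions if s >= 3)
        frames = [make_session_design(
            s, a, seed=config.seed, triplet_counts=config.triplet_counts,
            ratio_applies_to=config.ratio_applies_to).trials
            for a in assignments for s in main_sessions]
        table = simulate_experiment(cohort,
                                    pd.concat(frames, ignore_index=True),
                                    seed=config.seed)
        write_trials(table, out / "trials.csv")

        stage = "error_summaries"
        summaries = err.summarize_errors(table)
        summaries.to_csv(out / "error_summaries.csv", index=False,
                         float_format="%.10g")
        results["summaries"] = summaries

        stage = "contrasts"
        t1 = err.table1(table, n_boot=config.n_boot,
                        seed=substream_seed(config.seed, "contrasts"))
        t1.to_csv(out / "contrasts.csv", index=False, float_format="%.10g")
        results["contrasts"] = t1

        stage = "reliance"
        reliance = err.visual_reliance(table)
        reliance.to_csv(out / "visual_reliance.csv", index=False,
                        float_format="%.10g")
        r_vis, n_vis = err.manipulation_check(table, "visual")
        r_av, n_av = err.manipulation_check(table, "audiovisual")
        results["manipulation_check"] = {
            "visual_r": r_vis, "visual_n": n_vis,
            "audiovisual_r": r_av, "audiovisual_n": n_av}

        stage = "optimality_gap"
        gap = validation.optimality_gap(table)
        gap.to_csv(out / "optimality_gap.csv", index=False,
                   float_format="%.10g")
        results["optimality_gap"] = gap

        stage = "reweighting"
        directions = {a.participant_id: a.direction for a in assignments}
        if len(set(directions.values())) < 2:
            msg = ("reweighting fit needs participants in both reliability "
                   "directions; got only "
                   f"{sorted(set(directions.values()))}")
            log.error(msg)
            results["reweighting_error"] = msg
        elif {3, 5} <= set(main_sessions):
            data = ReweightingData.from_table(table, directions)
            post = fit_reweighting(data, McmcConfig(
                n_chains=config.mcmc_chains, n_samples=config.mcmc_samples,
                n_burnin=config.mcmc_burnin,
                seed=substream_seed(config.seed, "mcmc")))
            summary = summarize_reweighting(post)
            summary["participants"].to_csv(out / "reweighting_weights.csv",
                                           index=False, float_format="%.10g")
            js = {k: v for k, v in summary.items() if k != "participants"}
            (out / "reweighting_summary.json").write_text(
                json.dumps(js, indent=2, default=float))
            _write_draws(post, out / "reweighting_draws.csv")
            results["reweighting"] = summary

        if config.n_type1_replicates:
            stage = "type1_simulation"
            rep = validation.type1_error_sim(
                config.n_type1_replicates,
                cohort_size=config.n_participants,
                seed=substream_seed(config.seed, "type1"))
            (out / "type1_report.json").write_text(
                json.dumps({"n_replicates": rep.n_replicates,
                            **rep.aggregate}, indent=2))
            results["type1"] = rep
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
    finally:
        root.removeHandler(fh)
        fh.close()
    return results


def _write_draws(post, path, thin: int = 10) -> None:
    """Posterior draws in long format (chain, iteration, parameter, value),
    thinned for file size."""
    rows = []
    for name, arr in post.draws.items():
        c, s = arr.shape[0], arr.shape[1]
        it = np.arange(0, s, thin)
        for ci in range(c):
            if arr.ndim == 3:
                for pi, pid in enumerate(post.participants):
                    rows.append(pd.DataFrame({
                        "chain": ci, "iteration": it,
                        "parameter": f"{name}[{pid}]",
                        "value": arr[ci, it, pi]}))
            else:
                rows.append(pd.DataFrame({
                    "chain": ci, "iteration": it, "parameter": name,
                    "value": arr[ci, it]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              float_format="%.10g")
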