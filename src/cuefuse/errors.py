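"""Log-scale error decomposition and the matched-pair precision tests.

Responses and targets are compared on the natural-log scale.  For each
participant x session x trial-type cell the signed log error is split into
a constant error (CE, the mean bias) and per-trial variable errors (VE,
squared bias-corrected residuals — the precision component):

    CE = mean(ln response - ln target)
    VE_k = (ln response_k - ln target_k - CE)^2

The headline contrasts pair each audio-visual trial's VE with a reference —
either the VE of the best single cue's trial from the same matched triplet,
or the perfect-integrator prediction (1/sigma_a^2 + 1/sigma_v^2)^-1 built
from the cell's single-cue mean VEs — and test the paired differences with
a two-tailed Wilcoxon sign-rank test.  Effect sizes are percent reductions
in mean VE with percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._streams import substream

log = logging.getLogger(__name__)

__all__ = [
    "constant_error",
    "variable_error",
    "add_log_errors",
    "summarize_errors",
    "best_single_cue",
    "pair_av_vs_best",
    "pair_av_vs_optimal",
    "signrank_test",
    "SignRankResult",
    "ve_change",
    "optimal_variance",
    "paired_contrast",
    "PairedComparison",
    "table1",
    "visual_reliance",
    "alternative_error_metrics",
    "manipulation_check",
    "ve_to_sd_fraction",
]

MAIN_TYPES = ("audio", "visual", "audiovisual")


def constant_error(targets, responses) -> float:
    """Mean signed log error — the bias component (log units)."""
    t = np.asarray(targets, float)
    r = np.asarray(responses, float)
    if t.size == 0:
        raise ValueError("need at least one trial")
    if np.any(t <= 0) or np.any(r <= 0):
        raise ValueError("targets and responses must be positive")
    return float(np.mean(np.log(r) - np.log(t)))


def variable_error(targets, responses, ce: float) -> np.ndarray:
    """Per-trial squared bias-corrected log errors (squared log units).

    ``ce`` must be the constant error of the same cell; residuals then
    average to zero and the VEs isolate the precision component.
    """
    t = np.asarray(targets, float)
    r = np.asarray(responses, float)
    return (np.log(r) - np.log(t) - ce) ** 2


def ve_to_sd_fraction(ve: float) -> float:
    """Response SD as a fraction of target distance for a given mean VE.

    A VE of 0.01 (log units squared) is an SD of 0.1 log units, i.e.
    e^0.1 - 1 ~ 10.5% of the subject-target distance.
    """
    return float(np.expm1(np.sqrt(ve)))


def _main_trials(table: pd.DataFrame) -> pd.DataFrame:
    m = (table["phase"] == "main") & table["trial_type"].isin(MAIN_TYPES)
    out = table.loc[m]
    if out["response_m"].isna().any():
        raise ValueError("main trials with missing responses")
    return out


def add_log_errors(table: pd.DataFrame) -> pd.DataFrame:
    """Main continuous trials with ``log_error``, cell ``ce`` and per-trial
    ``ve`` columns attached.  Warm-up, preview and forced-choice trials are
    excluded.  Cells with fewer than 2 trials are dropped with a warning."""
    df = _main_trials(table).copy()
    df["log_error"] = np.log(df["response_m"]) - np.log(df["target_m"])
    cell = ["participant_id", "session", "trial_type"]
    sizes = df.groupby(cell)["log_error"].transform("size")
    if np.any(sizes < 2):
        small = df.loc[sizes < 2, cell].drop_duplicates()
        log.warning("excluding %d cells with < 2 trials", len(small))
        df = df.loc[sizes >= 2]
    df["ce"] = df.groupby(cell)["log_error"].transform("mean")
    df["ve"] = (df["log_error"] - df["ce"]) ** 2
    return df


def summarize_errors(table: pd.DataFrame) -> pd.DataFrame:
    """One row per participant x session x trial-type cell.

    Columns: ``constant_error``, ``mean_variable_error``, ``n_trials``.
    The standard 12-participant, 3-session, 3-type design yields 108 cells
    (one bias correction each).
    """
    df = table if "ve" in table.columns else add_log_errors(table)
    cell = ["participant_id", "session", "trial_type"]
    out = (df.groupby(cell)
             .agg(constant_error=("ce", "first"),
                  mean_variable_error=("ve", "mean"),
                  n_trials=("ve", "size"))
             .reset_index())
    return out


def best_single_cue(summaries: pd.DataFrame, participant_id, session) -> str:
    """The single-cue modality with the lower mean VE for one cell.

    Ties break toward audio (and are logged); both modalities must exist.
    """
    sub = summaries[(summaries["participant_id"] == participant_id)
                    & (summaries["session"] == session)]
    ve = sub.set_index("trial_type")["mean_variable_error"]
    for m in ("audio", "visual"):
        if m not in ve.index:
            raise ValueError(f"missing {m} summary for {participant_id} "
                             f"session {session}")
    if ve["audio"] == ve["visual"]:
        log.info("best-single-cue tie for %s session %s; choosing audio",
                 participant_id, session)
        return "audio"
    return "audio" if ve["audio"] < ve["visual"] else "visual"


def _best_map(summaries: pd.DataFrame) -> pd.DataFrame:
    """participant x session table of the best single cue."""
    wide = summaries.pivot_table(index=["participant_id", "session"],
                                 columns="trial_type",
                                 values="mean_variable_error")
    wide = wide.dropna(subset=["audio", "visual"])
    best = np.where(wide["audio"] <= wide["visual"], "audio", "visual")
    return pd.DataFrame({"best_cue": best}, index=wide.index).reset_index()


def pair_av_vs_best(table: pd.DataFrame,
                    summaries: pd.DataFrame | None = None) -> pd.DataFrame:
    """Match each audio-visual trial's VE with the best single cue's VE.

    The reference is the VE of the best-single-cue trial from the *same
    triplet* (same target, participant, session), so the only difference
    across a pair is the presence of the second, worse cue.  Returns one
    row per audio-visual main trial with ``ref_ve`` and ``av_ve``.
    """
    df = table if "ve" in table.columns else add_log_errors(table)
    if summaries is None:
        summaries = summarize_errors(df)
    best = _best_map(summaries)
    keys = ["participant_id", "session", "triplet_id"]
    av = df[df["trial_type"] == "audiovisual"]
    single = df[df["trial_type"].isin(("audio", "visual"))]
    single = single.merge(best, on=["participant_id", "session"])
    ref = single[single["trial_type"] == single["best_cue"]]
    pairs = av.merge(ref[keys + ["ve"]].rename(columns={"ve": "ref_ve"}),
                     on=keys, how="left", validate="one_to_one")
    broken = pairs["ref_ve"].isna()
    if broken.any():
        log.warning("skipping %d audio-visual trials with broken triplets",
                    int(broken.sum()))
        pairs = pairs.loc[~broken]
    out = pairs[keys + ["target_m", "ref_ve"]].copy()
    out["av_ve"] = pairs["ve"].to_numpy()
    return out.reset_index(drop=True)


def optimal_variance(sigma_audio_sq, sigma_visual_sq):
    """Minimum-variance (perfect Bayes) prediction:
    (sigma_a^-2 + sigma_v^-2)^-1.  Never exceeds the smaller input."""
    sa = np.asarray(sigma_audio_sq, float)
    sv = np.asarray(sigma_visual_sq, float)
    if np.any(sa <= 0) or np.any(sv <= 0):
        raise ValueError("variances must be positive")
    res = 1.0 / (1.0 / sa + 1.0 / sv)
    return float(res) if res.ndim == 0 else res


def pair_av_vs_optimal(table: pd.DataFrame,
                       summaries: pd.DataFrame | None = None) -> pd.DataFrame:
    """Match each audio-visual trial's VE with the perfect-integrator
    reference for its triplet.

    The reference for trial k is the best single cue's VE from the same
    triplet, rescaled by (optimal cell variance / best-single cell mean
    VE), so that within each participant-session the reference averages
    exactly to the optimal variance built from the cell's single-cue mean
    VEs while keeping the skewed per-trial distribution of squared errors.
    A constant reference at the cell mean would bias the sign-rank test:
    squared errors have their median well below their mean, so even an
    exactly optimal observer would be flagged as "beating" the prediction.
    """
    df = table if "ve" in table.columns else add_log_errors(table)
    if summaries is None:
        summaries = summarize_errors(df)
    pairs = pair_av_vs_best(df, summaries)
    wide = summaries.pivot_table(index=["participant_id", "session"],
                                 columns="trial_type",
                                 values="mean_variable_error")
    wide = wide.dropna(subset=["audio", "visual"])
    best_mean = np.minimum(wide["audio"].to_numpy(), wide["visual"].to_numpy())
    opt = optimal_variance(wide["audio"].to_numpy(), wide["visual"].to_numpy())
    scale = pd.DataFrame({"opt_scale": opt / best_mean}, index=wide.index)
    out = pairs.merge(scale.reset_index(), on=["participant_id", "session"])
    out["ref_ve"] = out["ref_ve"] * out["opt_scale"]
    return out.drop(columns="opt_scale")


@dataclass
class SignRankResult:
    z: float
    p: float
    n: int
    method: str


def _exact_signrank_p(ranks2: np.ndarray, w2_plus: int) -> float:
    """Two-tailed exact p for the signed-rank statistic.

    ``ranks2`` are the (tie-averaged) ranks doubled to integers; the null
    distribution of the doubled positive-rank sum is built by dynamic
    programming over all 2^n sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    counts /= counts.sum()
    p_le = counts[: w2_plus + 1].sum()
    p_ge = counts[w2_plus:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def signrank_test(differences) -> SignRankResult:
    """Two-tailed Wilcoxon sign-rank test on paired differences.

    Zero differences are dropped.  For n <= 25 the p-value comes from exact
    enumeration of the signed-rank distribution (valid with ties); for
    larger n a normal approximation with tie and continuity corrections is
    used.  The z statistic is signed: positive when differences tend to be
    positive.
    """
    d = np.asarray(differences, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        log.warning("all paired differences are zero")
        return SignRankResult(z=0.0, p=1.0, n=0, method="degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return SignRankResult(z=0.0, p=1.0, n=n, method="degenerate")
    cc = 0.5 * np.sign(w_plus - mu)
    z = (w_plus - mu - cc) / np.sqrt(var)
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _exact_signrank_p(ranks2, int(round(2 * w_plus)))
        return SignRankResult(z=float(z), p=p, n=n, method="exact")
    p = 2.0 * stats.norm.sf(abs(z))
    return SignRankResult(z=float(z), p=float(p), n=n, method="approx")


def ve_change(pairs: pd.DataFrame, n_boot: int = 10_000,
              seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Effect size: percent reduction of the smaller mean VE below the
    larger, with a percentile-bootstrap 95% CI over pairs.

    effect = 100 * (1 - min(m_ref, m_av) / max(m_ref, m_av)) where m are
    the two mean VEs across pairs.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    ref = pairs["ref_ve"].to_numpy(float)
    av = pairs["av_ve"].to_numpy(float)
    n = len(ref)
    if n == 0:
        raise ValueError("no pairs")

    def effect(m1, m2):
        lo = np.minimum(m1, m2)
        hi = np.maximum(m1, m2)
        if np.any(hi == 0):
            raise ValueError("zero mean variable error; effect undefined")
        return 100.0 * (1.0 - lo / hi)

    point = float(effect(ref.mean(), av.mean()))
    rng = substream(seed, "ve_change_bootstrap")
    boots = np.empty(n_boot)
    chunk = max(1, int(2e7) // n)
    for start in range(0, n_boot, chunk):
        k = min(chunk, n_boot - start)
        idx = rng.integers(0, n, size=(k, n))
        boots[start:start + k] = effect(ref[idx].mean(axis=1),
                                        av[idx].mean(axis=1))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return point, ci


@dataclass
class PairedComparison:
    """One matched-pair contrast, Table-1 style."""

    label: str
    n_pairs: int
    z: float
    p: float
    ve_change_pct: float
    ci95: tuple[float, float]


def paired_contrast(table: pd.DataFrame, contrast: str = "best",
                    sessions=None, n_boot: int = 10_000,
                    seed: int = 0) -> PairedComparison:
    """Run one full contrast: pairing, sign-rank test, effect size.

    ``contrast='best'`` compares audio-visual VE against the best single
    cue (differences ref - av; positive z means the bimodal condition is
    more precise).  ``contrast='optimal'`` compares against the
    perfect-integrator prediction (negative z means performance falls
    short of optimal).
    """
    df = table if "ve" in table.columns else add_log_errors(table)
    if sessions is not None:
        df = df[df["session"].isin(sessions)]
    pairer = {"best": pair_av_vs_best, "optimal": pair_av_vs_optimal}[contrast]
    pairs = pairer(df)
    res = signrank_test(pairs["ref_ve"].to_numpy() - pairs["av_ve"].to_numpy())
    eff, ci = ve_change(pairs, n_boot=n_boot, seed=seed)
    label = {"best": "Best Single vs Audio-Visual",
             "optimal": "Audio-Visual vs Optimal"}[contrast]
    return PairedComparison(label, len(pairs), res.z, res.p, eff, ci)


def table1(table: pd.DataFrame, n_boot: int = 10_000,
           seed: int = 0) -> pd.DataFrame:
    """Both contrasts for the omnibus data and per session."""
    df = add_log_errors(table)
    groupings = [("Omnibus", None)] + [
        (f"Session {s}", (s,)) for s in sorted(df["session"].unique())
    ]
    rows = []
    for name, sess in groupings:
        for contrast in ("best", "optimal"):
            c = paired_contrast(df, contrast, sessions=sess,
                                n_boot=n_boot, seed=seed)
            rows.append({"grouping": name, "contrast": c.label,
                         "n_pairs": c.n_pairs, "z": c.z, "p": c.p,
                         "ve_change_pct": c.ve_change_pct,
                         "ci_low": c.ci95[0], "ci_high": c.ci95[1]})
    return pd.DataFrame(rows)


def visual_reliance(table: pd.DataFrame) -> pd.DataFrame:
    """Mean |ln response - ln visual center| over audio-visual main trials,
    per participant-session.  Lower values = responses hug the visual cue
    = stronger reliance on vision."""
    df = _main_trials(table)
    av = df[df["trial_type"] == "audiovisual"]
    if len(av) == 0:
        raise ValueError("no audio-visual trials")
    d = np.abs(np.log(av["response_m"].to_numpy(float))
               - np.log(av["visual_center_m"].to_numpy(float)))
    out = (av.assign(reliance=d)
             .groupby(["participant_id", "session"])
             .agg(reliance=("reliance", "mean"),
                  visual_sd_log=("visual_sd_log", "first"),
                  n_trials=("reliance", "size"))
             .reset_index())
    return out


def alternative_error_metrics(table: pd.DataFrame, mode: str,
                              n_boot: int = 10_000, seed: int = 0):
    """Robustness variants of the main contrast.

    ``mode='total_error'``: per-trial squared log error without the CE
    correction, paired exactly like the main analysis.
    ``mode='mean_ve'``: one mean audio-visual VE and one mean best-single
    VE per participant (12 pairs in the standard design), sign-rank tested.
    """
    df = add_log_errors(table)
    if mode == "total_error":
        df = df.copy()
        df["ve"] = df["log_error"] ** 2
        return paired_contrast(df, "best", n_boot=n_boot, seed=seed)
    if mode == "mean_ve":
        pairs = pair_av_vs_best(df)
        per = (pairs.groupby("participant_id")[["ref_ve", "av_ve"]]
               .mean().reset_index())
        res = signrank_test(per["ref_ve"].to_numpy() - per["av_ve"].to_numpy())
        eff, ci = ve_change(per, n_boot=n_boot, seed=seed)
        return PairedComparison("Best Single vs Audio-Visual (participant means)",
                                len(per), res.z, res.p, eff, ci)
    raise ValueError(f"unknown mode {mode!r}")


def manipulation_check(table: pd.DataFrame,
                       trial_type: str = "visual") -> tuple[float, int]:
    """Pearson correlation between displayed visual variance and observed
    mean VE across participant-sessions (the check that the reliability
    manipulation changed performance as intended)."""
    df = add_log_errors(table)
    df = df[df["session"].isin((3, 5))]
    cells = (df[df["trial_type"] == trial_type]
             .groupby(["participant_id", "session"])
             .agg(ve=("ve", "mean"), vsd=("visual_sd_log", "first"))
             .dropna())
    r, _ = stats.pearsonr(cells["vsd"] ** 2, cells["ve"])
    return float(r), len(cells)
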