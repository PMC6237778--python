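"""Trial-design generation: target grids, matched triplets, and sessions.

The experiment runs five one-hour sessions per participant.  Sessions 1-2
train the audio cue (forced-choice, then continuous responses with
feedback).  Sessions 3-5 present matched triplets — audio-only,
visual-only, and audio-visual trials generated from one audio-visual
specification — so that single- and dual-cue precision can be compared on
identical targets.  Session 4 swaps the click frequency (feedback removed
on trials with the new sound); Session 5 swaps the visual reliability
(feedback removed on audio-visual trials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._streams import substream
from .stimuli import RESPONSE_RANGE

log = logging.getLogger(__name__)

__all__ = [
    "TRIAL_COLUMNS",
    "TripletDesign",
    "SessionDesign",
    "ParticipantAssignment",
    "log_spaced_targets",
    "make_triplet_block",
    "make_session_design",
    "make_experiment_design",
    "default_assignments",
]

#: Column order of the trial-table dialect used throughout the package.
TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "phase",
    "trial_type",
    "triplet_id",
    "target_m",
    "visual_center_m",
    "visual_sd_log",
    "audio_freq_hz",
    "feedback",
]

#: Standard per-session counts: AFC blocks in Session 1, continuous audio
#: trials in Session 2, matched triplets in Sessions 3-5.
AFC_COUNTS = {2: 50, 3: 100, 5: 150}
S2_CONTINUOUS = 250
TRIPLETS = {3: 83, 4: 62, 5: 83}
WARMUP_TRIALS = 40
PREVIEW_TRIALS = 10


def log_spaced_targets(n: int, lo: float = RESPONSE_RANGE[0],
                       hi: float = RESPONSE_RANGE[1]) -> np.ndarray:
    """``n`` target distances spaced evenly on a log scale over [lo, hi]."""
    if n < 2:
        raise ValueError("need at least 2 targets")
    if not (0 < lo < hi):
        raise ValueError("require 0 < lo < hi")
    return np.exp(np.linspace(np.log(lo), np.log(hi), n))


@dataclass
class TripletDesign:
    """One audio-visual specification, expanded to three matched trials."""

    triplet_id: str
    target_m: float
    visual_center_m: float
    visual_sd_log: float
    audio_freq_hz: float

    def expand(self, participant_id: str, session: int,
               feedback: dict[str, bool]) -> list[dict]:
        """The matched audio / visual / audio-visual trial rows.

        Single-cue trials simply drop the unused cue; everything else in
        the triplet is shared.
        """
        rows = []
        for ttype in ("audio", "visual", "audiovisual"):
            has_visual = ttype in ("visual", "audiovisual")
            has_audio = ttype in ("audio", "audiovisual")
            rows.append({
                "participant_id": participant_id,
                "session": session,
                "phase": "main",
                "trial_type": ttype,
                "triplet_id": self.triplet_id,
                "target_m": self.target_m,
                "visual_center_m": self.visual_center_m if has_visual else np.nan,
                "visual_sd_log": self.visual_sd_log if has_visual else np.nan,
                "audio_freq_hz": self.audio_freq_hz if has_audio else np.nan,
                "feedback": feedback[ttype],
            })
        return rows


def make_triplet_block(
    n_triplets: int,
    audio_sd_log: float,
    sd_ratio: float = 0.75,
    freq: float = 4000.0,
    seed: int = 0,
    ratio_applies_to: str = "sd",
    rng: np.random.Generator | None = None,
    id_prefix: str = "t",
) -> list[TripletDesign]:
    """Generate matched-triplet specifications.

    Visual-distribution centers are spaced evenly on a log scale across the
    response line; the visual spread is ``sd_ratio`` times the
    participant's audio error (on the SD scale by default, or on the
    variance scale with ``ratio_applies_to='variance'``); each target is an
    actual draw from the displayed distribution, redrawn (not clipped) if
    it falls off the response line.
    """
    if n_triplets <= 0:
        raise ValueError("n_triplets must be positive")
    if audio_sd_log <= 0:
        raise ValueError("audio_sd_log must be positive")
    if ratio_applies_to == "sd":
        visual_sd = sd_ratio * audio_sd_log
    elif ratio_applies_to == "variance":
        visual_sd = np.sqrt(sd_ratio) * audio_sd_log
    else:
        raise ValueError("ratio_applies_to must be 'sd' or 'variance'")
    if rng is None:
        rng = np.random.default_rng(seed)

    lo, hi = RESPONSE_RANGE
    # Inset the center grid so the displayed distribution (~ +/- 3 SD) and
    # its target draws stay on the response line; targets are then actual
    # draws from the display with only negligible (> 3 sigma) redraws.
    margin = min(3.0 * visual_sd, 0.45 * (np.log(hi) - np.log(lo)))
    c_lo, c_hi = lo * np.exp(margin), hi * np.exp(-margin)
    centers = log_spaced_targets(n_triplets, c_lo, c_hi) if n_triplets >= 2 \
        else np.array([np.sqrt(lo * hi)])
    redraws = 0
    triplets = []
    for i, c in enumerate(centers):
        while True:
            target = float(np.exp(rng.normal(np.log(c), visual_sd)))
            if lo <= target <= hi:
                break
            redraws += 1
        triplets.append(TripletDesign(
            triplet_id=f"{id_prefix}{i:03d}",
            target_m=target,
            visual_center_m=float(c),
            visual_sd_log=float(visual_sd),
            audio_freq_hz=float(freq),
        ))
    if redraws:
        log.info("redrew %d off-line targets for %d triplets", redraws, n_triplets)
    return triplets


@dataclass
class ParticipantAssignment:
    """Counterbalancing for one participant.

    Half the cohort starts with the 4000 Hz click and switches to 2000 Hz
    in Session 4 (the rest vice versa); half sees the narrow visual cue
    (sd_ratio 0.75) in Sessions 3-4 and the wide one (1.25) in Session 5
    (the rest vice versa).  ``direction`` records whether the visual cue's
    reliability decreased or increased from Session 3 to Session 5.
    """

    participant_id: str
    freq_initial: float
    freq_new: float
    sd_ratio_s34: float
    sd_ratio_s5: float
    audio_sd_log: float = 0.12

    @property
    def direction(self) -> str:
        return "decreased" if self.sd_ratio_s5 > self.sd_ratio_s34 else "increased"

    def freq(self, session: int) -> float:
        return self.freq_new if session == 4 else self.freq_initial

    def sd_ratio(self, session: int) -> float:
        return self.sd_ratio_s5 if session == 5 else self.sd_ratio_s34


def default_assignments(n_participants: int = 12,
                        audio_sd_log: float | list[float] = 0.12
                        ) -> list[ParticipantAssignment]:
    """Balanced counterbalancing over frequency order and sd-ratio order."""
    sds = np.broadcast_to(np.asarray(audio_sd_log, dtype=float),
                          (n_participants,))
    out = []
    for p in range(n_participants):
        narrow_first = p < n_participants / 2
        out.append(ParticipantAssignment(
            participant_id=f"P{p + 1:02d}",
            freq_initial=4000.0 if p % 2 == 0 else 2000.0,
            freq_new=2000.0 if p % 2 == 0 else 4000.0,
            sd_ratio_s34=0.75 if narrow_first else 1.25,
            sd_ratio_s5=1.25 if narrow_first else 0.75,
            audio_sd_log=float(sds[p]),
        ))
    return out


@dataclass
class SessionDesign:
    """Ordered trial list for one participant-session."""

    session_id: int
    participant_id: str
    trials: pd.DataFrame = field(repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _afc_rows(participant_id: str, session: int, freq: float,
              counts: dict[int, int], phase: str,
              rng: np.random.Generator) -> list[dict]:
    """Forced-choice trials: targets drawn as evenly as possible from the
    option grid (2AFC: line endpoints; 3AFC adds the log midpoint; 5AFC
    adds the 25% and 75% log points)."""
    lo, hi = RESPONSE_RANGE
    rows = []
    for n_alt, count in counts.items():
        options = log_spaced_targets(n_alt, lo, hi) if n_alt > 1 else [lo]
        reps = np.tile(options, count // n_alt + 1)[:count]
        rng.shuffle(reps)
        for t in reps:
            rows.append({
                "participant_id": participant_id,
                "session": session,
                "phase": phase,
                "trial_type": f"afc{n_alt}",
                "triplet_id": "",
                "target_m": float(t),
                "visual_center_m": np.nan,
                "visual_sd_log": np.nan,
                "audio_freq_hz": freq,
                "feedback": True,
            })
    return rows


def _warmup_rows(participant_id: str, session: int, freq: float,
                 rng: np.random.Generator) -> list[dict]:
    # 40 reminder trials mixing 2-, 3- and 5-alternative choices
    return _afc_rows(participant_id, session, freq,
                     {2: 10, 3: 12, 5: 18}, "warmup", rng)


def _feedback_rules(session: int) -> dict[str, bool]:
    if session == 3:
        return {"audio": True, "visual": True, "audiovisual": True}
    if session == 4:  # no feedback on trials containing the new sound
        return {"audio": False, "visual": True, "audiovisual": False}
    if session == 5:  # no feedback on bimodal trials
        return {"audio": True, "visual": True, "audiovisual": False}
    raise ValueError(f"no feedback rules for session {session}")


def make_session_design(
    session_id: int,
    assignment: ParticipantAssignment,
    seed: int = 0,
    triplet_counts: dict[int, int] | None = None,
    afc_counts: dict[int, int] | None = None,
    ratio_applies_to: str = "sd",
) -> SessionDesign:
    """Build the ordered trial list for one participant-session.

    Warm-up and preview trials are flagged by ``phase`` and excluded from
    analysis downstream; main-trial order is randomized under the seed.
    """
    if session_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown session_id {session_id!r}")
    pid = assignment.participant_id
    rng = substream(seed, "design", pid, session_id)
    triplet_counts = dict(TRIPLETS if triplet_counts is None else triplet_counts)
    afc_counts = dict(AFC_COUNTS if afc_counts is None else afc_counts)
    freq = assignment.freq(session_id)
    rows: list[dict] = []

    if session_id == 1:
        # blocks run in increasing difficulty and are not interleaved
        for n_alt in sorted(afc_counts):
            rows += _afc_rows(pid, 1, freq, {n_alt: afc_counts[n_alt]},
                              "main", rng)
    elif session_id == 2:
        rows += _warmup_rows(pid, 2, freq, rng)
        targets = log_spaced_targets(S2_CONTINUOUS)
        rng.shuffle(targets)
        for t in targets:
            rows.append({
                "participant_id": pid, "session": 2, "phase": "main",
                "trial_type": "audio", "triplet_id": "",
                "target_m": float(t), "visual_center_m": np.nan,
                "visual_sd_log": np.nan, "audio_freq_hz": freq,
                "feedback": True,
            })
        rows += _preview_rows(pid, 2, assignment, rng, ratio_applies_to)
    else:
        rows += _warmup_rows(pid, session_id, freq, rng)
        triplets = make_triplet_block(
            triplet_counts[session_id], assignment.audio_sd_log,
            sd_ratio=assignment.sd_ratio(session_id), freq=freq,
            rng=rng, ratio_applies_to=ratio_applies_to,
            id_prefix=f"{pid}s{session_id}_",
        )
        feedback = _feedback_rules(session_id)
        main: list[dict] = []
        for tr in triplets:
            main += tr.expand(pid, session_id, feedback)
        order = rng.permutation(len(main))
        rows += [main[i] for i in order]
        if session_id in (3, 4):
            rows += _preview_rows(pid, session_id, assignment, rng,
                                  ratio_applies_to)

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SessionDesign(session_id, pid, df)


def _preview_rows(participant_id: str, session: int,
                  assignment: ParticipantAssignment,
                  rng: np.random.Generator,
                  ratio_applies_to: str) -> list[dict]:
    """10 closing trials introducing what the next session will look like."""
    nxt = session + 1
    triplets = make_triplet_block(
        4, assignment.audio_sd_log,
        sd_ratio=assignment.sd_ratio(nxt) if nxt <= 5 else 0.75,
        freq=assignment.freq(nxt) if nxt <= 5 else assignment.freq_initial,
        rng=rng, ratio_applies_to=ratio_applies_to,
        id_prefix=f"{participant_id}s{session}pre_",
    )
    rows: list[dict] = []
    for tr in triplets:
        for r in tr.expand(participant_id, session,
                           {"audio": True, "visual": True, "audiovisual": True}):
            r["phase"] = "preview"
            rows.append(r)
    return rows[:PREVIEW_TRIALS]


def make_experiment_design(
    assignments: list[ParticipantAssignment] | None = None,
    sessions: tuple[int, ...] = (1, 2, 3, 4, 5),
    seed: int = 0,
    triplet_counts: dict[int, int] | None = None,
    ratio_applies_to: str = "sd",
) -> pd.DataFrame:
    """Concatenated trial table for a whole cohort."""
    if assignments is None:
        assignments = default_assignments()
    frames = [
        make_session_design(s, a, seed=seed, triplet_counts=triplet_counts,
                            ratio_applies_to=ratio_applies_to).trials
        for a in assignments
        for s in sessions
    ]
    return pd.concat(frames, ignore_index=True)
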