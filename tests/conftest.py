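import numpy as np
import pandas as pd
import pytest

from cuefuse.validation import simulate_cohort_table


@pytest.fixture(scope="session")
def ideal_run():
    """A full Sessions-3-5 simulation of 12 ideal observers.

    Returns (trial table, cohort dict, assignments list); shared across
    tests since it is deterministic under its seed.
    """
    return simulate_cohort_table(seed=11)


@pytest.fixture(scope="session")
def ideal_table(ideal_run):
    return ideal_run[0]


@pytest.fixture()
def tiny_table():
    """A handmade two-triplet table with known responses."""
    rows = []
    for pid in ("P01",):
        for k, (target, center) in enumerate([(15.0, 14.0), (25.0, 26.0)]):
            for ttype in ("audio", "visual", "audiovisual"):
                has_vis = ttype in ("visual", "audiovisual")
                rows.append({
                    "participant_id": pid, "session": 3, "phase": "main",
                    "trial_type": ttype, "triplet_id": f"t{k}",
                    "target_m": target,
                    "visual_center_m": center if has_vis else np.nan,
                    "visual_sd_log": 0.1 if has_vis else np.nan,
                    "audio_freq_hz": 4000.0 if ttype != "visual" else np.nan,
                    "feedback": True,
                    "response_m": target,
                })
    return pd.DataFrame(rows)
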