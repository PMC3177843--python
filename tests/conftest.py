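import numpy as np
import pandas as pd
import pytest

from gazecue.saccades import (STATUS_ANTICIPATION, STATUS_DELAY, STATUS_KEPT,
                              STATUS_NO_SACCADE)


def make_trials(n_correct_cong, n_cong, n_correct_inc, n_inc,
                rt_cong=250.0, rt_inc=285.0, participant="P1",
                group="left", character="X") -> pd.DataFrame:
    """Scored kept trials for one participant x character cell pair."""
    rows = []
    for i in range(n_cong):
        rows.append({"participant_id": participant, "group": group,
                     "character": character, "cue_direction": "left",
                     "congruency": "congruent", "rt_ms": rt_cong,
                     "correct": i < n_correct_cong, "status": STATUS_KEPT})
    for i in range(n_inc):
        rows.append({"participant_id": participant, "group": group,
                     "character": character, "cue_direction": "left",
                     "congruency": "incongruent", "rt_ms": rt_inc,
                     "correct": i < n_correct_inc, "status": STATUS_KEPT})
    return pd.DataFrame(rows)


def status_frame(n_kept, n_no_sac, n_antic, n_delay) -> pd.DataFrame:
    status = ([STATUS_KEPT] * n_kept + [STATUS_NO_SACCADE] * n_no_sac
              + [STATUS_ANTICIPATION] * n_antic + [STATUS_DELAY] * n_delay)
    return pd.DataFrame({"status": status})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
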