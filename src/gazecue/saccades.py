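"""Saccade detection and trial-level filtering for horizontal gaze traces.

A trial yields one scored saccade: the first post-cue horizontal movement
whose velocity exceeds a threshold and whose total displacement exceeds the
amplitude criterion (default 2 degrees of visual angle).  Trials without
such a movement are excluded; trials whose saccadic latency falls below
100 ms (anticipations) or above 500 ms (delays) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_AMPLITUDE_DEG = 2.0
DEFAULT_VELOCITY_THRESHOLD = 30.0   # deg/s
RT_MIN_MS = 100.0
RT_MAX_MS = 500.0

STATUS_KEPT = "kept"
STATUS_NO_SACCADE = "excluded_no_saccade"
STATUS_ANTICIPATION = "rejected_anticipation"
STATUS_DELAY = "rejected_delay"
ALL_STATUSES = (STATUS_KEPT, STATUS_NO_SACCADE, STATUS_ANTICIPATION, STATUS_DELAY)


class MalformedTraceError(ValueError):
    """Raised for traces with non-monotonic timestamps or too few samples."""


@dataclass
class GazeTrace:
    """Time-stamped horizontal eye position for one trial.

    t is in ms since trial start (strictly increasing); x is signed
    horizontal position in degrees, rightward positive; cue_onset_ms marks
    the imperative color change.
    """

    t: np.ndarray
    x: np.ndarray
    cue_onset_ms: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.size != self.x.size:
            raise MalformedTraceError("t and x must have equal length")
        if self.t.size < 2:
            raise MalformedTraceError("trace needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise MalformedTraceError("timestamps must be strictly increasing")


@dataclass
class SaccadeEvent:
    """First scored saccade of a trial, relative to cue onset."""

    onset_ms: float          # relative to cue onset
    amplitude_deg: float     # nonnegative
    direction: str           # 'left' | 'right'


def _onset_refine(t: np.ndarray, x: np.ndarray, m_pre: float, disp: float,
                  onset: int, offset: int) -> int:
    """Broken-stick refinement of a movement onset index.

    Fits a flat-then-ramp model (flat at the pre-movement median, then a
    free-slope line) over candidate break points around the velocity-run
    start and returns the break with the smallest squared error.  The ramp
    segment is truncated below 85% of the step so the plateau does not bias
    the break point.
    """
    rel = np.abs(x - m_pre)
    k85 = onset
    while k85 < offset and rel[k85] < 0.85 * abs(disp):
        k85 += 1
    lo = max(onset - 8, 1)
    hi = min(onset + 6, k85 - 1)
    best, best_sse = onset, np.inf
    for tau in range(lo, max(hi, lo) + 1):
        seg = x[tau:k85 + 1] - m_pre
        tt = t[tau:k85 + 1] - t[tau]
        denom = (tt * tt).sum()
        slope = (seg * tt).sum() / denom if denom > 0 else 0.0
        sse = ((seg - slope * tt) ** 2).sum()
        flat = x[max(tau - 16, 0):tau] - m_pre
        sse += (flat ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, tau
    return best


def detect_first_saccade(
    trace: GazeTrace,
    min_amplitude_deg: float = DEFAULT_MIN_AMPLITUDE_DEG,
    velocity_threshold_deg_s: float = DEFAULT_VELOCITY_THRESHOLD,
    noise_lambda: float = 3.0,
) -> SaccadeEvent | None:
    """Detect the first post-cue saccade exceeding the amplitude criterion.

    Candidate movements are runs of at least two consecutive samples whose
    smoothed (5-point moving-average) velocity exceeds the effective
    threshold: the larger of ``velocity_threshold_deg_s`` and
    ``noise_lambda`` times the robust (MAD-based) SD of the pre-cue
    velocity, so fixation jitter does not trigger spurious runs.  A run
    qualifies when the displacement from the median pre-onset position (up
    to 100 ms back) to the median position over the 50 ms after the run
    exceeds ``min_amplitude_deg`` and the run itself carries most of it;
    subthreshold movements are skipped and the scan continues.  The
    reported onset is refined by a broken-stick (flat-then-ramp)
    least-squares fit around the run start.  Returns None when no
    qualifying movement exists.
    """
    t, x = trace.t, trace.x
    n = t.size
    if not (t[0] <= trace.cue_onset_ms <= t[-1]):
        raise MalformedTraceError("cue onset outside trace span")
    if n < 5:
        return None

    period = float(np.median(np.diff(t)))
    v = np.zeros(n)
    v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * period) * 1000.0
    pre_v = v[2:-2][t[2:-2] < trace.cue_onset_ms]
    if pre_v.size:
        mad_sd = 1.4826 * np.median(np.abs(pre_v - np.median(pre_v)))
    else:
        mad_sd = 0.0
    threshold = max(velocity_threshold_deg_s, noise_lambda * mad_sd)
    fast = np.abs(v) >= threshold

    i = int(np.searchsorted(t, trace.cue_onset_ms, side="right"))
    while i < n - 1:
        if not (fast[i] and fast[i + 1]):
            i += 1
            continue
        onset = i
        j = onset
        while j < n - 1 and (fast[j] or fast[j + 1]):   # bridge 1-sample dropouts
            j += 1
        offset = min(j, n - 1)
        pre = x[(t < t[onset]) & (t >= t[onset] - 100.0)]
        if pre.size == 0:
            pre = x[:onset] if onset > 0 else x[:1]
        m_pre = float(np.median(pre))
        post = x[(t >= t[offset]) & (t <= t[offset] + 50.0)]
        disp = float(np.median(post) - m_pre)
        run_disp = float(x[offset] - x[onset])
        if abs(disp) > min_amplitude_deg and abs(run_disp) > 0.25 * abs(disp):
            refined = _onset_refine(t, x, m_pre, disp, onset, offset)
            return SaccadeEvent(
                onset_ms=float(t[refined] - trace.cue_onset_ms),
                amplitude_deg=abs(disp),
                direction="right" if disp > 0 else "left",
            )
        i = j + 1
    return None


def score_trial(
    trace_or_event: GazeTrace | SaccadeEvent | None,
    participant_id,
    character: str,
    cue_direction: str,
    congruency: str,
    group: str | None = None,
    **detector_kwargs,
) -> dict:
    """Score one trial into a TrialRecord row.

    Accepts a raw trace (the detector runs first) or an already-detected
    event (None meaning no saccade).  ``correct`` is True when the saccade
    direction matches the cue direction; the status filters are inclusive:
    a trial is kept iff 100 <= RT <= 500 ms.
    """
    if isinstance(trace_or_event, GazeTrace):
        event = detect_first_saccade(trace_or_event, **detector_kwargs)
    else:
        event = trace_or_event

    rec = {
        "participant_id": participant_id,
        "group": group,
        "character": character,
        "cue_direction": cue_direction,
        "congruency": congruency,
        "rt_ms": np.nan,
        "amplitude_deg": np.nan,
        "saccade_direction": None,
        "correct": None,
        "status": STATUS_NO_SACCADE,
    }
    if event is None:
        return rec
    rt = float(event.onset_ms)
    rec.update(
        rt_ms=rt,
        amplitude_deg=float(event.amplitude_deg),
        saccade_direction=event.direction,
        correct=bool(event.direction == cue_direction),
    )
    if rt < RT_MIN_MS:
        rec["status"] = STATUS_ANTICIPATION
    elif rt > RT_MAX_MS:
        rec["status"] = STATUS_DELAY
    else:
        rec["status"] = STATUS_KEPT
    return rec


def filter_summary(trials: pd.DataFrame) -> dict:
    """Counts and percentages per exclusion status.

    Percentages are over all trials; the anticipation/delay rejection rate
    is additionally reported over the trials with a detected saccade, since
    both denominator conventions appear in practice.
    """
    if len(trials) == 0:
        raise ValueError("empty trial list")
    total = len(trials)
    counts = {s: int((trials["status"] == s).sum()) for s in ALL_STATUSES}
    unknown = total - sum(counts.values())
    if unknown:
        raise ValueError("trials contain unknown status labels")
    pct = {s: 100.0 * c / total for s, c in counts.items()}
    with_saccade = total - counts[STATUS_NO_SACCADE]
    rejected = counts[STATUS_ANTICIPATION] + counts[STATUS_DELAY]
    return {
        "n_total": total,
        "counts": counts,
        "pct_of_total": pct,
        "pct_no_saccade": pct[STATUS_NO_SACCADE],
        "pct_rejected_of_total": 100.0 * rejected / total,
        "pct_rejected_of_detected": (
            100.0 * rejected / with_saccade if with_saccade else np.nan),
    }


def read_traces_csv(path) -> dict:
    """Read traces from CSV columns (trial_id, t_ms, x_deg, cue_onset_ms)."""
    df = pd.read_csv(path)
    required = {"trial_id", "t_ms", "x_deg", "cue_onset_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    out = {}
    for trial_id, g in df.groupby("trial_id", sort=False):
        out[trial_id] = GazeTrace(
            t=g["t_ms"].to_numpy(), x=g["x_deg"].to_numpy(),
            cue_onset_ms=float(g["cue_onset_ms"].iloc[0]),
        )
    return out
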