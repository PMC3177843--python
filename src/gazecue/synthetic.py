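"""Seeded synthetic gaze-following experiments.

Emulates a two-group (left- vs right-wing voters, 15/13 participants)
gaze-cueing study: four character blocks of 48 trials each (2 cue
directions x 2 congruency levels x 12 repetitions, 75 ms SOA), with
congruency-dependent directional-error rates modulated per group and
character, right-skewed saccadic latencies in the 100-500 ms window,
a configurable fraction of no-saccade trials and of anticipations/delays,
and questionnaire tables (25-item Big-Five adjective profiles for self and
each character, positive/negative emotion ratings).

A latent per-participant-per-character deviate couples the perceived
personality similarity to the injected accuracy-interference effect with
correlation ``similarity_coupling``, so pipeline-level recovery of the
similarity-interference association can be exercised at any chosen
strength (0 = independent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import ITEM_KEYS, N_ITEMS
from .saccades import (GazeTrace, STATUS_KEPT, STATUS_NO_SACCADE,
                       STATUS_ANTICIPATION, STATUS_DELAY)

GROUPS = ("left", "right")
CHARACTERS = ("Di Pietro", "Prodi", "Berlusconi", "Vespa")

# Default interference structure (percentage points of accuracy
# interference per group x character) — the reference group-by-character
# pattern the generator emulates: right-wing observers are captured
# strongly by the right-wing characters' gaze (18.3 / 17.4 points for
# Berlusconi / Vespa) and weakly by the left-wing ones, while left-wing
# observers show moderate ingroup interference and little from Berlusconi.
DEFAULT_INTERFERENCE_PTS = {
    ("right", "Berlusconi"): 18.3, ("right", "Vespa"): 17.4,
    ("right", "Di Pietro"): 8.7, ("right", "Prodi"): 4.0,
    ("left", "Di Pietro"): 10.0, ("left", "Prodi"): 9.0,
    ("left", "Berlusconi"): 2.1, ("left", "Vespa"): 5.2,
}
DEFAULT_CONGRUENT_ERR = 0.04

# Target mean perceived-similarity per group x character (ingroup higher).
DEFAULT_SIMILARITY = {
    ("left", "Di Pietro"): 0.77, ("left", "Prodi"): 0.73,
    ("left", "Berlusconi"): 0.60, ("left", "Vespa"): 0.62,
    ("right", "Berlusconi"): 0.74, ("right", "Vespa"): 0.72,
    ("right", "Di Pietro"): 0.61, ("right", "Prodi"): 0.56,
}

# Mean (SD) differential emotion per group x character (ingroup bias).
DEFAULT_EMOTION = {
    ("right", "Di Pietro"): (-0.2, 2.2), ("right", "Prodi"): (-2.2, 2.0),
    ("right", "Berlusconi"): (1.5, 2.0), ("right", "Vespa"): (0.2, 1.2),
    ("left", "Di Pietro"): (1.4, 1.9), ("left", "Prodi"): (0.3, 2.3),
    ("left", "Berlusconi"): (-3.1, 1.4), ("left", "Vespa"): (-2.3, 1.8),
}


class ConfigurationError(ValueError):
    """Invalid cohort configuration; the message names the field."""


def default_err_prob() -> dict:
    """(group, character, congruency) -> directional-error probability."""
    out = {}
    for (g, c), pts in DEFAULT_INTERFERENCE_PTS.items():
        out[(g, c, "congruent")] = DEFAULT_CONGRUENT_ERR
        out[(g, c, "incongruent")] = DEFAULT_CONGRUENT_ERR + pts / 100.0
    return out


@dataclass
class CohortConfig:
    """Full parameterization of one synthetic experiment."""

    n_per_group: dict = field(default_factory=lambda: {"left": 15, "right": 13})
    characters: tuple = CHARACTERS
    reps_per_cell: int = 12
    soa_ms: float = 75.0
    err_prob: dict = field(default_factory=default_err_prob)
    rt_model: dict = field(default_factory=lambda: {
        "family": "shifted_lognormal", "shift_ms": 150.0,
        "mu_log": float(np.log(90.0)), "sigma_log": 0.4,
        "incongruent_shift_ms": 35.0,
    })
    p_no_saccade: float = 0.135
    p_anticipation: float = 0.020
    p_delay: float = 0.014
    similarity_coupling: float = 0.5
    interference_sd: float = 13.0        # points, across participant x character
    base_similarity: dict = field(default_factory=lambda: dict(DEFAULT_SIMILARITY))
    similarity_sd: float = 0.08
    emotion_params: dict = field(default_factory=lambda: dict(DEFAULT_EMOTION))
    drop_one_ratings: bool = False       # mimic one participant's missing ratings
    sampling_hz: float = 240.0
    seed: int = 0

    @property
    def trials_per_block(self) -> int:
        return self.reps_per_cell * 2 * 2

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ConfigurationError(f"n_per_group[{g!r}] must be positive")
        if len(self.n_per_group) != 2:
            raise ConfigurationError("n_per_group must define exactly 2 groups")
        if len(self.characters) != 4:
            raise ConfigurationError("characters must list 4 labels")
        for name in ("p_no_saccade", "p_anticipation", "p_delay"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.p_no_saccade + self.p_anticipation + self.p_delay > 1.0:
            raise ConfigurationError(
                "p_no_saccade + p_anticipation + p_delay must not exceed 1")
        for key, p in self.err_prob.items():
            if not 0.0 <= p <= 0.5:
                raise ConfigurationError(f"err_prob[{key}] must lie in [0, 0.5]")
        if not -1.0 <= self.similarity_coupling <= 1.0:
            raise ConfigurationError("similarity_coupling must lie in [-1, 1]")
        if self.reps_per_cell < 1:
            raise ConfigurationError("reps_per_cell must be positive")
        if self.sampling_hz <= 0:
            raise ConfigurationError("sampling_hz must be positive")
        if self.soa_ms < 0:
            raise ConfigurationError("soa_ms must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["characters"] = list(self.characters)
        d["err_prob"] = {"|".join(k): v for k, v in self.err_prob.items()}
        d["base_similarity"] = {"|".join(k): v for k, v in self.base_similarity.items()}
        d["emotion_params"] = {"|".join(k): list(v) for k, v in self.emotion_params.items()}
        return d


@dataclass
class SyntheticDataset:
    """One generated experiment: trial table plus questionnaire tables."""

    participants: pd.DataFrame   # participant_id, group
    trials: pd.DataFrame         # TrialRecord rows
    ratings: pd.DataFrame        # participant_id, target, item_key, rating
    emotions: pd.DataFrame       # participant_id, character, positive, negative
    injected: pd.DataFrame       # participant_id, character, injected truth
    provenance: dict
    traces: dict = field(default_factory=dict)

    def write_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.csv", index=False)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        self.ratings.to_csv(outdir / "ratings.csv", index=False)
        self.emotions.to_csv(outdir / "emotions.csv", index=False)
        self.injected.to_csv(outdir / "injected_truth.csv", index=False)
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
        if self.traces:
            rows = []
            for trial_id, tr in self.traces.items():
                rows.append(pd.DataFrame({
                    "trial_id": trial_id, "t_ms": tr.t, "x_deg": tr.x,
                    "cue_onset_ms": tr.cue_onset_ms,
                }))
            pd.concat(rows).to_csv(outdir / "traces.csv", index=False)


# ---------------------------------------------------------------------------
# rating-profile construction
# ---------------------------------------------------------------------------

def _draw_self_profile(rng: np.random.Generator) -> np.ndarray:
    """Discretized normal on {1..5}, centered slightly above the midpoint."""
    raw = np.rint(rng.normal(3.2, 0.9, size=N_ITEMS))
    return np.clip(raw, 1, 5).astype(int)


def _profile_at_distance(self_items: np.ndarray, distance: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Character profile at exact summed city-block distance from self.

    Each item is assigned a perturbation direction; ``distance`` unit steps
    are then spread at random over items with remaining headroom, keeping
    every rating in 1..5.
    """
    up = 5 - self_items
    down = self_items - 1
    sign = np.where(rng.random(N_ITEMS) < 0.5, 1, -1)
    cap = np.where(sign > 0, up, down)
    # flip items toward their roomier side until the target is reachable
    order = rng.permutation(N_ITEMS)
    for i in order:
        if cap.sum() >= distance:
            break
        flipped = -sign[i]
        cap_f = up[i] if flipped > 0 else down[i]
        if cap_f > cap[i]:
            sign[i], cap[i] = flipped, cap_f
    distance = min(distance, int(cap.sum()))
    offsets = np.zeros(N_ITEMS, dtype=int)
    for _ in range(distance):
        open_items = np.flatnonzero(offsets < cap)
        i = open_items[rng.integers(open_items.size)]
        offsets[i] += 1
    return self_items + sign * offsets


def _emotion_pair(diff: int, rng: np.random.Generator) -> tuple[int, int]:
    """Integer (positive, negative) ratings in 1..5 with pos - neg = diff."""
    d = int(np.clip(diff, -4, 4))
    if d >= 0:
        neg = int(rng.integers(1, 6 - d))
        return neg + d, neg
    pos = int(rng.integers(1, 6 + d))
    return pos, pos - d


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, with_traces: bool = False) -> SyntheticDataset:
    """Generate a complete synthetic experiment, reproducible per seed.

    The latent deviate u(participant, character) drives the target
    perceived similarity; the interference deviate is
    v = coupling * u + sqrt(1 - coupling^2) * w with independent w, so the
    injected accuracy interference correlates with the similarity score at
    approximately ``similarity_coupling``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = list(config.n_per_group)
    chars = list(config.characters)

    pids, pgroups = [], []
    for g in groups:
        for i in range(config.n_per_group[g]):
            pids.append(f"{g[0].upper()}{i+1:02d}")
            pgroups.append(g)
    participants = pd.DataFrame({"participant_id": pids, "group": pgroups})
    n_total = len(pids)

    # --- latent structure ---------------------------------------------------
    # similarity targets first; the interference deviate is then coupled to
    # the realized similarity standardized within each character, so the
    # similarity-interference correlation holds across the whole cohort
    # even when group-level base similarities differ
    coupling = config.similarity_coupling
    u = rng.standard_normal((n_total, 4))
    w = rng.standard_normal((n_total, 4))

    sim_target = np.empty((n_total, 4))
    p_cong = np.empty((n_total, 4))
    base_inc = np.empty((n_total, 4))
    for pi, g in enumerate(pgroups):
        for ci, c in enumerate(chars):
            base_s = config.base_similarity.get((g, c), 0.65)
            sim_target[pi, ci] = np.clip(
                base_s + config.similarity_sd * u[pi, ci], 0.40, 0.95)
            p_cong[pi, ci] = config.err_prob[(g, c, "congruent")]
            base_inc[pi, ci] = config.err_prob[(g, c, "incongruent")]

    sd_c = sim_target.std(axis=0, ddof=0)
    z = np.where(sd_c > 1e-12,
                 (sim_target - sim_target.mean(axis=0)) / np.where(sd_c > 1e-12, sd_c, 1.0),
                 u)
    v = coupling * z + np.sqrt(max(0.0, 1.0 - coupling ** 2)) * w
    p_incong = np.clip(base_inc + config.interference_sd / 100.0 * v, 0.0, 0.5)

    injected = pd.DataFrame({
        "participant_id": np.repeat(pids, 4),
        "character": np.tile(chars, n_total),
        "target_similarity": sim_target.ravel(),
        "injected_interference_pts": (100.0 * (p_incong - p_cong)).ravel(),
    })

    # --- trials --------------------------------------------------------------
    reps = config.reps_per_cell
    per_block = config.trials_per_block
    cue_dirs = np.tile(np.repeat(["left", "right"], 2 * reps), 1)
    congr = np.tile(np.repeat(["congruent", "incongruent"], reps), 2)
    rtm = config.rt_model

    frames = []
    for pi, (pid, g) in enumerate(zip(pids, pgroups)):
        for ci, c in enumerate(chars):
            order = rng.permutation(per_block)
            cd = cue_dirs[order]
            cg = congr[order]
            is_inc = cg == "incongruent"
            p_err = np.where(is_inc, p_incong[pi, ci], p_cong[pi, ci])
            err = rng.random(per_block) < p_err

            cat = rng.random(per_block)
            no_sac = cat < config.p_no_saccade
            antic = (~no_sac) & (cat < config.p_no_saccade + config.p_anticipation)
            delay = (~no_sac) & (~antic) & (
                cat < config.p_no_saccade + config.p_anticipation + config.p_delay)
            kept = ~(no_sac | antic | delay)

            rt = config.rt_model["shift_ms"] + rng.lognormal(
                rtm["mu_log"], rtm["sigma_log"], size=per_block)
            rt = rt + np.where(is_inc, rtm["incongruent_shift_ms"], 0.0)
            rt = np.clip(rt, 100.0, 500.0)
            rt[antic] = rng.uniform(40.0, 99.0, antic.sum())
            rt[delay] = rng.uniform(501.0, 650.0, delay.sum())
            rt[no_sac] = np.nan

            sac_dir = np.where(err, np.where(cd == "left", "right", "left"), cd)
            status = np.full(per_block, STATUS_KEPT, dtype=object)
            status[no_sac] = STATUS_NO_SACCADE
            status[antic] = STATUS_ANTICIPATION
            status[delay] = STATUS_DELAY
            amp = np.clip(rng.normal(9.5, 1.5, per_block), 2.5, None)
            amp[no_sac] = np.nan

            frames.append(pd.DataFrame({
                "participant_id": pid, "group": g, "character": c,
                "block": ci, "trial_in_block": np.arange(per_block),
                "cue_direction": cd, "congruency": cg,
                "rt_ms": rt, "amplitude_deg": amp,
                "saccade_direction": np.where(no_sac, None, sac_dir),
                "correct": np.where(no_sac, None, ~err),
                "status": status,
            }))
    trials = pd.concat(frames, ignore_index=True)
    trials["trial_id"] = np.arange(len(trials))

    # --- questionnaire tables ------------------------------------------------
    rating_rows, emotion_rows = [], []
    rated_pids = list(pids)
    if config.drop_one_ratings and rated_pids:
        rated_pids.remove(rated_pids[rng.integers(len(rated_pids))])
    for pi, (pid, g) in enumerate(zip(pids, pgroups)):
        if pid not in rated_pids:
            continue
        self_items = _draw_self_profile(rng)
        rating_rows.append(pd.DataFrame({
            "participant_id": pid, "target": "self",
            "item_key": ITEM_KEYS, "rating": self_items,
        }))
        for ci, c in enumerate(chars):
            dist = int(np.rint((1.0 - sim_target[pi, ci]) * 100.0))
            char_items = _profile_at_distance(self_items, dist, rng)
            rating_rows.append(pd.DataFrame({
                "participant_id": pid, "target": c,
                "item_key": ITEM_KEYS, "rating": char_items,
            }))
            mean, sd = config.emotion_params.get((g, c), (0.0, 2.0))
            diff = int(np.rint(rng.normal(mean, sd)))
            pos, neg = _emotion_pair(diff, rng)
            emotion_rows.append({
                "participant_id": pid, "character": c,
                "positive": pos, "negative": neg,
            })
    ratings = pd.concat(rating_rows, ignore_index=True)
    emotions = pd.DataFrame(emotion_rows)

    traces = {}
    if with_traces:
        for row in trials.itertuples():
            if row.status == STATUS_NO_SACCADE:
                traces[row.trial_id] = generate_trace(
                    rt_ms=None, amplitude_deg=0.0, direction="right",
                    sampling_hz=config.sampling_hz, tail_ms=800.0, rng=rng)
            else:
                traces[row.trial_id] = generate_trace(
                    rt_ms=row.rt_ms, amplitude_deg=row.amplitude_deg,
                    direction=row.saccade_direction,
                    sampling_hz=config.sampling_hz, tail_ms=800.0, rng=rng)

    return SyntheticDataset(
        participants=participants, trials=trials, ratings=ratings,
        emotions=emotions, injected=injected,
        provenance={"seed": config.seed, "config": config.to_dict(),
                    "n_trials": len(trials)},
        traces=traces,
    )


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------

def generate_trace(
    rt_ms: float | None,
    amplitude_deg: float,
    direction: str,
    sampling_hz: float = 240.0,
    cue_onset_ms: float = 575.0,
    noise_sd: float = 0.1,
    rise_ms: float = 30.0,
    tail_ms: float = 650.0,
    rng: np.random.Generator | int | None = None,
) -> GazeTrace:
    """Synthesize a horizontal gaze trace with one step-like saccade.

    Fixation noise around zero, then from ``cue_onset_ms + rt_ms`` a linear
    rise over ``rise_ms`` to the signed amplitude, then a stable tail.
    ``rt_ms=None`` or zero amplitude yields a saccade-free trace.
    """
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be positive")
    if amplitude_deg < 0:
        raise ValueError("amplitude_deg must be nonnegative")
    if rt_ms is not None and rt_ms + rise_ms > tail_ms:
        raise ValueError("rt_ms must fall within the trace duration")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    period = 1000.0 / sampling_hz
    t = np.arange(0.0, cue_onset_ms + tail_ms, period)
    x = rng.normal(0.0, noise_sd, size=t.size)
    if rt_ms is not None and amplitude_deg > 0:
        sign = 1.0 if direction == "right" else -1.0
        t0 = cue_onset_ms + rt_ms
        ramp = np.clip((t - t0) / rise_ms, 0.0, 1.0)
        x = x + sign * amplitude_deg * ramp
    return GazeTrace(t=t, x=x, cue_onset_ms=cue_onset_ms)


# ---------------------------------------------------------------------------
# canned study conditions
# ---------------------------------------------------------------------------

def null_config(seed: int = 0) -> CohortConfig:
    """No group/character structure anywhere: flat error rates, no
    interference heterogeneity, no similarity coupling."""
    flat = {}
    for g in GROUPS:
        for c in CHARACTERS:
            flat[(g, c, "congruent")] = 0.10
            flat[(g, c, "incongruent")] = 0.10
    return CohortConfig(err_prob=flat, similarity_coupling=0.0,
                        interference_sd=0.0, seed=seed)


def planted_interaction_config(effect_pts: float = 15.0, seed: int = 0) -> CohortConfig:
    """One group's two ingroup characters carry a planted accuracy
    interference of ``effect_pts`` points; everything else is flat."""
    err = {}
    for g in GROUPS:
        for c in CHARACTERS:
            err[(g, c, "congruent")] = DEFAULT_CONGRUENT_ERR
            boost = effect_pts / 100.0 if (
                g == "right" and c in ("Berlusconi", "Vespa")) else 0.0
            err[(g, c, "incongruent")] = DEFAULT_CONGRUENT_ERR + boost
    return CohortConfig(err_prob=err, similarity_coupling=0.0,
                        interference_sd=0.0, seed=seed)


def coupled_similarity_config(coupling: float = 0.5, seed: int = 0) -> CohortConfig:
    """Uniform moderate interference with participant-level heterogeneity
    coupled to perceived similarity at ``coupling``."""
    err = {}
    for g in GROUPS:
        for c in CHARACTERS:
            err[(g, c, "congruent")] = 0.02
            err[(g, c, "incongruent")] = 0.20
    return CohortConfig(err_prob=err, similarity_coupling=coupling,
                        interference_sd=15.0, seed=seed)
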