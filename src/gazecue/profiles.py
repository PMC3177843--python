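"""Emotion-positivity and personality-similarity scores from ratings.

Participants rate themselves and each character on 25 Big-Five marker
adjectives (5 markers for each of Energy/Extraversion, Agreeableness,
Conscientiousness, Emotional stability, Openness) on a 1-5 scale.
Similarity between two profiles is 1 minus the normalized summed per-item
Euclidean distance; since each item's distance is the square root of a
single squared difference, it reduces to the absolute difference, and the
normalizer is 25 items x 4 (the maximum per-item distance) = 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_ITEMS = 25
MAX_ITEM_DISTANCE = 4.0
NORMALIZER = N_ITEMS * MAX_ITEM_DISTANCE   # 100

BIG_FIVE_MARKERS = {
    "energy": ["happy", "determined", "dynamic", "energetic", "active"],
    "agreeableness": ["cordial", "generous", "loyal", "sincere", "unselfish"],
    "conscientiousness": ["efficient", "scrupulous", "precise",
                          "conscientious", "diligent"],
    "emotional_stability": ["optimistic", "self-confident", "solid",
                            "relaxed", "calm"],
    "openness": ["sharp", "creative", "innovative", "modern", "informed"],
}
ITEM_KEYS = [adj for markers in BIG_FIVE_MARKERS.values() for adj in markers]


@dataclass
class RatingProfile:
    """25 integer adjective ratings (1-5) by one rater about one target."""

    target: str
    items: np.ndarray

    def __post_init__(self):
        self.items = np.asarray(self.items, dtype=float)
        if self.items.size != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} items, got {self.items.size}")
        if not np.all(np.isin(self.items, [1, 2, 3, 4, 5])):
            raise ValueError("ratings must be integers in 1..5")


@dataclass
class SimilarityScore:
    participant_id: object
    character: str
    score: float
    mode: str   # 'perceived' | 'objective'

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("similarity score must lie in [0, 1]")


def emotion_positivity(pos_rating: int, neg_rating: int) -> int:
    """Signed emotional-positivity index: positive minus negative rating."""
    for name, r in (("positive", pos_rating), ("negative", neg_rating)):
        if r not in (1, 2, 3, 4, 5):
            raise ValueError(f"{name} rating must be in 1..5, got {r}")
    return int(pos_rating) - int(neg_rating)


def _similarity_from_items(a: np.ndarray, b: np.ndarray) -> float:
    dist = np.minimum(np.abs(a - b), MAX_ITEM_DISTANCE)
    return 1.0 - float(dist.sum()) / NORMALIZER


def perceived_similarity(self_profile: RatingProfile,
                         char_profile: RatingProfile) -> float:
    """Similarity between a rater's self profile and their character profile.

    score = 1 - sum_i |self_i - char_i| / 100, in [0, 1]; 1 means identical
    profiles, 0 means every item maximally distant.
    """
    return _similarity_from_items(self_profile.items, char_profile.items)


def consensus_profile(char_profiles: list[RatingProfile]) -> np.ndarray:
    """Per-item sample-mean character profile across raters (real-valued)."""
    if len(char_profiles) < 2:
        raise ValueError("consensus requires at least 2 raters")
    return np.mean([p.items for p in char_profiles], axis=0)


def objective_similarity(self_profile: RatingProfile,
                         consensus: np.ndarray) -> float:
    """Similarity of a self profile to the sample-consensus character profile.

    Same formula as :func:`perceived_similarity` with the consensus item
    means in place of the rater's own character ratings; per-item distances
    are capped at 4 before summation.
    """
    consensus = np.asarray(consensus, dtype=float)
    if consensus.size != N_ITEMS:
        raise ValueError(f"consensus must have {N_ITEMS} items")
    if np.any(consensus < 1) or np.any(consensus > 5):
        raise ValueError("consensus items must lie in [1, 5]")
    return _similarity_from_items(self_profile.items, consensus)


def similarity_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Perceived and objective similarity for every participant x character.

    ``ratings`` is long-form with columns (participant_id, target, item_key,
    rating); target 'self' holds the self profile, any other target is a
    character.  The objective consensus for a character averages ratings
    across the whole sample, self-rater included.
    """
    required = {"participant_id", "target", "item_key", "rating"}
    if missing := required - set(ratings.columns):
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")

    def profile_of(sub: pd.DataFrame, target: str) -> RatingProfile:
        sub = sub.set_index("item_key").reindex(ITEM_KEYS)
        if sub["rating"].isna().any():
            raise ValueError(f"misaligned or missing item keys for target {target}")
        return RatingProfile(target=target, items=sub["rating"].to_numpy())

    characters = sorted(set(ratings["target"]) - {"self"})
    by_pc: dict[tuple, RatingProfile] = {}
    selves: dict = {}
    for (pid, target), sub in ratings.groupby(["participant_id", "target"]):
        prof = profile_of(sub, target)
        if target == "self":
            selves[pid] = prof
        else:
            by_pc[(pid, target)] = prof

    consensus = {
        c: consensus_profile([p for (pid, t), p in by_pc.items() if t == c])
        for c in characters
    }
    rows = []
    for pid, self_prof in selves.items():
        for c in characters:
            if (pid, c) not in by_pc:
                continue
            rows.append({
                "participant_id": pid, "character": c,
                "perceived": perceived_similarity(self_prof, by_pc[(pid, c)]),
                "objective": objective_similarity(self_prof, consensus[c]),
            })
    return pd.DataFrame(rows)


def emotion_table(emotions: pd.DataFrame) -> pd.DataFrame:
    """Emotional-positivity index per participant x character.

    ``emotions`` has columns (participant_id, character, positive, negative).
    """
    required = {"participant_id", "character", "positive", "negative"}
    if missing := required - set(emotions.columns):
        raise ValueError(f"emotion table missing columns: {sorted(missing)}")
    out = emotions.copy()
    out["positivity"] = [
        emotion_positivity(int(p), int(n))
        for p, n in zip(out["positive"], out["negative"])
    ]
    return out
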