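"""Binocular-rivalry imagery-strength scoring and participant selection.

In the pre-test, each trial cues a colour to imagine; a brief binocular
rivalry display follows and the participant reports which colour was
dominant (or "mixed"). Imagery strength is the priming rate

    %primed = n_primed / (n - n_mock - n_mixed)

where n is the total trial count, n_mock the catch trials (a physical
mixture; a non-"mixed" response there indicates decision bias), n_mixed
the non-catch mixed reports, and n_primed the non-catch trials where the
report matched the cued colour. Participants at or above 60% priming pass
the selection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ImageryScore",
    "score_imagery_strength",
    "select_participants",
    "catch_failure_rate",
]

SELECTION_THRESHOLD = 0.60


@dataclass(frozen=True)
class ImageryScore:
    """Priming-based imagery strength with the selection verdict."""

    strength: float
    passes_threshold: bool
    n_scorable: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")


def _check_trials(trials: pd.DataFrame) -> None:
    required = {"cue", "response", "vividness", "is_catch"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table needs columns {sorted(required)}")
    if not trials["vividness"].isin([1, 2, 3, 4]).all():
        raise ValueError("vividness ratings must be 1-4")


def score_imagery_strength(
    trials: pd.DataFrame, threshold: float = SELECTION_THRESHOLD
) -> ImageryScore:
    """Evaluate %primed = n_primed / (n - n_mock - n_mixed).

    Catch trials and non-catch mixed reports are excluded from the
    denominator and can never count as primed.
    """
    _check_trials(trials)
    n = len(trials)
    non_catch = trials[~trials["is_catch"]]
    n_mock = int(trials["is_catch"].sum())
    n_mixed = int((non_catch["response"] == "mixed").sum())
    scorable = n - n_mock - n_mixed
    if scorable <= 0:
        raise ValueError("no scorable trials (denominator is zero)")
    decided = non_catch[non_catch["response"] != "mixed"]
    n_primed = int((decided["response"] == decided["cue"]).sum())
    strength = n_primed / scorable
    return ImageryScore(
        strength=strength,
        passes_threshold=strength >= threshold,
        n_scorable=scorable,
    )


def catch_failure_rate(trials: pd.DataFrame) -> float:
    """Fraction of catch trials not answered "mixed" (decision-bias index).

    Reported descriptively; no exclusion rule is applied to it.
    """
    _check_trials(trials)
    catch = trials[trials["is_catch"]]
    if len(catch) == 0:
        return float("nan")
    return float((catch["response"] != "mixed").mean())


def select_participants(
    scores: list[ImageryScore], threshold: float = SELECTION_THRESHOLD
) -> np.ndarray:
    """Indices of participants whose strength is at or above threshold."""
    return np.array(
        [i for i, s in enumerate(scores) if s.strength >= threshold], dtype=int
    )
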