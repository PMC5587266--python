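"""Playback-trial scoring and the conspecific-preference test.

A trial plays three long-call stimuli (Type 1A, Type 1B, Type 2) to a
territorial male in random order, one minute each, and counts the
territorial calls he answers with in each window.  A trial is valid when
any single window holds strictly more than 20 territorial calls.  Scoring
yields, per trial:

* response call numbers — the raw per-stimulus counts;
* response call ratio — each count as a fraction of the trial total
  (the male's energy allocation across opponents);
* highest defense opponent (HDO) — the stimulus with the unique maximal
  count, or TIE.

At the population level, the HDO choices of the valid, untied trials are
compared against a uniform no-preference null with a one-way chi-square
(df = number of stimulus types - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .stats_core import AssociationResult

__all__ = [
    "STIMULI",
    "TIE",
    "PlaybackTrial",
    "ResponseMetrics",
    "trial_valid",
    "score_trial",
    "preference_test",
]

STIMULI = ("Type1A", "Type1B", "Type2")
TIE = "TIE"
VALIDITY_THRESHOLD = 20  # strict: a window must exceed this


@dataclass(frozen=True)
class PlaybackTrial:
    male_id: str
    population: str  # e.g. "JP" (northern) or "OT" (southern)
    pretreatment_count: int
    response_counts: dict[str, int]
    stimulus_order: tuple[str, ...] = STIMULI

    def __post_init__(self) -> None:
        if set(self.response_counts) != set(STIMULI):
            raise ValueError(f"trial must count every stimulus in {STIMULI} exactly once")
        if sorted(self.stimulus_order) != sorted(STIMULI):
            raise ValueError("stimulus_order must be a permutation of the three types")
        if self.pretreatment_count < 0 or any(v < 0 for v in self.response_counts.values()):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ResponseMetrics:
    response_call_numbers: dict[str, int]
    response_call_ratio: dict[str, float]
    highest_defense_opponent: str


def trial_valid(trial: PlaybackTrial) -> bool:
    """True iff some 1-min window exceeds 20 territorial calls (strict)."""
    return max(trial.response_counts.values()) > VALIDITY_THRESHOLD


def score_trial(trial: PlaybackTrial, subtract_pretreatment: bool = False) -> ResponseMetrics:
    """Score a valid trial.

    ``subtract_pretreatment=True`` reads "net" response as count minus the
    1-min pretreatment baseline (floored at 0); the default keeps raw
    window counts with the baseline as a separate column.
    """
    counts = {s: int(trial.response_counts[s]) for s in STIMULI}
    if subtract_pretreatment:
        counts = {s: max(c - trial.pretreatment_count, 0) for s, c in counts.items()}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot score a trial with zero total responses")
    ratios = {s: c / total for s, c in counts.items()}
    top = max(counts.values())
    winners = [s for s, c in counts.items() if c == top]
    hdo = winners[0] if len(winners) == 1 else TIE
    return ResponseMetrics(
        response_call_numbers=counts,
        response_call_ratio=ratios,
        highest_defense_opponent=hdo,
    )


def preference_test(hdo_choices: list[str], n_types: int = 3) -> AssociationResult:
    """One-way chi-square of HDO choices against a uniform null.

    Ties are excluded (their count is disclosed on the result as
    ``n_ties`` in ``fixed`` reporting by callers); at least one non-tie
    choice is required.
    """
    choices = [c for c in hdo_choices if c != TIE]
    n_ties = len(hdo_choices) - len(choices)
    if not choices:
        raise ValueError("all choices are ties; no preference test possible")
    observed = np.array([choices.count(s) for s in STIMULI[:n_types]], dtype=float)
    chi2, p = sstats.chisquare(observed)
    res = AssociationResult(chi2=float(chi2), df=n_types - 1, p_value=float(p))
    res.n_ties = n_ties  # disclosed tie count
    return res
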