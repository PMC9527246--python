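"""Behavioral scoring: congruency operationalization, memory grain, percent
correct, and chance-level exclusions.

Congruency is taken from the participant's own relatedness judgments: a pair
is scored congruent when at least two of the three encoding judgments were
"related".  Retrieval responses are classified as *detailed* (correct
context and correct specific scene), *coarse* (correct context but scene
unknown or the wrong scene of the same context), or *forgotten*.  Percent
scores are over a participant's trials per operational condition and delay,
on the 0-100 scale.  Participants scoring below 33% total at a delay lose
that delay's data only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SCENES, StimulusPair

__all__ = [
    "EncodingJudgments",
    "TrialOutcome",
    "CHANCE_EXCLUSION_PCT",
    "operationalize_congruency",
    "classify_grain",
    "compute_scores",
    "apply_exclusions",
    "judgment_consistency",
]

JUDGMENTS = ("related", "unrelated", "missing")
GRAINS = ("detailed", "coarse", "forgotten")
CHANCE_EXCLUSION_PCT = 33.0


class IndeterminateCongruency(ValueError):
    """Fewer than two usable encoding judgments for a pair."""


@dataclass(frozen=True)
class EncodingJudgments:
    object_id: str
    judgments: tuple[str, str, str]  # one per encoding run

    def __post_init__(self):
        if len(self.judgments) != 3:
            raise ValueError("expected exactly three encoding judgments")
        for j in self.judgments:
            if j not in JUDGMENTS:
                raise ValueError(f"unknown judgment {j!r}")


@dataclass(frozen=True)
class TrialOutcome:
    object_id: str
    delay: str
    congruency: str  # operationalized: 'congruent' | 'incongruent'
    context_response: str  # 'kitchen' | 'beach' | 'dont_know'
    scene_response: str  # scene_id | 'dont_know' | 'absent'
    grain: str  # 'detailed' | 'coarse' | 'forgotten'


def operationalize_congruency(j: EncodingJudgments) -> str:
    """Label a pair congruent iff >=2 of the 3 encoding judgments are
    'related'.

    Raises
    ------
    IndeterminateCongruency
        If more than one judgment is missing.
    """
    n_missing = sum(x == "missing" for x in j.judgments)
    if n_missing > 1:
        raise IndeterminateCongruency(
            f"{j.object_id}: {n_missing} of 3 encoding judgments missing"
        )
    n_related = sum(x == "related" for x in j.judgments)
    return "congruent" if n_related >= 2 else "incongruent"


def classify_grain(
    context_response: str, scene_response: str, truth: StimulusPair
) -> str:
    """Map a retrieval response pair onto a memory grain.

    detailed : correct context and correct specific scene
    coarse   : correct context, but scene 'dont_know' or the wrong scene of
               the same context
    forgotten: anything else (wrong or no context)
    """
    if context_response not in ("kitchen", "beach", "dont_know"):
        raise ValueError(f"unknown context response {context_response!r}")
    if context_response == "dont_know" or context_response != truth.context:
        return "forgotten"
    # context correct: a scene window must have been offered
    if scene_response == "absent":
        raise ValueError(
            "scene_response 'absent' but a context was chosen; "
            "scene window should have been offered"
        )
    if scene_response == truth.scene_id:
        return "detailed"
    if scene_response == "dont_know" or (
        scene_response in SCENES and SCENES[scene_response] == truth.context
    ):
        return "coarse"
    # a scene of the other context is not selectable given the chosen
    # context, but score it defensively as forgotten-grade
    return "forgotten"


def compute_scores(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Percent-correct scores per participant x delay x condition.

    Parameters
    ----------
    outcomes
        Tidy table with columns ``participant, delay, congruency, grain``
        (one row per retrieval trial).

    Returns
    -------
    DataFrame with columns ``participant, delay, congruency, n_trials,
    detailed_pct, coarse_pct, total_pct``.  Conditions with zero trials are
    absent (undefined scores are not fabricated).
    """
    required = {"participant", "delay", "congruency", "grain"}
    missing = required - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcomes table missing columns {sorted(missing)}")

    rows = []
    for (pid, delay, cong), grp in outcomes.groupby(
        ["participant", "delay", "congruency"], sort=True
    ):
        n = len(grp)
        detailed = (grp["grain"] == "detailed").sum()
        coarse = (grp["grain"] == "coarse").sum()
        rows.append(
            {
                "participant": pid,
                "delay": delay,
                "congruency": cong,
                "n_trials": n,
                "detailed_pct": 100.0 * detailed / n,
                "coarse_pct": 100.0 * coarse / n,
                "total_pct": 100.0 * (detailed + coarse) / n,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    scores: pd.DataFrame, threshold_pct: float = CHANCE_EXCLUSION_PCT
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop delay-level data for participants below chance at that delay.

    The pooled (conditions combined) total percent correct at each delay is
    compared to the strict ``< threshold`` rule; a failure removes only that
    participant's rows at the failing delay.

    Returns
    -------
    (retained scores, exclusion log) — the log has one row per excluded
    participant x delay with the pooled score that triggered it.
    """
    pooled = (
        scores.assign(
            n_remembered=lambda d: d["total_pct"] / 100.0 * d["n_trials"]
        )
        .groupby(["participant", "delay"])[["n_trials", "n_remembered"]]
        .sum()
        .reset_index()
    )
    pooled["pooled_total_pct"] = 100.0 * pooled["n_remembered"] / pooled["n_trials"]
    excluded = pooled[pooled["pooled_total_pct"] < threshold_pct]

    log = excluded[["participant", "delay", "pooled_total_pct"]].reset_index(drop=True)
    bad = set(zip(excluded["participant"], excluded["delay"]))
    keep = ~scores.apply(
        lambda r: (r["participant"], r["delay"]) in bad, axis=1
    ) if len(scores) else pd.Series([], dtype=bool)
    return scores[keep].reset_index(drop=True), log


def judgment_consistency(
    judgment_sets: list[EncodingJudgments], mode: str = "all3"
) -> float:
    """Percent of pairs judged consistently across the three encoding runs.

    ``mode='all3'`` counts a pair consistent only when all three non-missing
    judgments are identical (strictest reading); ``mode='pairwise'`` returns
    the mean percent of agreeing run pairs.  Pairs with any missing judgment
    are excluded from the denominator.
    """
    if mode not in ("all3", "pairwise"):
        raise ValueError(f"unknown consistency mode {mode!r}")
    usable = [
        j.judgments for j in judgment_sets if "missing" not in j.judgments
    ]
    if not usable:
        return float("nan")
    if mode == "all3":
        hits = sum(len(set(trio)) == 1 for trio in usable)
        return 100.0 * hits / len(usable)
    agree = [
        np.mean([a == b for a, b in ((t[0], t[1]), (t[0], t[2]), (t[1], t[2]))])
        for t in usable
    ]
    return 100.0 * float(np.mean(agree))
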