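"""Adjustment weights, strategy labels, exclusion rules and summaries.

The weight of advice s = (E2 - E1) / (X - E1) is computed exactly as a
:class:`fractions.Fraction`, so s = 0, s = 1 and the interval bounds are
never subject to floating-point ties.  Rounds are labelled:

=======================  ==========================================
label                    condition
=======================  ==========================================
stay                     E2 = E1                    (s = 0)
copy                     E2 = X != E1               (s = 1)
compromise               E2 strictly between E1, X  (0 < s < 1)
invalid_negative         s < 0  (moved away from X)
invalid_overshoot        s > 1  (moved past X)
undefined_zero_distance  X = E1 (s has no denominator)
=======================  ==========================================

Participants with three or more rounds outside {stay, copy, compromise}
are excluded from modelling; for retained participants only valid rounds
enter the adjustment and strategy analyses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Optional, Union

import pandas as pd

from .core_model import (
    CohortDataset,
    ParticipantRecord,
    TrialRound,
    VALID_LABELS,
)

#: Minimum number of unusable rounds that triggers participant exclusion.
EXCLUSION_THRESHOLD = 3

UNDEFINED = "undefined_zero_distance"


class UndefinedSummaryError(ValueError):
    """A summary was requested for a participant with no valid rounds."""


@dataclass(frozen=True)
class ParticipantSummary:
    participant_id: str
    group: str
    n_valid_rounds: int
    mean_s: Optional[float]
    prop_s_below_half: Optional[float]
    counts: tuple[int, int, int]  # (n_stay, n_copy, n_compromise)
    accuracy_ratio: float


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_retained: int
    n_excluded: int
    invalid_round_counts: dict
    n_rounds_total: int
    n_rounds_valid: int


def adjustment_weight(e1: int, x: int, e2: int) -> Union[Fraction, str]:
    """Exact weight of advice, or ``"undefined_zero_distance"`` when X = E1.

    Satisfies the reconstruction identity e2 = (1 - s)*e1 + s*x exactly.
    """
    if min(e1, x, e2) < 1:
        raise ValueError(f"estimates must be positive integers, got {(e1, x, e2)}")
    if x == e1:
        return UNDEFINED
    return Fraction(e2 - e1, x - e1)


def classify_round(rnd: TrialRound) -> TrialRound:
    """Return a copy of the round with ``s`` and ``label`` filled in."""
    s = adjustment_weight(rnd.e1, rnd.x, rnd.e2)
    if s == UNDEFINED:
        return replace(rnd, s=None, label=UNDEFINED)
    if s < 0:
        label = "invalid_negative"
    elif s > 1:
        label = "invalid_overshoot"
    elif s == 0:
        label = "stay"
    elif s == 1:
        label = "copy"
    else:
        label = "compromise"
    return replace(rnd, s=s, label=label)


def score_cohort(cohort: CohortDataset) -> CohortDataset:
    """Classify every round of every participant."""
    scored = [
        p.with_rounds([classify_round(r) for r in p.rounds]) for p in cohort.participants
    ]
    return CohortDataset(participants=scored, exclusion_log=list(cohort.exclusion_log))


def filter_participants(cohort: CohortDataset) -> tuple[CohortDataset, FilterReport]:
    """Drop participants with >= 3 unusable rounds; log them with a reason.

    Idempotent: running the filter twice gives the same retained set.
    Rounds must already be classified (see :func:`score_cohort`).
    """
    retained: list[ParticipantRecord] = []
    log = list(cohort.exclusion_log)
    invalid_counts: dict[str, int] = {}
    n_rounds_total = 0
    n_rounds_valid = 0
    for p in cohort.participants:
        if any(r.label is None for r in p.rounds):
            raise ValueError(
                f"participant {p.participant_id!r} has unclassified rounds; "
                "run score_cohort first"
            )
        n_rounds_total += len(p.rounds)
        for r in p.rounds:
            if r.is_valid:
                n_rounds_valid += 1
            else:
                invalid_counts[r.label] = invalid_counts.get(r.label, 0) + 1
        if p.n_invalid >= EXCLUSION_THRESHOLD:
            log.append((p.participant_id, "too_many_invalid_rounds"))
        else:
            retained.append(p)
    report = FilterReport(
        n_input=len(cohort.participants),
        n_retained=len(retained),
        n_excluded=len(cohort.participants) - len(retained),
        invalid_round_counts=invalid_counts,
        n_rounds_total=n_rounds_total,
        n_rounds_valid=n_rounds_valid,
    )
    return CohortDataset(participants=retained, exclusion_log=log), report


def summarize_participant(record: ParticipantRecord) -> ParticipantSummary:
    """Per-participant summary over valid rounds (accuracy over all rounds).

    ``accuracy_ratio`` is the mean of E1 / true_count across all five
    rounds: validity rules concern E2 only, so every first estimate counts.
    """
    valid = [r for r in record.rounds if r.is_valid]
    if any(r.label is None for r in record.rounds):
        raise ValueError("rounds must be classified before summarizing")
    counts = (
        sum(1 for r in valid if r.label == "stay"),
        sum(1 for r in valid if r.label == "copy"),
        sum(1 for r in valid if r.label == "compromise"),
    )
    if not valid:
        raise UndefinedSummaryError(
            f"participant {record.participant_id!r} has no valid rounds"
        )
    mean_s = float(sum(r.s for r in valid) / len(valid))
    prop_below = sum(1 for r in valid if r.s < Fraction(1, 2)) / len(valid)
    accuracy = sum(r.e1 / r.true_count for r in record.rounds) / len(record.rounds)
    return ParticipantSummary(
        participant_id=record.participant_id,
        group=record.group,
        n_valid_rounds=len(valid),
        mean_s=mean_s,
        prop_s_below_half=prop_below,
        counts=counts,
        accuracy_ratio=accuracy,
    )


def summarize_cohort(cohort: CohortDataset) -> list[ParticipantSummary]:
    return [summarize_participant(p) for p in cohort.participants]


def strategy_table(cohort: CohortDataset) -> pd.DataFrame:
    """Round-level strategy counts and shares by group (all labels).

    Percentages are of *valid* rounds, reported alongside the raw counts.
    """
    rows = []
    for group, members in cohort.by_group().items():
        counts: dict[str, int] = {}
        for p in members:
            for r in p.rounds:
                counts[r.label] = counts.get(r.label, 0) + 1
        n_valid = sum(counts.get(lbl, 0) for lbl in VALID_LABELS)
        for lbl, n in sorted(counts.items()):
            rows.append(
                {
                    "group": group,
                    "label": lbl,
                    "n_rounds": n,
                    "n_valid_rounds": n_valid,
                    "pct_of_valid": 100.0 * n / n_valid
                    if (n_valid and lbl in VALID_LABELS)
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def write_scored(cohort: CohortDataset, path) -> None:
    """Scored round-level CSV: input columns plus s (decimal), label, is_valid."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["participant_id", "group", "round", "true_count", "e1", "x", "e2",
             "age", "iq", "s", "label", "is_valid"]
        )
        for p in cohort.participants:
            for r in p.rounds:
                writer.writerow(
                    [
                        p.participant_id, p.group, r.round_index, r.true_count,
                        r.e1, r.x, r.e2,
                        "" if p.age_years is None else repr(p.age_years),
                        "" if p.iq is None else repr(p.iq),
                        "" if r.s is None else f"{float(r.s):.10g}",
                        r.label,
                        "" if r.is_valid is None else str(r.is_valid).lower(),
                    ]
                )


def write_summaries(summaries, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["participant_id", "group", "n_valid_rounds", "mean_s",
             "prop_s_below_half", "n_stay", "n_copy", "n_compromise", "accuracy_ratio"]
        )
        for s in summaries:
            writer.writerow(
                [
                    s.participant_id, s.group, s.n_valid_rounds,
                    "" if s.mean_s is None else f"{s.mean_s:.10g}",
                    "" if s.prop_s_below_half is None else f"{s.prop_s_below_half:.10g}",
                    *s.counts,
                    f"{s.accuracy_ratio:.10g}",
                ]
            )
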