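"""Domain types and round-level CSV I/O for the BEAST belief-updating task.

The task is a two-stage numerosity judgement: a participant estimates the
number of animals in a briefly shown image (E1), sees another person's
estimate (the social information X), and then gives a final estimate (E2).
The weight of advice s = (E2 - E1) / (X - E1) measures how far the
participant moved towards X; s = 0 means they kept their own estimate
("stay"), s = 1 means they adopted the other's ("copy"), and 0 < s < 1 is a
"compromise".  All estimates are integers (keyboard entry), so s is computed
in exact rational arithmetic and only converted to float for modelling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import pandas as pd

GROUPS = ("TD", "CP_LCU", "CP_HCU")

#: Round labels.  The first three are the behavioural strategies; the last
#: three mark rounds unusable for the adjustment analysis.
VALID_LABELS = ("stay", "copy", "compromise")
INVALID_LABELS = ("invalid_negative", "invalid_overshoot", "undefined_zero_distance")

REQUIRED_COLUMNS = ("participant_id", "group", "round", "true_count", "e1", "x", "e2")
OPTIONAL_COLUMNS = ("age", "iq")

N_ROUNDS = 5


class SchemaError(ValueError):
    """The CSV file does not have the required column layout."""


class CohortValueError(ValueError):
    """A cell holds a value of the wrong type or out of range."""


class IntegrityError(ValueError):
    """Structural violation: duplicate rounds, inconsistent per-participant data."""


@dataclass(frozen=True)
class TrialRound:
    """One task round.

    ``s`` and ``label`` are filled in by :mod:`beastlab.scoring`; a freshly
    loaded round has ``s=None`` and ``label=None``.
    """

    round_index: int
    true_count: int
    e1: int
    x: int
    e2: int
    s: Optional[Fraction] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("round_index", "true_count", "e1", "x", "e2"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise CohortValueError(f"{name} must be an integer, got {v!r}")
        if not 1 <= self.round_index <= N_ROUNDS:
            raise CohortValueError(f"round_index must be 1..{N_ROUNDS}, got {self.round_index}")
        if min(self.true_count, self.e1, self.x, self.e2) < 1:
            raise CohortValueError("true_count, e1, x, e2 must all be >= 1")

    @property
    def is_valid(self) -> Optional[bool]:
        if self.label is None:
            return None
        return self.label in VALID_LABELS


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group: str
    rounds: tuple[TrialRound, ...]
    age_years: Optional[float] = None
    iq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortValueError(
                f"group must be one of {GROUPS}, got {self.group!r} "
                f"(participant {self.participant_id})"
            )
        idx = sorted(r.round_index for r in self.rounds)
        if idx != list(range(1, N_ROUNDS + 1)):
            raise IntegrityError(
                f"participant {self.participant_id!r} has round indices {idx}; "
                f"expected exactly 1..{N_ROUNDS}"
            )

    @property
    def n_invalid(self) -> int:
        """Rounds whose label is not a usable strategy (requires scoring first)."""
        return sum(1 for r in self.rounds if r.label is not None and not r.is_valid)

    def with_rounds(self, rounds: Sequence[TrialRound]) -> "ParticipantRecord":
        return replace(self, rounds=tuple(sorted(rounds, key=lambda r: r.round_index)))


@dataclass
class CohortDataset:
    participants: list[ParticipantRecord]
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate participant ids: {dup}")

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def n_rounds(self) -> int:
        return sum(len(p.rounds) for p in self.participants)

    def by_group(self) -> dict[str, list[ParticipantRecord]]:
        out: dict[str, list[ParticipantRecord]] = {g: [] for g in GROUPS}
        for p in self.participants:
            out[p.group].append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy round-level view (one row per round)."""
        rows = []
        for p in self.participants:
            for r in p.rounds:
                rows.append(
                    {
                        "participant_id": p.participant_id,
                        "group": p.group,
                        "round": r.round_index,
                        "true_count": r.true_count,
                        "e1": r.e1,
                        "x": r.x,
                        "e2": r.e2,
                        "age": p.age_years,
                        "iq": p.iq,
                        "s": None if r.s is None else float(r.s),
                        "label": r.label,
                        "is_valid": r.is_valid,
                    }
                )
        return pd.DataFrame(rows)


def _parse_int(value: str, column: str, row_number: int) -> int:
    text = str(value).strip()
    try:
        return int(text)
    except (TypeError, ValueError):
        raise CohortValueError(
            f"row {row_number}, column {column!r}: expected an integer, got {value!r}"
        ) from None


def _parse_optional_float(value, column: str, row_number: int) -> Optional[float]:
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan", "none"}:
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortValueError(
            f"row {row_number}, column {column!r}: expected a number, got {value!r}"
        ) from None


def load_cohort(path) -> CohortDataset:
    """Read a round-level cohort CSV into a typed :class:`CohortDataset`.

    Row numbers in error messages count the header as row 1, so the first
    data row is row 2 (what a spreadsheet shows).
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        has_age = "age" in reader.fieldnames
        has_iq = "iq" in reader.fieldnames

        per_participant: dict[str, dict] = {}
        order: list[str] = []
        for row_number, row in enumerate(reader, start=2):
            pid = str(row["participant_id"]).strip()
            if not pid:
                raise CohortValueError(f"row {row_number}: empty participant_id")
            group = str(row["group"]).strip()
            rnd = _parse_int(row["round"], "round", row_number)
            tr = TrialRound(
                round_index=rnd,
                true_count=_parse_int(row["true_count"], "true_count", row_number),
                e1=_parse_int(row["e1"], "e1", row_number),
                x=_parse_int(row["x"], "x", row_number),
                e2=_parse_int(row["e2"], "e2", row_number),
            )
            age = _parse_optional_float(row.get("age"), "age", row_number) if has_age else None
            iq = _parse_optional_float(row.get("iq"), "iq", row_number) if has_iq else None

            if pid not in per_participant:
                per_participant[pid] = {"group": group, "age": age, "iq": iq, "rounds": {}}
                order.append(pid)
            bucket = per_participant[pid]
            if bucket["group"] != group:
                raise IntegrityError(
                    f"row {row_number}: participant {pid!r} appears with group "
                    f"{group!r} but was previously {bucket['group']!r}"
                )
            if rnd in bucket["rounds"]:
                raise IntegrityError(
                    f"row {row_number}: duplicate round {rnd} for participant {pid!r}"
                )
            bucket["rounds"][rnd] = tr

    participants = [
        ParticipantRecord(
            participant_id=pid,
            group=per_participant[pid]["group"],
            rounds=tuple(
                per_participant[pid]["rounds"][k]
                for k in sorted(per_participant[pid]["rounds"])
            ),
            age_years=per_participant[pid]["age"],
            iq=per_participant[pid]["iq"],
        )
        for pid in order
    ]
    return CohortDataset(participants=participants)


def write_cohort(cohort: CohortDataset, path) -> None:
    """Write the round-level CSV; inverse of :func:`load_cohort`."""
    has_cov = any(p.age_years is not None or p.iq is not None for p in cohort.participants)
    columns = list(REQUIRED_COLUMNS) + (list(OPTIONAL_COLUMNS) if has_cov else [])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for p in cohort.participants:
            for r in p.rounds:
                row = [p.participant_id, p.group, r.round_index, r.true_count, r.e1, r.x, r.e2]
                if has_cov:
                    row += [
                        "" if p.age_years is None else repr(p.age_years),
                        "" if p.iq is None else repr(p.iq),
                    ]
                writer.writerow(row)


def write_exclusion_log(cohort: CohortDataset, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "reason"])
        writer.writerows(cohort.exclusion_log)
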