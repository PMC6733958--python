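"""Athlete table ingest, validation, and group partitioning.

The row unit of all downstream analysis is :class:`AthleteRecord`: one
finalist's variables for one competition edition.  Finalists are ranked
1..8; ranks 1-3 are medalists, 4-8 non-medalists.  Six variables become
network nodes by default; race time and velocity are outcome variables
and are rejected as nodes unless explicitly overridden.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Default node variables, in canonical column order.
NODE_VARIABLES: tuple[str, ...] = (
    "age",
    "weight",
    "height",
    "bmi",
    "olympic_medals",
    "reaction_time",
)

#: Outcome variables excluded from networks by default (they directly
#: encode the race result and would bias the model).
OUTCOME_VARIABLES: tuple[str, ...] = ("race_time", "velocity")

MEDALIST = "medalist"
NON_MEDALIST = "non_medalist"
GROUP_LABELS = (MEDALIST, NON_MEDALIST)

#: Exact CSV header names (mandatory part).
CSV_MANDATORY_COLUMNS = {
    "edition": "edition_label",
    "rank": "finish_rank",
    "age": "age",
    "weight_kg": "weight",
    "height_cm": "height",
    "bmi": "bmi",
    "olympic_medals": "olympic_medals",
    "reaction_time_s": "reaction_time",
}
CSV_OPTIONAL_COLUMNS = {
    "race_time_s": "race_time",
    "velocity_ms": "velocity",
}

_FINAL_SIZE = 8
_MEDAL_RANKS = frozenset({1, 2, 3})
_DISTANCE_M = 50.0  # event length used for the velocity/race-time check


class CohortError(ValueError):
    """Raised for schema or consistency violations in athlete tables."""


@dataclass(frozen=True)
class AthleteRecord:
    """One finalist's variables for one edition.

    ``degenerate_flags`` names variables that were generated (or
    observed) with zero spread and therefore cannot carry correlation
    information within their group.
    """

    edition_label: str
    finish_rank: int
    age: float
    weight: float
    height: float
    bmi: float
    olympic_medals: int
    reaction_time: float
    race_time: float | None = None
    velocity: float | None = None
    degenerate_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        # ranks > 8 are tolerated on the record itself so large synthetic
        # calibration draws are possible; the 1..8 window is enforced at
        # CSV ingest and by GroupTable.
        if self.finish_rank < 1:
            raise CohortError(f"finish_rank must be >= 1, got {self.finish_rank}")
        for name in ("weight", "height", "reaction_time"):
            if getattr(self, name) <= 0:
                raise CohortError(f"{name} must be positive, got {getattr(self, name)}")
        if self.olympic_medals < 0:
            raise CohortError("olympic_medals must be non-negative")
        if self.race_time is not None and self.velocity is not None:
            implied = _DISTANCE_M / self.race_time
            if abs(self.velocity - implied) > 0.01 * implied:
                raise CohortError(
                    f"velocity {self.velocity} inconsistent with race_time "
                    f"{self.race_time} (expected ~{implied:.3f} m/s for a "
                    f"{_DISTANCE_M:.0f} m event)"
                )

    @property
    def is_medalist(self) -> bool:
        return self.finish_rank in _MEDAL_RANKS

    def variable(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            raise CohortError(f"variable {name!r} is absent on this record")
        return float(value)


@dataclass
class GroupTable:
    """All records of one (edition, group) with an ordered node-variable list."""

    edition_label: str
    group_label: str
    records: list[AthleteRecord]
    variables: tuple[str, ...] = NODE_VARIABLES

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise CohortError(f"group_label must be one of {GROUP_LABELS}")
        ranks = {r.finish_rank for r in self.records}
        expected = _MEDAL_RANKS if self.group_label == MEDALIST else (
            set(range(4, _FINAL_SIZE + 1))
        )
        if self.records and not ranks <= expected:
            raise CohortError(
                f"{self.group_label} table may only hold ranks {sorted(expected)}, "
                f"got {sorted(ranks)}"
            )

    @property
    def n_athletes(self) -> int:
        return len(self.records)


def read_cohort_csv(path: str | Path) -> list[AthleteRecord]:
    """Read athlete records from a cohort CSV.

    The header is matched case-insensitively and order-free; optional
    columns (``race_time_s``, ``velocity_ms``) may be absent and unknown
    columns (e.g. birth year) are ignored.  Malformed numeric cells are
    reported with their row number.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    frame.columns = [str(c).strip().lower() for c in frame.columns]

    missing = sorted(set(CSV_MANDATORY_COLUMNS) - set(frame.columns))
    if missing:
        raise CohortError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[AthleteRecord] = []
    seen: set[tuple[str, int]] = set()
    column_map = dict(CSV_MANDATORY_COLUMNS)
    column_map.update(
        {c: f for c, f in CSV_OPTIONAL_COLUMNS.items() if c in frame.columns}
    )
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        raw = dict(zip(frame.columns, row))
        kwargs: dict[str, object] = {}
        for column, fieldname in column_map.items():
            cell = raw[column]
            if fieldname == "edition_label":
                kwargs[fieldname] = str(cell).strip()
                continue
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and not cell.strip()
            ):
                if column in CSV_OPTIONAL_COLUMNS:
                    kwargs[fieldname] = None
                    continue
                raise CohortError(f"row {i}: empty value in mandatory column {column!r}")
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise CohortError(
                    f"row {i}: malformed numeric value {cell!r} in column {column!r}"
                ) from None
            if fieldname in ("finish_rank", "olympic_medals"):
                if value != int(value):
                    raise CohortError(
                        f"row {i}: column {column!r} must be an integer, got {cell!r}"
                    )
                value = int(value)
            kwargs[fieldname] = value
        rank = kwargs.get("finish_rank")
        if not isinstance(rank, int) or not 1 <= rank <= _FINAL_SIZE:
            raise CohortError(
                f"row {i}: rank must be in [1, {_FINAL_SIZE}], got {rank}"
            )
        try:
            record = AthleteRecord(**kwargs)  # type: ignore[arg-type]
        except CohortError as exc:
            raise CohortError(f"row {i}: {exc}") from None
        key = (record.edition_label, record.finish_rank)
        if key in seen:
            raise CohortError(f"row {i}: duplicate (edition, rank) {key}")
        seen.add(key)
        records.append(record)
    return records


def write_cohort_csv(records: Iterable[AthleteRecord], path: str | Path) -> Path:
    """Write records to the canonical cohort CSV schema."""
    path = Path(path)
    rows = []
    records = list(records)
    with_optional = any(r.race_time is not None or r.velocity is not None for r in records)
    for r in records:
        row = {
            "edition": r.edition_label,
            "rank": r.finish_rank,
            "age": r.age,
            "weight_kg": r.weight,
            "height_cm": r.height,
            "bmi": r.bmi,
            "olympic_medals": r.olympic_medals,
            "reaction_time_s": r.reaction_time,
        }
        if with_optional:
            row["race_time_s"] = r.race_time
            row["velocity_ms"] = r.velocity
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    return path


def group_by_edition(records: Iterable[AthleteRecord]) -> dict[str, list[AthleteRecord]]:
    """Group records by edition label, preserving first-seen order."""
    editions: dict[str, list[AthleteRecord]] = {}
    for record in records:
        editions.setdefault(record.edition_label, []).append(record)
    return editions


def split_by_medal(records: Sequence[AthleteRecord]) -> tuple[GroupTable, GroupTable]:
    """Partition one edition's 8 finalists into medalist / non-medalist tables.

    Requires exactly 8 records with distinct ranks 1..8 and a single
    edition label.  Every input record lands in exactly one output group.
    """
    records = list(records)
    editions = {r.edition_label for r in records}
    if len(editions) != 1:
        raise CohortError(f"expected records from a single edition, got {sorted(editions)}")
    ranks = sorted(r.finish_rank for r in records)
    if ranks != list(range(1, _FINAL_SIZE + 1)):
        raise CohortError(
            f"expected exactly {_FINAL_SIZE} records with distinct ranks "
            f"1..{_FINAL_SIZE}, got ranks {ranks}"
        )
    edition = next(iter(editions))
    medal = sorted((r for r in records if r.is_medalist), key=lambda r: r.finish_rank)
    rest = sorted((r for r in records if not r.is_medalist), key=lambda r: r.finish_rank)
    return (
        GroupTable(edition, MEDALIST, medal),
        GroupTable(edition, NON_MEDALIST, rest),
    )


def select_node_variables(
    group: GroupTable,
    variables: Sequence[str] | None = None,
    *,
    allow_outcome_variables: bool = False,
) -> np.ndarray:
    """Return the (n_athletes x n_variables) matrix for the requested variables.

    Column order follows the request exactly.  Outcome variables
    (race time, velocity) are rejected unless explicitly allowed: they
    directly predict the finish result, so using them as nodes would
    bias the network toward the outcome.
    """
    requested = tuple(variables) if variables is not None else tuple(group.variables)
    if not allow_outcome_variables:
        banned = [v for v in requested if v in OUTCOME_VARIABLES]
        if banned:
            raise CohortError(
                f"variable(s) {banned} are outcome measures and are excluded "
                "from networks to avoid bias; pass allow_outcome_variables=True "
                "to override"
            )
    known = {f.name for f in dataclasses.fields(AthleteRecord)}
    for v in requested:
        if v not in known:
            raise CohortError(f"unknown variable {v!r}")
    matrix = np.empty((len(group.records), len(requested)), dtype=float)
    for i, record in enumerate(group.records):
        for j, v in enumerate(requested):
            matrix[i, j] = record.variable(v)
    return matrix
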