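"""Per-patient cohort records and 2x2 contingency tables.

The unit of observation is one CABG patient with reduced ejection fraction
(LVEF < 40%), assigned to either the levosimendan-preconditioning arm or
standard care. Six binary postoperative outcomes are tracked (new-onset
atrial fibrillation, low cardiac output, cardiogenic shock, renal failure,
prolonged mechanical ventilation, in-hospital death) together with ICU and
postoperative-ward lengths of stay.

Cohort files are plain CSV with a mandatory header::

    id,arm,lvef_stratum,noaf,lco,cardiogenic_shock,renal_failure,
    prolonged_mv,death,icu_los,ward_los

Booleans are coded 0/1; ``arm`` is ``intervention``/``control``;
``lvef_stratum`` is ``lvef_35_40``/``lvef_lt_35``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import (
    ConsistencyError,
    DegenerateTableError,
    ParseError,
    SchemaError,
    UndefinedProportionError,
    ValidationError,
)


class Arm(str, Enum):
    INTERVENTION = "intervention"
    CONTROL = "control"


class LvefStratum(str, Enum):
    """LVEF stratum used for the stratified (Mantel-Haenszel) analysis."""

    LVEF_35_40 = "lvef_35_40"
    LVEF_LT_35 = "lvef_lt_35"


#: Binary outcome flags, in the order they appear in the cohort schema.
EVENT_FLAGS = (
    "noaf",
    "lco",
    "cardiogenic_shock",
    "renal_failure",
    "prolonged_mv",
    "death",
)

#: The four complications that define the effectiveness endpoint
#: (a patient is "complication-free" when none of these occurred).
MODEL_EVENTS = ("noaf", "lco", "renal_failure", "prolonged_mv")

COHORT_COLUMNS = (
    "id",
    "arm",
    "lvef_stratum",
    *EVENT_FLAGS,
    "icu_los",
    "ward_los",
)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: arm assignment, LVEF stratum, outcomes and stays."""

    id: str
    arm: Arm
    lvef_stratum: LvefStratum
    noaf: bool
    lco: bool
    cardiogenic_shock: bool
    renal_failure: bool
    prolonged_mv: bool
    death: bool
    icu_los: float
    ward_los: float

    def __post_init__(self) -> None:
        if self.cardiogenic_shock and not self.lco:
            raise ConsistencyError(
                f"record {self.id!r}: cardiogenic shock implies low cardiac "
                "output (shock is the severe extreme of the LCO definition)"
            )
        for name in ("icu_los", "ward_los"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"record {self.id!r}: {name} must be finite and >= 0, got {v}"
                )

    @property
    def complication_free(self) -> bool:
        """True when none of the four modelled complications occurred."""
        return not any(getattr(self, e) for e in MODEL_EVENTS)


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 event-by-arm counts.

    ``a`` = intervention with event, ``b`` = intervention without,
    ``c`` = control with event, ``d`` = control without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"count {name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) = (intervention, control, event, no event)."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class StratumSet:
    """Ordered labelled strata of fourfold tables for a stratified test."""

    strata: tuple[tuple[str, FourfoldTable], ...]

    def __post_init__(self) -> None:
        if len(self.strata) < 1:
            raise ValidationError("a StratumSet needs at least one stratum")

    def pooled(self) -> FourfoldTable:
        return FourfoldTable(
            a=sum(t.a for _, t in self.strata),
            b=sum(t.b for _, t in self.strata),
            c=sum(t.c for _, t in self.strata),
            d=sum(t.d for _, t in self.strata),
        )


def _parse_flag(raw: str, column: str, row: int) -> bool:
    v = raw.strip().lower()
    if v in {"0", "false"}:
        return False
    if v in {"1", "true"}:
        return True
    raise ParseError(f"row {row}: column {column!r} must be 0/1, got {raw!r}")


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV into a list of :class:`PatientRecord`.

    Raises :class:`SchemaError` when a required column is missing,
    :class:`ParseError` on malformed values (with the offending row number)
    and :class:`ConsistencyError` when a row records shock without LCO.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"cohort file {path} is missing column(s): {missing}")
        records: list[PatientRecord] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                arm = Arm(row["arm"].strip())
                stratum = LvefStratum(row["lvef_stratum"].strip())
            except ValueError as exc:
                raise ParseError(f"row {i}: {exc}") from exc
            try:
                icu = float(row["icu_los"])
                ward = float(row["ward_los"])
            except ValueError as exc:
                raise ParseError(f"row {i}: length of stay not numeric") from exc
            records.append(
                PatientRecord(
                    id=row["id"],
                    arm=arm,
                    lvef_stratum=stratum,
                    icu_los=icu,
                    ward_los=ward,
                    **{e: _parse_flag(row[e], e, i) for e in EVENT_FLAGS},
                )
            )
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to CSV in the documented schema (booleans as 0/1)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [r.id, r.arm.value, r.lvef_stratum.value]
                + [int(getattr(r, e)) for e in EVENT_FLAGS]
                + [r.icu_los, r.ward_los]
            )


def tabulate(records: Sequence[PatientRecord], event: str) -> FourfoldTable:
    """Build the event-by-arm fourfold table for one outcome flag."""
    if event not in EVENT_FLAGS:
        raise ValidationError(f"unknown event flag {event!r}; choose from {EVENT_FLAGS}")
    a = b = c = d = 0
    for r in records:
        flag = bool(getattr(r, event))
        if r.arm is Arm.INTERVENTION:
            a, b = (a + 1, b) if flag else (a, b + 1)
        else:
            c, d = (c + 1, d) if flag else (c, d + 1)
    return FourfoldTable(a, b, c, d)


def stratified_tables(records: Sequence[PatientRecord], event: str) -> StratumSet:
    """Fourfold tables per LVEF stratum (35-40% first, then < 35%)."""
    strata = []
    for stratum in (LvefStratum.LVEF_35_40, LvefStratum.LVEF_LT_35):
        subset = [r for r in records if r.lvef_stratum is stratum]
        if subset:
            strata.append((stratum.value, tabulate(subset, event)))
    if not strata:
        raise DegenerateTableError("no records to stratify")
    return StratumSet(tuple(strata))


def arm_percentages(t: FourfoldTable) -> tuple[float, float]:
    """Event percentage per arm, rounded to one decimal place."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise UndefinedProportionError("cannot compute a percentage for an empty arm")
    return (
        round(100.0 * t.a / (t.a + t.b), 1),
        round(100.0 * t.c / (t.c + t.d), 1),
    )


def complication_free_counts(records: Sequence[PatientRecord]) -> dict[Arm, tuple[int, int]]:
    """Per arm: (number complication-free, arm size)."""
    out: dict[Arm, tuple[int, int]] = {}
    for arm in Arm:
        sub = [r for r in records if r.arm is arm]
        out[arm] = (sum(r.complication_free for r in sub), len(sub))
    return out
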