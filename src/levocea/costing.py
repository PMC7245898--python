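"""Unit-cost catalogue and per-pathway costing.

The catalogue mirrors the hospital-accounting price list used by the
evaluation: 23 items grouped into procedures, supplemental tests,
medications and stays, all in euros. Costs carry no discounting (the model
horizon runs from intervention to discharge) and are held as plain floats;
display rounding to 2 dp happens only at the reporting edge.

A :class:`ResourceProfile` is a bag of quantities keyed by catalogue code;
``pathway_cost`` is the (linear) inner product of quantities and unit costs,
with a per-category breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .exceptions import LookupError_, ValidationError


class CostCategory(str, Enum):
    PROCEDURE = "procedure"
    TEST = "test"
    MEDICATION = "medication"
    STAY = "stay"


@dataclass(frozen=True)
class UnitCost:
    code: str
    label: str
    unit_cost: float
    category: CostCategory

    def __post_init__(self) -> None:
        if not (self.unit_cost >= 0.0 and self.unit_cost == self.unit_cost):
            raise ValidationError(f"{self.code}: unit cost must be finite and >= 0")


@dataclass(frozen=True)
class CostCatalogue:
    entries: Mapping[str, UnitCost]

    def __getitem__(self, code: str) -> UnitCost:
        try:
            return self.entries[code]
        except KeyError:
            raise LookupError_(f"unknown catalogue code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def cost(self, code: str) -> float:
        return self[code].unit_cost

    def replace(self, **overrides: float) -> "CostCatalogue":
        """New catalogue with some unit costs replaced (codes must exist)."""
        new = dict(self.entries)
        for code, value in overrides.items():
            old = self[code]
            new[code] = UnitCost(old.code, old.label, float(value), old.category)
        return CostCatalogue(new)


@dataclass(frozen=True)
class ResourceProfile:
    """Quantities of catalogue items consumed on one pathway segment."""

    quantities: Mapping[str, float]
    applies_to: str = ""

    def __post_init__(self) -> None:
        for code, q in self.quantities.items():
            if not (q >= 0.0 and q == q):
                raise ValidationError(f"quantity for {code!r} must be finite and >= 0")

    def scaled(self, factor: float) -> "ResourceProfile":
        return ResourceProfile(
            {c: q * factor for c, q in self.quantities.items()}, self.applies_to
        )

    def merged(self, other: "ResourceProfile") -> "ResourceProfile":
        out = dict(self.quantities)
        for c, q in other.quantities.items():
            out[c] = out.get(c, 0.0) + q
        return ResourceProfile(out, self.applies_to)


@dataclass(frozen=True)
class PathwayCost:
    total: float
    breakdown: Mapping[str, float] = field(default_factory=dict)


def _parse_entry(code: str, raw: object) -> UnitCost:
    if not isinstance(raw, dict) or "unit_cost" not in raw or "label" not in raw:
        raise ValidationError(f"catalogue entry {code!r} needs 'label' and 'unit_cost'")
    unknown = set(raw) - {"label", "unit_cost", "category"}
    if unknown:
        raise ValidationError(f"catalogue entry {code!r} has unknown keys {sorted(unknown)}")
    cost = float(raw["unit_cost"])
    if cost < 0:
        raise ValidationError(f"catalogue entry {code!r} has negative cost {cost}")
    return UnitCost(
        code=code,
        label=str(raw["label"]),
        unit_cost=cost,
        category=CostCategory(raw.get("category", "procedure")),
    )


def load_catalogue(path: str | Path) -> CostCatalogue:
    """Load a YAML unit-cost catalogue; rejects negative costs and duplicates."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"catalogue file {path} must be a mapping")
    entries: dict[str, UnitCost] = {}
    for code, item in raw.items():
        if code in entries:
            raise ValidationError(f"duplicate catalogue code {code!r}")
        entries[code] = _parse_entry(str(code), item)
    return CostCatalogue(entries)


def default_catalogue() -> CostCatalogue:
    """The packaged 23-item hospital price list."""
    ref = resources.files("levocea.data").joinpath("catalogue.yaml")
    with resources.as_file(ref) as p:
        return load_catalogue(p)


def write_catalogue(catalogue: CostCatalogue, path: str | Path) -> None:
    """Write a catalogue back to YAML (round-trips with ``load_catalogue``)."""
    out = {
        code: {
            "label": uc.label,
            "unit_cost": uc.unit_cost,
            "category": uc.category.value,
        }
        for code, uc in catalogue.entries.items()
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(out, fh, sort_keys=False, allow_unicode=True)


def pathway_cost(profile: ResourceProfile, catalogue: CostCatalogue) -> PathwayCost:
    """Total cost of a resource profile: sum of quantity x unit cost."""
    total = 0.0
    breakdown: dict[str, float] = {}
    for code, qty in profile.quantities.items():
        uc = catalogue[code]
        amount = qty * uc.unit_cost
        total += amount
        breakdown[uc.category.value] = breakdown.get(uc.category.value, 0.0) + amount
    return PathwayCost(total=total, breakdown=breakdown)


def intervention_upfront_profile(
    levosimendan_vials: float = 1.0,
    coronary_days: float = 1.0,
    extra_ward_days: float = 1.0,
) -> ResourceProfile:
    """Pre-operative add-on consumed only by the preconditioning arm.

    The 48-hour pre-operative admission: the 24-h levosimendan infusion
    monitored in the coronary care unit, then 24 h on the surgical ward.
    Defaults are one vial-course, one coronary-unit day and one extra ward
    day; all quantities configurable.
    """
    return ResourceProfile(
        {
            "levosimendan": levosimendan_vials,
            "coronary_unit_day": coronary_days,
            "ward_day": extra_ward_days,
        },
        applies_to="intervention pre-operative admission",
    )
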