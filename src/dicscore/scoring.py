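"""Declarative definitions and evaluation of the ISTH overt-DIC score and
eight modified scoring systems for AML bleeding-risk prediction.

The original ISTH score sums points over four coagulation components
(platelets, D-dimer, fibrinogen, prothrombin-time prolongation); a total
of 5 or more defines overt DIC.  The modified scores either add one
marker to the original four (LDH at a 400 or 800 threshold, hemoglobin,
INR, or genetic positivity; positivity threshold raised to 6) or drop
D-dimer and add LDH and/or genetic positivity (thresholds 5 or 4).

Boundary convention
-------------------
Published bin definitions use strict inequalities on both sides
(e.g. ">100 = 0, <100 = 1"), leaving exact threshold values unassigned.
Here a value exactly at a threshold goes to the *lower-risk* (fewer
points) bin, except where an explicit >=/<= is published (LDH >=400/>=800
scores 1; INR <=1.2 and hemoglobin >=7 score 0).  The convention is
encoded once, in the interval tables below, so it is auditable and
exported with :func:`definitions_to_json`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from typing import Optional, Union

import pandas as pd

from .cohort import Cohort, PatientRecord

__all__ = [
    "Component",
    "ScoreId",
    "Bin",
    "ComponentRule",
    "ScoreDefinition",
    "ScoreResult",
    "ScoreTable",
    "ComponentMissingError",
    "SCORE_DEFINITIONS",
    "PT_UPPER_NORMAL_S",
    "pt_prolongation",
    "component_points",
    "compute_score",
    "score_all",
    "definitions_to_json",
]

#: Upper limit of the laboratory PT normal range (11.5-13.5 s); PT
#: prolongation is scored as seconds over this baseline.
PT_UPPER_NORMAL_S = 13.5


class Component(str, enum.Enum):
    PT_PROLONGATION = "pt_prolongation"
    D_DIMER = "d_dimer"
    FIBRINOGEN = "fibrinogen"
    PLATELET = "platelet"
    LDH400 = "ldh400"
    LDH800 = "ldh800"
    HGB = "hgb"
    INR = "inr"
    GENETICS = "genetics"


class ScoreId(str, enum.Enum):
    ORIGINAL = "ORIGINAL"
    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"
    M5 = "M5"
    M6 = "M6"
    M7 = "M7"
    M8 = "M8"


class ComponentMissingError(ValueError):
    """A score requires a lab component that the record does not carry."""

    def __init__(self, component: Component, score_id: Optional[ScoreId] = None,
                 patient_id: Optional[str] = None):
        self.component = component
        self.score_id = score_id
        self.patient_id = patient_id
        where = f" for score {score_id.value}" if score_id else ""
        who = f" (patient {patient_id!r})" if patient_id else ""
        super().__init__(f"missing value for component {component.value!r}{where}{who}")


@dataclasses.dataclass(frozen=True)
class Bin:
    """Half-bounded interval on the component's canonical scale -> points."""

    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool
    points: int

    def contains(self, v: float) -> bool:
        lo_ok = v >= self.lower if self.lower_closed else v > self.lower
        hi_ok = v <= self.upper if self.upper_closed else v < self.upper
        return lo_ok and hi_ok


def _bins(*edges_points) -> tuple[Bin, ...]:
    """Build a gap-free partition of [0, inf) from (upper_edge, edge_scores_here, pts)."""
    out = []
    lo, lo_closed = 0.0, True
    for upper, upper_closed, pts in edges_points:
        out.append(Bin(lo, upper, lo_closed, upper_closed, pts))
        lo, lo_closed = upper, not upper_closed
    return tuple(out)


@dataclasses.dataclass(frozen=True)
class ComponentRule:
    """Binning rule mapping one component's value to integer points."""

    component: Component
    bins: tuple[Bin, ...]  # empty for GENETICS (boolean rule)
    max_points: int

    def points(self, value: Union[float, bool]) -> int:
        if self.component == Component.GENETICS:
            return 1 if value else 0
        if not isinstance(value, (int, float)) or isinstance(value, bool) or not math.isfinite(value):
            raise ValueError(f"{self.component.value}: expected finite numeric, got {value!r}")
        matches = [b for b in self.bins if b.contains(value)]
        assert len(matches) == 1, f"bins must match exactly once, got {len(matches)} for {value}"
        return matches[0].points


_RULES: dict[Component, ComponentRule] = {
    # PT prolongation (s over upper normal): <3 -> 0, 3-6 -> 1, >6 -> 2;
    # exact 3 and 6 fall to the lower-point bin.
    Component.PT_PROLONGATION: ComponentRule(
        Component.PT_PROLONGATION,
        _bins((3.0, True, 0), (6.0, True, 1), (math.inf, True, 2)),
        2,
    ),
    # D-dimer (ng/mL): <500 -> 0, 500-4000 -> 2 (moderate increase),
    # >4000 -> 3 (strong increase); both stated limits belong to the
    # moderate bin.
    Component.D_DIMER: ComponentRule(
        Component.D_DIMER,
        _bins((500.0, False, 0), (4000.0, True, 2), (math.inf, True, 3)),
        3,
    ),
    # fibrinogen (mg/dL): >100 -> 0, <100 -> 1; exact 100 -> 0
    Component.FIBRINOGEN: ComponentRule(
        Component.FIBRINOGEN,
        _bins((100.0, False, 1), (math.inf, True, 0)),
        1,
    ),
    # platelets (1e9/L): >100 -> 0, <100 -> 1, <50 -> 2; 50 -> 1, 100 -> 0
    Component.PLATELET: ComponentRule(
        Component.PLATELET,
        _bins((50.0, False, 2), (100.0, False, 1), (math.inf, True, 0)),
        2,
    ),
    # LDH (reported scale): >=400 -> 1
    Component.LDH400: ComponentRule(
        Component.LDH400, _bins((400.0, False, 0), (math.inf, True, 1)), 1
    ),
    # LDH (reported scale): >=800 -> 1
    Component.LDH800: ComponentRule(
        Component.LDH800, _bins((800.0, False, 0), (math.inf, True, 1)), 1
    ),
    # hemoglobin (g/dL): >=7 -> 0, <7 -> 1
    Component.HGB: ComponentRule(
        Component.HGB, _bins((7.0, False, 1), (math.inf, True, 0)), 1
    ),
    # INR: <=1.2 -> 0, >1.2 -> 1
    Component.INR: ComponentRule(
        Component.INR, _bins((1.2, True, 0), (math.inf, True, 1)), 1
    ),
    Component.GENETICS: ComponentRule(Component.GENETICS, (), 1),
}


@dataclasses.dataclass(frozen=True)
class ScoreDefinition:
    score_id: ScoreId
    components: tuple[Component, ...]
    positivity_threshold: int

    @property
    def rules(self) -> tuple[ComponentRule, ...]:
        return tuple(_RULES[c] for c in self.components)

    @property
    def max_total(self) -> int:
        return sum(r.max_points for r in self.rules)


_CORE = (Component.PT_PROLONGATION, Component.D_DIMER, Component.FIBRINOGEN,
         Component.PLATELET)
_NO_DD = (Component.PT_PROLONGATION, Component.FIBRINOGEN, Component.PLATELET)

SCORE_DEFINITIONS: dict[ScoreId, ScoreDefinition] = {
    ScoreId.ORIGINAL: ScoreDefinition(ScoreId.ORIGINAL, _CORE, 5),
    ScoreId.M1: ScoreDefinition(ScoreId.M1, _CORE + (Component.LDH400,), 6),
    ScoreId.M2: ScoreDefinition(ScoreId.M2, _CORE + (Component.LDH800,), 6),
    ScoreId.M3: ScoreDefinition(ScoreId.M3, _CORE + (Component.GENETICS,), 6),
    ScoreId.M4: ScoreDefinition(ScoreId.M4, _CORE + (Component.HGB,), 6),
    ScoreId.M5: ScoreDefinition(ScoreId.M5, _CORE + (Component.INR,), 6),
    ScoreId.M6: ScoreDefinition(
        ScoreId.M6, _NO_DD + (Component.LDH400, Component.GENETICS), 5
    ),
    ScoreId.M7: ScoreDefinition(
        ScoreId.M7, _NO_DD + (Component.LDH800, Component.GENETICS), 5
    ),
    ScoreId.M8: ScoreDefinition(ScoreId.M8, _NO_DD + (Component.GENETICS,), 4),
}


@dataclasses.dataclass(frozen=True)
class ScoreResult:
    patient_id: str
    score_id: ScoreId
    component_points: dict[Component, int]
    total: int
    positive: bool


def pt_prolongation(pt_seconds: float, baseline: float = PT_UPPER_NORMAL_S) -> float:
    """Prothrombin-time prolongation: seconds over the upper normal limit,
    floored at zero (a PT within or below the normal range is not prolonged)."""
    return max(pt_seconds - baseline, 0.0)


def component_points(rule: ComponentRule, value: Union[float, bool, None]) -> int:
    """Points a component rule assigns to a canonical-scale value.

    Raises :class:`ComponentMissingError` if the value is ``None``.
    """
    if value is None:
        raise ComponentMissingError(rule.component)
    return rule.points(value)


def _canonical_value(record: PatientRecord, component: Component):
    if component == Component.PT_PROLONGATION:
        return None if record.pt_seconds is None else pt_prolongation(record.pt_seconds)
    field = {
        Component.D_DIMER: "d_dimer_ng_ml",
        Component.FIBRINOGEN: "fibrinogen_mg_dl",
        Component.PLATELET: "platelet_1e9_l",
        Component.LDH400: "ldh",
        Component.LDH800: "ldh",
        Component.HGB: "hemoglobin_g_dl",
        Component.INR: "inr",
        Component.GENETICS: "genetic_positive",
    }[component]
    return getattr(record, field)


def compute_score(record: PatientRecord, score_id: ScoreId) -> ScoreResult:
    """Evaluate one scoring system on one patient record.

    Pure and deterministic; the subgroup never alters scoring.  A lab
    component required by this score but missing on the record raises
    :class:`ComponentMissingError` naming the score and component.
    """
    definition = SCORE_DEFINITIONS[ScoreId(score_id)]
    pts: dict[Component, int] = {}
    for rule in definition.rules:
        value = _canonical_value(record, rule.component)
        if value is None:
            raise ComponentMissingError(rule.component, definition.score_id,
                                        record.patient_id)
        pts[rule.component] = rule.points(value)
    total = sum(pts.values())
    return ScoreResult(
        patient_id=record.patient_id,
        score_id=definition.score_id,
        component_points=pts,
        total=total,
        positive=total >= definition.positivity_threshold,
    )


@dataclasses.dataclass
class ScoreTable:
    """All score results for a cohort, with scoring failures kept visible."""

    results: list[ScoreResult]
    failures: list[ComponentMissingError]

    def to_frame(self) -> pd.DataFrame:
        """One row per (patient, score); one column per component (blank
        where a score does not use the component), plus total and positivity."""
        rows = []
        for r in self.results:
            row = {"patient_id": r.patient_id, "score_id": r.score_id.value}
            for c in Component:
                row[c.value] = r.component_points.get(c, pd.NA)
            row["total"] = r.total
            row["positive"] = int(r.positive)
            rows.append(row)
        cols = ["patient_id", "score_id", *[c.value for c in Component],
                "total", "positive"]
        return pd.DataFrame(rows, columns=cols)


def score_all(cohort: Cohort, score_ids: list[ScoreId]) -> ScoreTable:
    """Score every patient with every requested system.

    Records missing a component required by a particular score are
    reported in ``failures`` for that score and still scored by the
    systems that do not need the component.
    """
    results, failures = [], []
    for record in cohort.records:
        for sid in score_ids:
            try:
                results.append(compute_score(record, sid))
            except ComponentMissingError as e:
                failures.append(e)
    return ScoreTable(results=results, failures=failures)


def definitions_to_json(indent: int = 2) -> str:
    """Machine-readable export of all nine score definitions (components,
    bin edges, boundary closure, points, positivity threshold)."""
    doc = {}
    for sid, d in SCORE_DEFINITIONS.items():
        comps = []
        for rule in d.rules:
            if rule.component == Component.GENETICS:
                bins = [{"value": False, "points": 0}, {"value": True, "points": 1}]
            else:
                bins = [
                    {
                        "lower": b.lower,
                        "upper": None if math.isinf(b.upper) else b.upper,
                        "lower_closed": b.lower_closed,
                        "upper_closed": b.upper_closed,
                        "points": b.points,
                    }
                    for b in rule.bins
                ]
            comps.append({"component": rule.component.value, "bins": bins,
                          "max_points": rule.max_points})
        doc[sid.value] = {
            "components": comps,
            "positivity_threshold": d.positivity_threshold,
            "max_total": d.max_total,
        }
    return json.dumps(doc, indent=indent)
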