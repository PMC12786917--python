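"""Per-patient derived scores.

Three composites summarize the questionnaires:

* **PainDETECT final score** — sum of the seven 0-5 sensory items
  (0-35), plus a course-pattern adjustment (persistent with slight
  fluctuations 0, persistent with attacks -1, attacks without pain
  between +1, attacks with pain between +1), plus +2 for radiating
  pain; clamped to [0, 38] and banded as negative (<= 12), unclear
  (13-18) or positive (>= 19, indicating a neuropathic component).
* **Sum VAS** — sum of the pain-intensity scales.  The eight-item
  variant (default) sums dysmenorrhea, dyspareunia, dysuria, dyschezia,
  chronic pelvic pain, pain now, strongest and average pain in the last
  4 weeks; a five-item variant restricted to the classical symptoms is
  provided because the published group means of the composite are more
  consistent with it (see docs/methods.md).
* **Sum of significant parameters (SP sum)** — the count of 34 binary
  indicators (the "asterisked" group-discriminating items), enumerated
  in :data:`DEFAULT_SP_REGISTRY`.

Missing answers contribute 0/false to every score: the instrument
tolerates sparse answers because no single item is decisive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

from .model import (
    Adjective, CoursePattern, PainLocation, PatientRecord, SensoryItem,
)

__all__ = [
    "VasVariant", "PainDetectBand", "NotScorableError", "ScoreSet",
    "SpRule", "SpRegistry", "DEFAULT_SP_REGISTRY", "paindetect_final_score",
    "paindetect_band", "sum_vas", "sp_indicators", "sum_sp", "score_record",
]


class VasVariant(str, Enum):
    EIGHT_ITEM = "EIGHT_ITEM"
    FIVE_ITEM = "FIVE_ITEM"


class PainDetectBand(str, Enum):
    NEGATIVE = "NEGATIVE"
    UNCLEAR = "UNCLEAR"
    POSITIVE = "POSITIVE"


class NotScorableError(ValueError):
    """Raised when every PainDETECT input is missing.

    A fully missing screen is distinguished from a true 0 score; callers
    that tolerate it (SP indicators, the score-set builder) treat the
    screen as absent rather than negative.
    """


_PATTERN_ADJUSTMENT = {
    CoursePattern.PERSISTENT_SLIGHT_FLUCT: 0,
    CoursePattern.PERSISTENT_WITH_ATTACKS: -1,
    CoursePattern.ATTACKS_NO_PAIN_BETWEEN: 1,
    CoursePattern.ATTACKS_WITH_PAIN_BETWEEN: 1,
}


def paindetect_band(final: int) -> PainDetectBand:
    if final <= 12:
        return PainDetectBand.NEGATIVE
    if final <= 18:
        return PainDetectBand.UNCLEAR
    return PainDetectBand.POSITIVE


def paindetect_final_score(record: PatientRecord) -> tuple[int, PainDetectBand]:
    """Final score and band; missing components contribute 0.

    Raises :class:`NotScorableError` when all inputs (sensory items,
    course pattern, radiating pain) are missing.
    """
    sensory = [record.sensory_items[s] for s in SensoryItem]
    inputs = sensory + [record.course_pattern, record.radiating_pain]
    if all(v is None for v in inputs):
        raise NotScorableError(
            f"patient {record.patient_id}: all PainDETECT inputs missing")
    total = sum(v for v in sensory if v is not None)
    if record.course_pattern is not None:
        total += _PATTERN_ADJUSTMENT[record.course_pattern]
    if record.radiating_pain:
        total += 2
    final = max(0, min(38, total))
    return final, paindetect_band(final)


_VAS_ITEMS_EIGHT = (
    "dysmenorrhea_nrs", "dyspareunia_nrs", "dysuria_nrs", "dyschezia_nrs",
    "cpp_nrs", "pain_now_nrs", "strongest_4wks_nrs", "average_4wks_nrs",
)
_VAS_ITEMS_FIVE = _VAS_ITEMS_EIGHT[:5]


def sum_vas(record: PatientRecord,
            variant: VasVariant = VasVariant.EIGHT_ITEM) -> float:
    """Sum of the pain-intensity NRS values; missing counts as 0."""
    items = (_VAS_ITEMS_EIGHT if variant is VasVariant.EIGHT_ITEM
             else _VAS_ITEMS_FIVE)
    return float(sum(v for f in items if (v := getattr(record, f)) is not None))


# --- significant-parameter registry -------------------------------------

@dataclass(frozen=True)
class SpRule:
    """One dichotomization rule: record (and derived scores) -> bool."""

    sp_id: int
    name: str
    kind: str           # item_true | nrs_gt | conjunction | pattern_eq
                        # | paindetect_ge | sum_vas_gt
    params: tuple = ()

    def evaluate(self, record: PatientRecord, sum_vas_value: float) -> bool:
        from .model import get_item_value
        if self.kind == "item_true":
            return get_item_value(record, self.params[0]) is True
        if self.kind == "nrs_gt":
            item, thr = self.params
            v = get_item_value(record, item)
            return v is not None and v > thr
        if self.kind == "conjunction":
            return all(get_item_value(record, it) is True for it in self.params)
        if self.kind == "pattern_eq":
            return record.course_pattern is CoursePattern(self.params[0])
        if self.kind == "paindetect_ge":
            try:
                final, _ = paindetect_final_score(record)
            except NotScorableError:
                return False
            return final >= self.params[0]
        if self.kind == "sum_vas_gt":
            return sum_vas_value > self.params[0]
        raise ValueError(f"unknown rule kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"sp_id": self.sp_id, "name": self.name,
                "kind": self.kind, "params": list(self.params)}


@dataclass
class SpRegistry:
    """Ordered set of the 34 significant-parameter rules.

    Exactly one rule (the composite-score cut-off, SP 34) depends on the
    sum-VAS value rather than the raw record.
    """

    rules: list[SpRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.sp_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sp_id in registry")
        derived = [r for r in self.rules if r.kind == "sum_vas_gt"]
        if self.rules and len(derived) != 1:
            raise ValueError("registry must contain exactly one sum_vas rule")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @property
    def sp_ids(self) -> list[int]:
        return [r.sp_id for r in self.rules]

    def to_json(self) -> str:
        return json.dumps([r.to_dict() for r in self.rules], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SpRegistry":
        return cls([SpRule(d["sp_id"], d["name"], d["kind"],
                           tuple(d.get("params", ()))) for d in json.loads(text)])


def _default_rules() -> list[SpRule]:
    R = SpRule
    rules = [
        R(1, "analgesic use", "item_true", ("analgesic_use",)),
        R(2, "dysmenorrhea present", "item_true", ("dysmenorrhea",)),
        R(3, "dysmenorrhea NRS > 3", "nrs_gt", ("dysmenorrhea_nrs", 3)),
        R(4, "pain before and during menses", "conjunction",
          ("pain_before_menses", "pain_during_menses")),
        R(5, "chronic pelvic pain", "item_true", ("cpp",)),
        R(6, "dysuria", "item_true", ("dysuria",)),
        R(7, "dyschezia", "item_true", ("dyschezia",)),
        R(8, "dyspareunia", "item_true", ("dyspareunia",)),
        R(9, "obstipation", "item_true", ("obstipation",)),
        R(10, "diarrhea", "item_true", ("diarrhea",)),
    ]
    sp_adjectives = [
        Adjective.CRAMPING, Adjective.TEARING, Adjective.PULLING,
        Adjective.STINGING, Adjective.PULSATILE, Adjective.TOUCH_SENSITIVE,
        Adjective.PRESSING, Adjective.COLD_WARMTH, Adjective.FLASHING,
    ]
    for i, adj in enumerate(sp_adjectives):
        rules.append(R(11 + i, f"pain {adj.value.lower()}", "item_true",
                       (f"adj_{adj.value.lower()}",)))
    rules += [
        R(20, "pain now > 0", "nrs_gt", ("pain_now_nrs", 0)),
        R(21, "strongest pain 4 wks > 0", "nrs_gt", ("strongest_4wks_nrs", 0)),
        R(22, "average pain 4 wks > 0", "nrs_gt", ("average_4wks_nrs", 0)),
    ]
    for i, loc in enumerate(PainLocation):
        rules.append(R(23 + i, f"pain at {loc.value.lower()}", "item_true",
                       (f"loc_{loc.value.lower()}",)))
    rules += [
        R(30, "persistent pain with attacks", "pattern_eq",
          (CoursePattern.PERSISTENT_WITH_ATTACKS.value,)),
        R(31, "attacks without pain between", "pattern_eq",
          (CoursePattern.ATTACKS_NO_PAIN_BETWEEN.value,)),
        R(32, "attacks with pain between", "pattern_eq",
          (CoursePattern.ATTACKS_WITH_PAIN_BETWEEN.value,)),
        R(33, "PainDETECT final >= 4", "paindetect_ge", (4,)),
        R(34, "sum VAS > 8.5", "sum_vas_gt", (8.5,)),
    ]
    return rules


DEFAULT_SP_REGISTRY = SpRegistry(_default_rules())


def sp_indicators(
    record: PatientRecord,
    registry: Optional[SpRegistry] = None,
    sum_vas_value: Optional[float] = None,
    variant: VasVariant = VasVariant.EIGHT_ITEM,
) -> dict[int, bool]:
    """Evaluate every registry rule; missing answers evaluate to false."""
    registry = registry or DEFAULT_SP_REGISTRY
    if sum_vas_value is None:
        sum_vas_value = sum_vas(record, variant)
    return {r.sp_id: r.evaluate(record, sum_vas_value) for r in registry}


def sum_sp(indicators: dict[int, bool],
           registry: Optional[SpRegistry] = None) -> int:
    """Count of true indicators; the key set must match the registry."""
    registry = registry or DEFAULT_SP_REGISTRY
    if set(indicators) != set(registry.sp_ids):
        raise ValueError("indicator keys do not match the registry sp_ids")
    return sum(bool(v) for v in indicators.values())


@dataclass
class ScoreSet:
    """All derived quantities for one patient.

    ``paindetect_final``/``paindetect_band`` are ``None`` when the
    PainDETECT screen was entirely unanswered (never silently 0).
    """

    sum_vas: float
    sum_vas_variant: VasVariant
    sum_sp: int
    sp_indicators: dict[int, bool]
    paindetect_final: Optional[int] = None
    paindetect_band: Optional[PainDetectBand] = None

    def __post_init__(self) -> None:
        if self.sum_sp != sum(bool(v) for v in self.sp_indicators.values()):
            raise ValueError("sum_sp inconsistent with sp_indicators")
        if self.paindetect_final is not None:
            if self.paindetect_band is not paindetect_band(self.paindetect_final):
                raise ValueError("paindetect band inconsistent with final score")


def score_record(
    record: PatientRecord,
    variant: VasVariant = VasVariant.EIGHT_ITEM,
    registry: Optional[SpRegistry] = None,
) -> ScoreSet:
    """Compute the full score set for one record."""
    vas = sum_vas(record, variant)
    ind = sp_indicators(record, registry, vas)
    try:
        final, band = paindetect_final_score(record)
    except NotScorableError:
        final, band = None, None
    return ScoreSet(sum_vas=vas, sum_vas_variant=variant,
                    sum_sp=sum(bool(v) for v in ind.values()),
                    sp_indicators=ind, paindetect_final=final,
                    paindetect_band=band)
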