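"""Patient-record data model, codebook and delimited-file I/O.

Two questionnaires are modeled: a symptom questionnaire (classical pain
items with 0-10 numeric rating scales, eleven pain adjectives, seven pain
locations) and the PainDETECT neuropathic-pain screen (seven 0-5 sensory
items, a pain-course pattern, radiating pain, three 0-10 intensity
scales).  Every answer is optional; a missing answer is represented
explicitly (``None`` in memory, empty cell on disk) and is never imputed
at this layer — downstream scoring defines how missingness contributes.

Cohort files are UTF-8 CSV (TSV via ``delimiter="\\t"``) with one row per
patient and the codebook item ids as header.  Booleans are serialized as
0/1, enums as uppercase tokens, missing as the empty string.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, fields as _dc_fields
from enum import Enum
from pathlib import Path
from typing import Optional, TextIO, Union

__all__ = [
    "Label", "Contraceptive", "Adjective", "PainLocation", "CoursePattern",
    "SensoryItem", "PatientRecord", "ItemDefinition", "Codebook",
    "default_codebook", "CohortError", "read_cohort", "write_cohort",
    "validate_record", "get_item_value", "set_item_value", "ITEM_IDS",
]


class Label(str, Enum):
    EMS = "EMS"
    NO_EMS = "NO_EMS"


class Contraceptive(str, Enum):
    DNG = "DNG"          # dienogest
    LNG = "LNG"          # levonorgestrel
    DSG = "DSG"          # desogestrel
    E_OTHER = "E_OTHER"  # estrogen + other progestin
    OTHER = "OTHER"


class Adjective(str, Enum):
    CRAMPING = "CRAMPING"
    TEARING = "TEARING"
    PULLING = "PULLING"
    STINGING = "STINGING"
    PULSATILE = "PULSATILE"
    TOUCH_SENSITIVE = "TOUCH_SENSITIVE"
    BURNING = "BURNING"
    PRESSING = "PRESSING"
    DIFFUSE = "DIFFUSE"
    COLD_WARMTH = "COLD_WARMTH"
    FLASHING = "FLASHING"


class PainLocation(str, Enum):
    LOWER_ABDOMEN = "LOWER_ABDOMEN"
    LUMBAR_SPINE = "LUMBAR_SPINE"
    THIGHS_LEGS = "THIGHS_LEGS"
    HIPS_GROINS = "HIPS_GROINS"
    UPPER_ABDOMEN = "UPPER_ABDOMEN"
    VAGINA_MONS = "VAGINA_MONS"
    GLUTEAL = "GLUTEAL"


class CoursePattern(str, Enum):
    PERSISTENT_SLIGHT_FLUCT = "PERSISTENT_SLIGHT_FLUCT"
    PERSISTENT_WITH_ATTACKS = "PERSISTENT_WITH_ATTACKS"
    ATTACKS_NO_PAIN_BETWEEN = "ATTACKS_NO_PAIN_BETWEEN"
    ATTACKS_WITH_PAIN_BETWEEN = "ATTACKS_WITH_PAIN_BETWEEN"


class SensoryItem(str, Enum):
    """The seven PainDETECT sensory descriptors, each rated 0-5."""

    BURNING_S = "BURNING_S"
    TINGLING = "TINGLING"
    ALLODYNIA = "ALLODYNIA"
    ATTACKS_S = "ATTACKS_S"
    THERMAL = "THERMAL"
    NUMBNESS = "NUMBNESS"
    PRESSURE_S = "PRESSURE_S"


def _none_map(enum_cls):
    return lambda: {member: None for member in enum_cls}


@dataclass
class PatientRecord:
    """One respondent's answers to both questionnaires.

    All fields except ``patient_id`` are optional; ``None`` means the
    question was not answered.  ``label`` is the examination/histology
    confirmed disease status when known.
    """

    patient_id: str
    label: Optional[Label] = None

    age_yrs: Optional[float] = None
    bmi: Optional[float] = None
    age_menarche_yrs: Optional[float] = None
    smoker: Optional[bool] = None
    allergies: Optional[bool] = None
    analgesic_use: Optional[bool] = None
    contraceptive: Optional[Contraceptive] = None

    dysmenorrhea: Optional[bool] = None
    dysmenorrhea_nrs: Optional[int] = None
    pain_before_menses: Optional[bool] = None
    pain_during_menses: Optional[bool] = None
    pain_after_menses: Optional[bool] = None

    cpp: Optional[bool] = None
    cpp_nrs: Optional[int] = None
    dysuria: Optional[bool] = None
    dysuria_nrs: Optional[int] = None
    dyschezia: Optional[bool] = None
    dyschezia_nrs: Optional[int] = None
    dyspareunia: Optional[bool] = None
    dyspareunia_nrs: Optional[int] = None
    obstipation: Optional[bool] = None
    diarrhea: Optional[bool] = None

    adjectives: dict = field(default_factory=_none_map(Adjective))

    pain_now_nrs: Optional[int] = None
    strongest_4wks_nrs: Optional[int] = None
    average_4wks_nrs: Optional[int] = None

    locations: dict = field(default_factory=_none_map(PainLocation))
    course_pattern: Optional[CoursePattern] = None
    radiating_pain: Optional[bool] = None
    sensory_items: dict = field(default_factory=_none_map(SensoryItem))


class ValueKind(str, Enum):
    ID = "ID"
    LABEL = "LABEL"
    REAL = "REAL"
    BOOLEAN = "BOOLEAN"
    NRS_0_10 = "NRS_0_10"
    SENSORY_0_5 = "SENSORY_0_5"
    CATEGORICAL = "CATEGORICAL"


@dataclass(frozen=True)
class ItemDefinition:
    item_id: str
    label: str
    value_kind: ValueKind
    source_table: str = ""
    is_significant_parameter: bool = False
    dichotomizer_id: Optional[str] = None
    enum_cls: Optional[type] = None


def _items() -> list[ItemDefinition]:
    I, K = ItemDefinition, ValueKind
    out = [
        I("patient_id", "patient identifier", K.ID),
        I("label", "disease group", K.LABEL, enum_cls=Label),
        I("age_yrs", "age in years", K.REAL, "demographics"),
        I("bmi", "body mass index", K.REAL, "demographics"),
        I("age_menarche_yrs", "age at menarche", K.REAL, "demographics"),
        I("smoker", "current smoker", K.BOOLEAN, "demographics"),
        I("allergies", "any allergies", K.BOOLEAN, "demographics"),
        I("analgesic_use", "analgesics during menstruation", K.BOOLEAN,
          "demographics", True, "sp1"),
        I("contraceptive", "contraceptive preparation", K.CATEGORICAL,
          "demographics", enum_cls=Contraceptive),
        I("dysmenorrhea", "menstrual pain present", K.BOOLEAN,
          "classical", True, "sp2"),
        I("dysmenorrhea_nrs", "menstrual pain NRS", K.NRS_0_10,
          "classical", True, "sp3"),
        I("pain_before_menses", "pain before menses", K.BOOLEAN,
          "classical", True, "sp4"),
        I("pain_during_menses", "pain during menses", K.BOOLEAN,
          "classical", True, "sp4"),
        I("pain_after_menses", "pain after menses", K.BOOLEAN, "classical"),
        I("cpp", "chronic pelvic pain present", K.BOOLEAN,
          "classical", True, "sp5"),
        I("cpp_nrs", "chronic pelvic pain NRS", K.NRS_0_10, "classical"),
        I("dysuria", "painful urination", K.BOOLEAN, "classical", True, "sp6"),
        I("dysuria_nrs", "painful urination NRS", K.NRS_0_10, "classical"),
        I("dyschezia", "painful defecation", K.BOOLEAN, "classical", True, "sp7"),
        I("dyschezia_nrs", "painful defecation NRS", K.NRS_0_10, "classical"),
        I("dyspareunia", "painful intercourse", K.BOOLEAN, "classical", True, "sp8"),
        I("dyspareunia_nrs", "painful intercourse NRS", K.NRS_0_10, "classical"),
        I("obstipation", "constipation", K.BOOLEAN, "classical", True, "sp9"),
        I("diarrhea", "diarrhea", K.BOOLEAN, "classical", True, "sp10"),
    ]
    sp_adjectives = {
        Adjective.CRAMPING: "sp11", Adjective.TEARING: "sp12",
        Adjective.PULLING: "sp13", Adjective.STINGING: "sp14",
        Adjective.PULSATILE: "sp15", Adjective.TOUCH_SENSITIVE: "sp16",
        Adjective.PRESSING: "sp17", Adjective.COLD_WARMTH: "sp18",
        Adjective.FLASHING: "sp19",
    }
    for adj in Adjective:
        sp = sp_adjectives.get(adj)
        out.append(I(f"adj_{adj.value.lower()}", f"pain described as {adj.value.lower()}",
                     K.BOOLEAN, "adjectives", sp is not None, sp))
    out += [
        I("pain_now_nrs", "pain right now NRS", K.NRS_0_10, "paindetect", True, "sp20"),
        I("strongest_4wks_nrs", "strongest pain in 4 weeks NRS", K.NRS_0_10,
          "paindetect", True, "sp21"),
        I("average_4wks_nrs", "average pain in 4 weeks NRS", K.NRS_0_10,
          "paindetect", True, "sp22"),
    ]
    for i, loc in enumerate(PainLocation):
        out.append(I(f"loc_{loc.value.lower()}", f"pain located at {loc.value.lower()}",
                     K.BOOLEAN, "paindetect", True, f"sp{23 + i}"))
    out += [
        I("course_pattern", "pain course pattern", K.CATEGORICAL, "paindetect",
          True, "sp30-32", enum_cls=CoursePattern),
        I("radiating_pain", "pain radiating to other regions", K.BOOLEAN, "paindetect"),
    ]
    for s in SensoryItem:
        out.append(I(f"sens_{s.value.lower()}", f"sensory item {s.value.lower()}",
                     K.SENSORY_0_5, "paindetect", True, "sp33"))
    return out


@dataclass
class Codebook:
    """Ordered item inventory defining the on-disk cohort format."""

    items: list[ItemDefinition]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("codebook item_ids must be unique")
        self._by_id = {it.item_id: it for it in self.items}

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    def __getitem__(self, item_id: str) -> ItemDefinition:
        return self._by_id[item_id]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def to_json(self) -> str:
        rows = [
            {
                "item_id": it.item_id,
                "label": it.label,
                "value_kind": it.value_kind.value,
                "source_table": it.source_table,
                "is_significant_parameter": it.is_significant_parameter,
                "dichotomizer_id": it.dichotomizer_id,
            }
            for it in self.items
        ]
        return json.dumps(rows, indent=1)


def default_codebook() -> Codebook:
    return Codebook(_items())


_DEFAULT_CODEBOOK = default_codebook()
ITEM_IDS = tuple(_DEFAULT_CODEBOOK.item_ids)

_ADJ_BY_ID = {f"adj_{a.value.lower()}": a for a in Adjective}
_LOC_BY_ID = {f"loc_{l.value.lower()}": l for l in PainLocation}
_SENS_BY_ID = {f"sens_{s.value.lower()}": s for s in SensoryItem}


def get_item_value(record: PatientRecord, item_id: str):
    """Raw answer for a codebook item id (``None`` when missing)."""
    if item_id in _ADJ_BY_ID:
        return record.adjectives[_ADJ_BY_ID[item_id]]
    if item_id in _LOC_BY_ID:
        return record.locations[_LOC_BY_ID[item_id]]
    if item_id in _SENS_BY_ID:
        return record.sensory_items[_SENS_BY_ID[item_id]]
    if item_id in ITEM_IDS:
        return getattr(record, item_id)
    raise KeyError(f"unknown item_id: {item_id!r}")


def set_item_value(record: PatientRecord, item_id: str, value) -> None:
    if item_id in _ADJ_BY_ID:
        record.adjectives[_ADJ_BY_ID[item_id]] = value
    elif item_id in _LOC_BY_ID:
        record.locations[_LOC_BY_ID[item_id]] = value
    elif item_id in _SENS_BY_ID:
        record.sensory_items[_SENS_BY_ID[item_id]] = value
    elif item_id in ITEM_IDS:
        setattr(record, item_id, value)
    else:
        raise KeyError(f"unknown item_id: {item_id!r}")


class CohortError(ValueError):
    """Malformed cohort file: names row, column and offending token."""


def _parse_cell(token: str, item: ItemDefinition, row: int):
    kind = item.value_kind

    def bad(why: str):
        return CohortError(
            f"row {row}, column {item.item_id!r}: {why} (got {token!r})")

    if kind is ValueKind.ID:
        if not token:
            raise bad("patient_id must be non-empty")
        return token
    if kind is ValueKind.BOOLEAN:
        if token == "1":
            return True
        if token == "0":
            return False
        raise bad("expected 0 or 1")
    if kind in (ValueKind.NRS_0_10, ValueKind.SENSORY_0_5):
        hi = 10 if kind is ValueKind.NRS_0_10 else 5
        try:
            v = int(token)
        except ValueError:
            raise bad("expected an integer") from None
        if not 0 <= v <= hi:
            raise bad(f"expected an integer in [0,{hi}]")
        return v
    if kind is ValueKind.REAL:
        try:
            return float(token)
        except ValueError:
            raise bad("expected a number") from None
    # LABEL / CATEGORICAL
    try:
        return item.enum_cls(token)
    except ValueError:
        allowed = ", ".join(m.value for m in item.enum_cls)
        raise bad(f"expected one of {{{allowed}}}") from None


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def read_cohort(
    source: Union[str, Path, TextIO],
    codebook: Optional[Codebook] = None,
    delimiter: str = ",",
) -> list[PatientRecord]:
    """Parse a delimited cohort file into validated patient records.

    Columns may appear in any order but must all be codebook item ids;
    an empty cell is a missing answer.  Raises :class:`CohortError`
    naming row, column and token on the first malformed value, unknown
    column, duplicate patient id or invariant violation.
    """
    codebook = codebook or _DEFAULT_CODEBOOK
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_cohort(fh, codebook, delimiter)

    reader = csv.reader(source, delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise CohortError("empty file: header row required") from None
    unknown = [c for c in header if c not in codebook]
    if unknown:
        raise CohortError(f"unknown column(s): {', '.join(map(repr, unknown))}")
    if "patient_id" not in header:
        raise CohortError("missing required column 'patient_id'")
    if len(set(header)) != len(header):
        raise CohortError("duplicate column in header")

    records: list[PatientRecord] = []
    seen_ids: set[str] = set()
    for row_no, row in enumerate(reader, start=2):
        if len(row) != len(header):
            raise CohortError(
                f"row {row_no}: expected {len(header)} cells, got {len(row)}")
        values = {}
        for col, token in zip(header, row):
            if token == "":
                continue
            values[col] = _parse_cell(token, codebook[col], row_no)
        if "patient_id" not in values:
            raise CohortError(f"row {row_no}: patient_id is empty")
        pid = values.pop("patient_id")
        if pid in seen_ids:
            raise CohortError(f"row {row_no}: duplicate patient_id {pid!r}")
        seen_ids.add(pid)
        record = PatientRecord(patient_id=pid)
        for col, v in values.items():
            set_item_value(record, col, v)
        violations = validate_record(record)
        if violations:
            raise CohortError(f"row {row_no}: " + "; ".join(violations))
        records.append(record)
    return records


def write_cohort(
    records: list[PatientRecord],
    dest: Union[str, Path, TextIO, None] = None,
    codebook: Optional[Codebook] = None,
    delimiter: str = ",",
) -> Optional[str]:
    """Serialize records to CSV/TSV; returns the text when ``dest`` is None.

    Output is deterministic for a fixed record order, and re-reading it
    reproduces the records field-for-field (missing stays missing).
    """
    codebook = codebook or _DEFAULT_CODEBOOK
    if dest is None:
        buf = io.StringIO()
        write_cohort(records, buf, codebook, delimiter)
        return buf.getvalue()
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_cohort(records, fh, codebook, delimiter)
        return None

    writer = csv.writer(dest, delimiter=delimiter, lineterminator="\n")
    writer.writerow(codebook.item_ids)
    for rec in records:
        writer.writerow(
            [_format_cell(get_item_value(rec, c)) for c in codebook.item_ids])
    return None


_NRS_PAIRS = [
    ("dysmenorrhea", "dysmenorrhea_nrs"),
    ("cpp", "cpp_nrs"),
    ("dysuria", "dysuria_nrs"),
    ("dyschezia", "dyschezia_nrs"),
    ("dyspareunia", "dyspareunia_nrs"),
]


def validate_record(record: PatientRecord) -> list[str]:
    """Return all invariant violations (empty list means valid).

    Total: never raises on a structurally parseable record.
    """
    out: list[str] = []
    if not record.patient_id:
        out.append("patient_id: must be non-empty")
    if record.label is not None and not isinstance(record.label, Label):
        out.append("label: must be EMS or NO_EMS")
    for fname in ("age_yrs", "bmi", "age_menarche_yrs"):
        v = getattr(record, fname)
        if v is not None and (v < 0 or (fname == "bmi" and v <= 0)):
            out.append(f"{fname}: must be positive")
    for item_id in ITEM_IDS:
        if item_id.endswith("_nrs"):
            v = get_item_value(record, item_id)
            if v is not None and not (isinstance(v, int) and 0 <= v <= 10):
                out.append(f"{item_id}: NRS must be an integer in [0,10]")
    for item_id in _SENS_BY_ID:
        v = get_item_value(record, item_id)
        if v is not None and not (isinstance(v, int) and 0 <= v <= 5):
            out.append(f"{item_id}: sensory item must be an integer in [0,5]")
    for sym, nrs in _NRS_PAIRS:
        s, v = getattr(record, sym), getattr(record, nrs)
        if s is False and v is not None and v != 0:
            out.append(f"{nrs}: symptom {sym} absent but NRS is {v} (expected 0)")
    return out
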