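"""Serializable binary decision trees over records and derived scores.

The classifier the package ships is a hand-crafted rule, not a learned
one: the engine only represents and evaluates trees, whose topology is
data (a JSON/YAML document), never code.  An internal node holds a
predicate over the patient's raw answers (``ITEM``) or derived scores
(``SP_COUNT``, ``SUM_VAS``); a leaf is the predicted label.

The shipped default (``default_tree``) reconstructs the published
hand-crafted tree from the 11 parameters it is known to use: the SP
count with a cut-off at 9 (> 8.5) as the root; on the positive branch
two necessary conditions, sum VAS > 12 and strongest pain in 4 weeks
> 3; then confirmation by any of dysuria, dyspareunia, obstipation,
pain in the thighs/legs, pain in the vagina, cramping, pulling or
flashing pain.  Only the parameter inventory and the resulting
confusion matrix of the original rule are public; this branch
arrangement is the reconstruction whose operating point on
marginal-calibrated synthetic cohorts is closest to that confusion
matrix (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .model import ITEM_IDS, Label, PatientRecord, get_item_value
from .scoring import ScoreSet, SpRegistry, VasVariant, score_record

__all__ = [
    "PredicateSource", "Comparator", "Predicate", "DecisionTree",
    "TreeError", "classify", "load_tree", "save_tree", "default_tree",
    "evaluate_tree",
]


class PredicateSource(str, Enum):
    SP_COUNT = "SP_COUNT"
    SUM_VAS = "SUM_VAS"
    ITEM = "ITEM"


class Comparator(str, Enum):
    GT = "GT"
    GE = "GE"
    EQ = "EQ"
    IS_TRUE = "IS_TRUE"


class TreeError(ValueError):
    """Malformed tree document (unknown item, missing child, bad node)."""


@dataclass(frozen=True)
class Predicate:
    source: PredicateSource
    comparator: Comparator = Comparator.IS_TRUE
    item_id: Optional[str] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source is PredicateSource.ITEM:
            if self.item_id is None:
                raise TreeError("ITEM predicate requires item_id")
            if self.item_id not in ITEM_IDS:
                raise TreeError(f"unknown item_id in predicate: {self.item_id!r}")
        elif self.threshold is None and self.comparator in (Comparator.GT,
                                                            Comparator.GE):
            raise TreeError(f"{self.source.value} predicate requires threshold")

    def evaluate(self, record: PatientRecord, scores: ScoreSet) -> bool:
        """Missing referenced answers evaluate to false."""
        if self.source is PredicateSource.SP_COUNT:
            value = scores.sum_sp
        elif self.source is PredicateSource.SUM_VAS:
            value = scores.sum_vas
        else:
            value = get_item_value(record, self.item_id)
        if value is None:
            return False
        if self.comparator is Comparator.IS_TRUE:
            return value is True
        if self.comparator is Comparator.GT:
            return value > self.threshold
        if self.comparator is Comparator.GE:
            return value >= self.threshold
        if isinstance(value, Enum):
            return value.value == self.threshold
        return value == self.threshold

    def to_dict(self) -> dict:
        d: dict = {"source": self.source.value, "comparator": self.comparator.value}
        if self.item_id is not None:
            d["item_id"] = self.item_id
        if self.threshold is not None:
            d["threshold"] = self.threshold
        return d


@dataclass(frozen=True)
class _Node:
    predicate: Predicate
    yes: Union["_Node", Label]
    no: Union["_Node", Label]


@dataclass(frozen=True)
class DecisionTree:
    """Rooted binary tree; every internal node has exactly two children."""

    root: Union[_Node, Label]
    name: str = "tree"

    def depth(self) -> int:
        def d(node):
            if isinstance(node, Label):
                return 0
            return 1 + max(d(node.yes), d(node.no))
        return d(self.root)

    def leaf_labels(self) -> set[Label]:
        out: set[Label] = set()

        def walk(node):
            if isinstance(node, Label):
                out.add(node)
            else:
                walk(node.yes)
                walk(node.no)
        walk(self.root)
        return out


def classify(record: PatientRecord, scores: ScoreSet,
             tree: DecisionTree) -> Label:
    """Deterministic root-to-leaf evaluation; returns the leaf label."""
    node = tree.root
    while not isinstance(node, Label):
        node = node.yes if node.predicate.evaluate(record, scores) else node.no
    return node


_MAX_DEPTH = 64


def _node_from_obj(obj, depth: int = 0):
    if depth > _MAX_DEPTH:
        raise TreeError("tree exceeds maximum depth (cyclic document?)")
    if isinstance(obj, str):
        try:
            return Label(obj)
        except ValueError:
            raise TreeError(f"leaf must be 'EMS' or 'NO_EMS', got {obj!r}") from None
    if not isinstance(obj, dict):
        raise TreeError(f"node must be a mapping or leaf string, got {type(obj).__name__}")
    missing = {"predicate", "yes", "no"} - set(obj)
    if missing:
        raise TreeError(f"internal node missing key(s): {', '.join(sorted(missing))}")
    p = obj["predicate"]
    try:
        predicate = Predicate(
            source=PredicateSource(p["source"]),
            comparator=Comparator(p.get("comparator", "IS_TRUE")),
            item_id=p.get("item_id"),
            threshold=p.get("threshold"),
        )
    except (KeyError, ValueError) as exc:
        raise TreeError(f"bad predicate {p!r}: {exc}") from exc
    return _Node(predicate,
                 _node_from_obj(obj["yes"], depth + 1),
                 _node_from_obj(obj["no"], depth + 1))


def _node_to_obj(node):
    if isinstance(node, Label):
        return node.value
    return {"predicate": node.predicate.to_dict(),
            "yes": _node_to_obj(node.yes),
            "no": _node_to_obj(node.no)}


def load_tree(document: Union[str, Path, dict], name: str = "tree") -> DecisionTree:
    """Load a tree from a JSON/YAML document, path or parsed mapping.

    Predicate item ids are validated against the codebook at load time,
    so a classify call can never hit an unknown item.
    """
    if isinstance(document, Path) or (
            isinstance(document, str) and "\n" not in document
            and document.endswith((".json", ".yaml", ".yml"))):
        path = Path(document)
        obj = yaml.safe_load(path.read_text(encoding="utf-8"))
        name = path.stem
    elif isinstance(document, str):
        obj = yaml.safe_load(document)
    else:
        obj = document
    return DecisionTree(root=_node_from_obj(obj), name=name)


def save_tree(tree: DecisionTree, dest: Union[str, Path, None] = None,
              fmt: str = "json") -> Optional[str]:
    """Serialize a tree; round-trips through :func:`load_tree`."""
    obj = _node_to_obj(tree.root)
    text = (json.dumps(obj, indent=1) if fmt == "json"
            else yaml.safe_dump(obj, sort_keys=False))
    if dest is None:
        return text
    Path(dest).write_text(text, encoding="utf-8")
    return None


def default_tree() -> DecisionTree:
    """The shipped reconstruction of the published hand-crafted tree."""
    text = (resources.files("endoquest") / "data" / "default_tree.json"
            ).read_text(encoding="utf-8")
    return DecisionTree(root=_node_from_obj(json.loads(text)),
                        name="default_tree")


def evaluate_tree(
    cohort: list[PatientRecord],
    tree: DecisionTree,
    variant: VasVariant = VasVariant.EIGHT_ITEM,
    registry: Optional[SpRegistry] = None,
):
    """Confusion counts of a tree on a fully labeled cohort.

    Returns a :class:`~endoquest.diagnostics.ContingencyTable` with rows
    = true label (control/case) and columns = predicted (negative/
    positive).
    """
    from .diagnostics import ContingencyTable

    if not cohort:
        raise ValueError("empty cohort")
    tn = fp = fn = tp = 0
    for rec in cohort:
        if rec.label is None:
            raise ValueError(f"patient {rec.patient_id}: missing label")
        pred = classify(rec, score_record(rec, variant, registry), tree)
        if rec.label is Label.EMS:
            if pred is Label.EMS:
                tp += 1
            else:
                fn += 1
        else:
            if pred is Label.EMS:
                fp += 1
            else:
                tn += 1
    return ContingencyTable(tn=tn, fp=fp, fn=fn, tp=tp)
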