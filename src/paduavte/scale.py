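"""The Padua scale: item definitions, weights, total score, risk levels.

The scale is an 11-item linear score; every present risk factor
contributes its integer point weight and the total is stratified into
risk levels at an integer cutoff (default 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

__all__ = [
    "ITEM_IDS",
    "BRANCH_A_ITEMS",
    "BRANCH_B_RULE_ITEMS",
    "BRANCH_B_NUMERIC_ITEMS",
    "PaduaItem",
    "ItemFlags",
    "RiskAssessment",
    "default_scale",
    "total_score",
    "stratify",
    "scale_to_json",
    "scale_from_json",
]

#: Canonical ordering of the 11 item identifiers.
ITEM_IDS: tuple = (
    "prior_vte",
    "active_cancer",
    "heart_resp_failure",
    "mi_stroke",
    "infection_rheum",
    "elderly",
    "obesity",
    "hormonal",
    "thrombophilic",
    "reduced_mobility",
    "recent_surgery_trauma",
)

#: Items decided by the disease-category classifier (Branch A), in
#: category-index order 0..4 (index 5 is the "Others" category).
BRANCH_A_ITEMS: tuple = (
    "prior_vte",
    "active_cancer",
    "heart_resp_failure",
    "mi_stroke",
    "infection_rheum",
)

#: Items decided by lexicon/rule extraction (Branch B).
BRANCH_B_RULE_ITEMS: tuple = ("hormonal", "reduced_mobility", "recent_surgery_trauma")

#: Items decided by numeric rules over structured fields.
BRANCH_B_NUMERIC_ITEMS: tuple = ("elderly", "obesity", "thrombophilic")


@dataclass(frozen=True)
class PaduaItem:
    """One scale row: identifier, display label, point weight, source branch."""

    id: str
    label: str
    points: int
    source: str

    def __post_init__(self) -> None:
        if self.id not in ITEM_IDS:
            raise ValueError(f"unknown Padua item id: {self.id!r}")
        if self.points not in (1, 2, 3):
            raise ValueError(f"item {self.id}: points must be 1, 2 or 3, got {self.points}")
        if self.source not in ("branch_a", "branch_b_rules", "branch_b_numeric"):
            raise ValueError(f"item {self.id}: bad source {self.source!r}")


@dataclass
class ItemFlags:
    """Boolean state of the 11 items plus human-readable evidence.

    ``provenance[item]`` must be non-empty whenever ``flags[item]`` is
    true; it carries the matched sentence/term or the numeric rule that
    fired.
    """

    flags: Dict[str, bool]
    provenance: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [i for i in ITEM_IDS if i not in self.flags]
        if missing:
            raise ValueError(f"ItemFlags missing item ids: {missing}")
        extra = [i for i in self.flags if i not in ITEM_IDS]
        if extra:
            raise ValueError(f"ItemFlags has unknown item ids: {extra}")
        for item in ITEM_IDS:
            self.provenance.setdefault(item, [])
            if self.flags[item] and not self.provenance[item]:
                raise ValueError(f"item {item} flagged true without provenance")

    @classmethod
    def none(cls) -> "ItemFlags":
        return cls(flags={i: False for i in ITEM_IDS})

    @classmethod
    def from_true_items(cls, items: Sequence[str], note: str = "set") -> "ItemFlags":
        flags = {i: i in set(items) for i in ITEM_IDS}
        prov = {i: [note] if flags[i] else [] for i in ITEM_IDS}
        return cls(flags=flags, provenance=prov)

    def true_items(self) -> List[str]:
        return [i for i in ITEM_IDS if self.flags[i]]


@dataclass
class RiskAssessment:
    """Final per-record outcome: flags, total score, risk level."""

    flags: ItemFlags
    total: int
    level: str  # score_zero | low | high

    def __post_init__(self) -> None:
        if self.level not in ("score_zero", "low", "high"):
            raise ValueError(f"bad risk level {self.level!r}")
        if (self.level == "score_zero") != (self.total == 0) and self.level == "score_zero":
            raise ValueError("level score_zero requires total 0")


_DEFAULT_ROWS = [
    ("prior_vte", "Prior VTE", 3, "branch_a"),
    ("active_cancer", "Active cancer", 3, "branch_a"),
    ("heart_resp_failure", "Heart/respiratory failure", 1, "branch_a"),
    ("mi_stroke", "Acute MI/ischemic stroke", 1, "branch_a"),
    ("infection_rheum", "Acute infection/rheumatologic disorder", 1, "branch_a"),
    ("elderly", "Elderly age (>=70 years)", 1, "branch_b_numeric"),
    ("obesity", "BMI >=30 kg/m^2", 1, "branch_b_numeric"),
    ("hormonal", "Ongoing hormonal treatment", 1, "branch_b_rules"),
    ("thrombophilic", "Thrombophilic", 3, "branch_b_numeric"),
    ("reduced_mobility", "Reduced mobility", 3, "branch_b_rules"),
    ("recent_surgery_trauma", "Recent (<=1 month of) trauma and/or surgery", 2, "branch_b_rules"),
]


def default_scale() -> List[PaduaItem]:
    """Return the 11 default Padua items with their standard weights."""
    return [PaduaItem(*row) for row in _DEFAULT_ROWS]


def _points_map(scale: Sequence[PaduaItem] | None = None) -> Dict[str, int]:
    items = list(scale) if scale is not None else default_scale()
    return {it.id: it.points for it in items}


def total_score(flags: ItemFlags | Mapping[str, bool], scale: Sequence[PaduaItem] | None = None) -> int:
    """Sum of point weights over the true flags.

    Raises ``ValueError`` if any of the 11 item ids is missing.
    """
    raw = flags.flags if isinstance(flags, ItemFlags) else dict(flags)
    missing = [i for i in ITEM_IDS if i not in raw]
    if missing:
        raise ValueError(f"flags missing item ids: {missing}")
    pts = _points_map(scale)
    return sum(pts[i] for i in ITEM_IDS if raw[i])


def stratify(total: int, cutoff: int = 3, three_level: bool = False) -> str:
    """Map a total score to a risk level.

    ``total >= cutoff`` is high risk, otherwise low; a score at the
    cutoff is treated as high (the conservative reading — the usual
    prose only pins down strictly-below and strictly-above). With
    ``three_level`` a zero total gets its own ``score_zero`` stratum.
    """
    if total < 0:
        raise ValueError(f"total score must be non-negative, got {total}")
    if three_level and total == 0:
        return "score_zero"
    return "high" if total >= cutoff else "low"


def scale_to_json(scale: Sequence[PaduaItem], path=None) -> str:
    """Serialize a scale definition; returns the JSON text."""
    doc = [{"id": it.id, "label": it.label, "points": it.points, "source": it.source} for it in scale]
    text = json.dumps(doc, indent=2, ensure_ascii=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def scale_from_json(source) -> List[PaduaItem]:
    """Load a scale definition from a JSON string or file path."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("["):
            doc = json.loads(text)
        else:
            with open(text, encoding="utf-8") as fh:
                doc = json.load(fh)
    items = [PaduaItem(d["id"], d["label"], int(d["points"]), d["source"]) for d in doc]
    ids = {it.id for it in items}
    if ids != set(ITEM_IDS):
        raise ValueError("scale JSON must define exactly the 11 Padua item ids")
    return items
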