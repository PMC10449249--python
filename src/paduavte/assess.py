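"""End-to-end orchestration: EMR in, 11 item flags, score, risk level.

Branch B supplies the six rule/numeric flags and the extracted
symptoms; Branch A (when a trained model is supplied) classifies each
(diagnosis, symptoms) unit into the five disease items.  Flags are
scored by the Padua scale and stratified; batch evaluation against
gold labels reuses :mod:`paduavte.metrics`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from paduavte import metrics as em
from paduavte.extractor import EMRecord, ExtractorConfig, extract_branch_b
from paduavte.model import PDCMModel, predict_patient
from paduavte.scale import BRANCH_A_ITEMS, ITEM_IDS, ItemFlags, RiskAssessment, stratify, total_score
from paduavte.tokenize import Lexicon

logger = logging.getLogger(__name__)

__all__ = ["AssessmentReport", "assess", "evaluate_batch"]


@dataclass
class AssessmentReport:
    assessments: List[RiskAssessment]
    record_ids: List[str]
    errors: List[str] = field(default_factory=list)
    metrics: Optional[dict] = None


def assess(
    record: EMRecord,
    model: Optional[PDCMModel],
    lexicons: Mapping[str, Lexicon],
    config: ExtractorConfig | None = None,
    cutoff: int = 3,
    three_level: bool = False,
) -> RiskAssessment:
    """Assess one record; deterministic for fixed inputs.

    With ``model=None`` only Branch B runs and the five disease items
    stay false.
    """
    cfg = config or ExtractorConfig()
    flags, prov, symptoms = extract_branch_b(record, lexicons, negation=lexicons.get("negation"), config=cfg)

    if model is not None and record.diagnoses:
        a_flags, scores = predict_patient(model, record.diagnoses, symptoms)
        for k, item in enumerate(BRANCH_A_ITEMS):
            if a_flags[k]:
                flags[item] = True
                prov[item].append(f"classifier: category {item} (score {scores[k]:.3f})")

    item_flags = ItemFlags(flags=flags, provenance=prov)
    total = total_score(item_flags)
    return RiskAssessment(flags=item_flags, total=total, level=stratify(total, cutoff=cutoff, three_level=three_level))


def evaluate_batch(
    records: Sequence[EMRecord],
    model: Optional[PDCMModel],
    lexicons: Mapping[str, Lexicon],
    config: ExtractorConfig | None = None,
    cutoff: int = 3,
) -> AssessmentReport:
    """Assess a batch and score it against the records' gold flags."""
    if not records:
        raise ValueError("no records")
    if any(r.gold_flags is None for r in records):
        raise ValueError("evaluate_batch requires gold_flags on every record")

    assessments: List[RiskAssessment] = []
    record_ids: List[str] = []
    errors: List[str] = []
    kept: List[EMRecord] = []
    for r in records:
        try:
            assessments.append(assess(r, model, lexicons, config=config, cutoff=cutoff))
            record_ids.append(r.record_id)
            kept.append(r)
        except ValueError as exc:  # schema-level rejection; batch continues
            errors.append(f"{r.record_id}: {exc}")
            logger.warning("record %s rejected: %s", r.record_id, exc)

    pred = np.array([[a.flags.flags[i] for i in ITEM_IDS] for a in assessments], dtype=int)
    gold = np.array([[r.gold_flags.flags[i] for i in ITEM_IDS] for r in kept], dtype=int)

    per_item: Dict[str, dict] = {}
    for j, item in enumerate(ITEM_IDS):
        entry: dict = {"agreement": float((pred[:, j] == gold[:, j]).mean())}
        if len(set(gold[:, j].tolist())) == 2:
            entry["auc"] = em.auc(pred[:, j].astype(float), gold[:, j])
        else:
            entry["auc"] = None  # both outcomes not present
        per_item[item] = entry

    totals = np.array([a.total for a in assessments])
    gold_totals = np.array([total_score(r.gold_flags) for r in kept])
    pred_high = totals >= cutoff
    gold_high = gold_totals >= cutoff
    panel = em.binary_panel(pred_high, gold_high)

    risk_auc = None
    if len(set(gold_high.tolist())) == 2:
        risk_auc = em.auc(totals.astype(float), gold_high.astype(int))

    report = AssessmentReport(
        assessments=assessments,
        record_ids=record_ids,
        errors=errors,
        metrics={
            "per_item": per_item,
            "risk_level": panel,
            "risk_auc": risk_auc,
            "n_records": len(assessments),
        },
    )
    return report
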