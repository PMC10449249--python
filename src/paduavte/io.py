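"""Readers, writers, schema validation and configuration.

EMR batches travel as UTF-8 JSON Lines with ISO-8601 dates; lexicons
are term-per-line text (``#`` comments) or two-column TSV; reports are
JSON written atomically (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, List, Optional, Tuple

from paduavte.extractor import EMRecord, ExtractorConfig, LabPanel, LabThresholds
from paduavte.model import TrainConfig, TrainingUnit
from paduavte.scale import ITEM_IDS, ItemFlags
from paduavte.tokenize import Lexicon

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_emr_jsonl",
    "write_emr_jsonl",
    "read_lexicon",
    "write_lexicon",
    "read_training_units",
    "write_training_units",
    "write_report",
]


_RECORD_KEYS = {
    "record_id",
    "record_date",
    "diagnoses",
    "sections",
    "age_years",
    "height_m",
    "weight_kg",
    "labs",
    "gold_flags",
}


def _record_from_obj(obj: dict) -> EMRecord:
    unknown = set(obj) - _RECORD_KEYS
    if unknown:
        raise ValueError(f"unknown keys: {sorted(unknown)}")
    labs = LabPanel(**obj.get("labs", {}))
    gold = None
    if obj.get("gold_flags") is not None:
        g = obj["gold_flags"]
        gold = ItemFlags(flags={i: bool(g["flags"][i]) for i in ITEM_IDS}, provenance={k: list(v) for k, v in g.get("provenance", {}).items()})
    return EMRecord(
        record_id=str(obj["record_id"]),
        record_date=date.fromisoformat(obj["record_date"]),
        diagnoses=[str(d) for d in obj.get("diagnoses", [])],
        sections={str(k): str(v) for k, v in obj.get("sections", {}).items()},
        age_years=obj.get("age_years"),
        height_m=obj.get("height_m"),
        weight_kg=obj.get("weight_kg"),
        labs=labs,
        gold_flags=gold,
    )


def _record_to_obj(r: EMRecord) -> dict:
    obj = {
        "record_id": r.record_id,
        "record_date": r.record_date.isoformat(),
        "diagnoses": list(r.diagnoses),
        "sections": dict(r.sections),
        "age_years": r.age_years,
        "height_m": r.height_m,
        "weight_kg": r.weight_kg,
        "labs": {k: v for k, v in dataclasses.asdict(r.labs).items() if v is not None},
    }
    if r.gold_flags is not None:
        obj["gold_flags"] = {"flags": dict(r.gold_flags.flags), "provenance": dict(r.gold_flags.provenance)}
    return obj


def read_emr_jsonl(path, strict: bool = False) -> Tuple[List[EMRecord], List[str]]:
    """Read records from JSON Lines; returns (records, per-line errors).

    Malformed lines are recorded and skipped.  Under ``strict``,
    records missing age/height/weight are dropped too (mirroring a
    missing-values removal policy).
    """
    records: List[EMRecord] = []
    errors: List[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = _record_from_obj(json.loads(line))
            except (ValueError, KeyError, TypeError) as exc:
                errors.append(f"line {lineno}: {exc}")
                logger.warning("skipping malformed record at line %d: %s", lineno, exc)
                continue
            if strict and (rec.age_years is None or rec.height_m is None or rec.weight_kg is None):
                errors.append(f"line {lineno}: dropped (missing values under strict mode)")
                continue
            records.append(rec)
    return records, errors


def write_emr_jsonl(records, path) -> None:
    _atomic_write(path, "".join(json.dumps(_record_to_obj(r), ensure_ascii=False) + "\n" for r in records))


def read_lexicon(path, name: Optional[str] = None) -> Lexicon | Dict[str, Lexicon]:
    """Read a lexicon file.

    Term-per-line format (``#`` comments, blank lines ignored) needs
    ``name``; TSV lines ``term<TAB>lexicon-name`` may mix lexicons, in
    which case a dict keyed by name is returned.
    """
    per_name: Dict[str, set] = {}
    n_dupes = 0
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                term, lex_name = line.split("\t", 1)
                term, lex_name = term.strip(), lex_name.strip()
            else:
                term, lex_name = line.strip(), name
            if lex_name is None:
                raise ValueError(f"{path}: term-per-line lexicon needs an explicit name")
            bucket = per_name.setdefault(lex_name, set())
            if term in bucket:
                n_dupes += 1
            bucket.add(term)
    if n_dupes:
        logger.warning("%s: %d duplicate terms ignored", path, n_dupes)
    if not per_name or all(not v for v in per_name.values()):
        raise ValueError(f"{path}: empty lexicon after parsing")
    lexicons = {n: Lexicon(n, terms) for n, terms in per_name.items()}
    if name is not None and list(lexicons) == [name]:
        return lexicons[name]
    return lexicons


def write_lexicon(lexicon: Lexicon, path) -> None:
    _atomic_write(path, "".join(t + "\n" for t in sorted(lexicon.entries)))


def read_training_units(path) -> List[TrainingUnit]:
    """TSV: diagnosis<TAB>comma-joined symptoms<TAB>label; or JSON Lines."""
    units: List[TrainingUnit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.lstrip().startswith("{"):
                obj = json.loads(line)
                units.append(TrainingUnit(obj["diagnosis_text"], list(obj["symptom_terms"]), int(obj["category_label"])))
            else:
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
                symptoms = [s for s in parts[1].split(",") if s]
                units.append(TrainingUnit(parts[0], symptoms, int(parts[2])))
    return units


def write_training_units(units, path) -> None:
    lines = [
        json.dumps(
            {"diagnosis_text": u.diagnosis_text, "symptom_terms": u.symptom_terms, "category_label": u.category_label},
            ensure_ascii=False,
        )
        for u in units
    ]
    _atomic_write(path, "".join(line + "\n" for line in lines))


def write_report(report: dict, path) -> None:
    """Write a JSON report atomically."""
    _atomic_write(path, json.dumps(report, indent=2, ensure_ascii=False, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, date):
        return obj.isoformat()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _atomic_write(path, text: str) -> None:
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


@dataclass
class PipelineConfig:
    """Top-level configuration loaded from JSON; unknown keys rejected."""

    seed: int = 0
    lexicon_paths: Dict[str, str] = field(default_factory=dict)
    scale_path: Optional[str] = None
    cutoff: int = 3
    train: TrainConfig = field(default_factory=TrainConfig)
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    coverage_normalized: bool = False

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        train = TrainConfig(**obj.pop("train", {}))
        extractor_obj = obj.pop("extractor", {})
        thresholds = LabThresholds(**extractor_obj.pop("lab_thresholds", {}))
        extractor = ExtractorConfig(lab_thresholds=thresholds, **extractor_obj)
        cfg = cls(train=train, extractor=extractor, **obj)
        for name, p in cfg.lexicon_paths.items():
            if not os.path.exists(p):
                raise ValueError(f"lexicon file for {name!r} does not exist: {p}")
        if cfg.scale_path is not None and not os.path.exists(cfg.scale_path):
            raise ValueError(f"scale file does not exist: {cfg.scale_path}")
        return cfg
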