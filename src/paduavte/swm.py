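"""TF-IWF symptom weighting and symptom-weight-vector construction.

Each of the six disease categories (five Padua disease items plus
"Others") owns a symptom corpus of term occurrence counts.  A symptom's
weight for a category is its term frequency within that category times
the log inverse frequency in the pooled corpus; a unit's weight vector
sums, per category, each symptom's weight normalized by the category's
maximum weight.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

N_CATEGORIES = 6

__all__ = [
    "N_CATEGORIES",
    "CategorySymptomCorpus",
    "GlobalSymptomCorpus",
    "SwmStats",
    "tf",
    "iwf",
    "ti",
    "build_swm",
    "corpora_from_tsv",
    "corpora_from_units",
]


@dataclass
class CategorySymptomCorpus:
    """Occurrence counts of symptom terms for one disease category."""

    category_index: int
    term_counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.category_index < N_CATEGORIES):
            raise ValueError(f"category_index must be in 0..{N_CATEGORIES - 1}")
        for t, c in self.term_counts.items():
            if c < 0:
                raise ValueError(f"negative count for term {t!r}")

    @property
    def total_count(self) -> int:
        return sum(self.term_counts.values())


@dataclass
class GlobalSymptomCorpus:
    """Element-wise sum of the six category corpora."""

    term_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.term_counts.values())

    @classmethod
    def from_categories(cls, corpora: Sequence[CategorySymptomCorpus]) -> "GlobalSymptomCorpus":
        counts: Dict[str, int] = {}
        for c in corpora:
            for t, n in c.term_counts.items():
                counts[t] = counts.get(t, 0) + n
        return cls(term_counts=counts)


def tf(term: str, corpus: CategorySymptomCorpus) -> float:
    """Term frequency of ``term`` within one category corpus."""
    total = corpus.total_count
    if total <= 0:
        raise ValueError("empty category corpus")
    return corpus.term_counts.get(term, 0) / total


def iwf(term: str, global_corpus: GlobalSymptomCorpus, base: float | None = None) -> float:
    """Log inverse frequency of ``term`` in the pooled corpus.

    Raises ``KeyError`` for a term absent from the pooled corpus; the
    builders treat such terms as contributing zero instead of calling
    this directly.
    """
    n = global_corpus.term_counts.get(term, 0)
    if n <= 0:
        raise KeyError(f"term {term!r} absent from global corpus")
    ratio = global_corpus.total_count / n
    return math.log(ratio) if base is None else math.log(ratio, base)


def ti(
    term: str,
    category_index: int,
    corpora: Sequence[CategorySymptomCorpus],
    global_corpus: GlobalSymptomCorpus | None = None,
    base: float | None = None,
) -> float:
    """TF x IWF of ``term`` for one category; 0 when absent there."""
    by_index = {c.category_index: c for c in corpora}
    if category_index not in by_index:
        raise ValueError(f"no corpus for category {category_index}")
    gc = global_corpus if global_corpus is not None else GlobalSymptomCorpus.from_categories(corpora)
    _check_consistent(corpora, gc)
    corpus = by_index[category_index]
    if corpus.term_counts.get(term, 0) == 0:
        return 0.0
    return tf(term, corpus) * iwf(term, gc, base=base)


def _check_consistent(corpora: Sequence[CategorySymptomCorpus], gc: GlobalSymptomCorpus) -> None:
    expect = GlobalSymptomCorpus.from_categories(corpora).term_counts
    if expect != gc.term_counts:
        raise ValueError("global corpus is not the element-wise sum of the category corpora")


class SwmStats:
    """Precomputed per-category normalized TF-IWF weights.

    ``weight(term, k)`` is ``TI(term, k) / max_t TI(t, k)`` — the unit
    contribution a symptom adds to category ``k``.  Serializable to
    JSON so trained models can ship their corpus statistics.
    """

    def __init__(self, corpora: Sequence[CategorySymptomCorpus], base: float | None = None):
        by_index = {c.category_index: c for c in corpora}
        if sorted(by_index) != list(range(N_CATEGORIES)):
            raise ValueError(f"need exactly one corpus per category 0..{N_CATEGORIES - 1}")
        gc = GlobalSymptomCorpus.from_categories(corpora)
        self._weights: List[Dict[str, float]] = []
        for k in range(N_CATEGORIES):
            corpus = by_index[k]
            raw: Dict[str, float] = {}
            total = corpus.total_count
            for term, n in corpus.term_counts.items():
                if n > 0 and total > 0:
                    raw[term] = (n / total) * iwf(term, gc, base=base)
            top = max(raw.values(), default=0.0)
            # max TI can be 0 (every category term spans the whole pool);
            # 0/0 is defined as 0.
            if top > 0:
                self._weights.append({t: v / top for t, v in raw.items()})
            else:
                self._weights.append({t: 0.0 for t in raw})

    def weight(self, term: str, category_index: int) -> float:
        return self._weights[category_index].get(term, 0.0)

    def swm(self, symptoms: Iterable[str], dedupe: bool = True) -> List[float]:
        terms = list(symptoms)
        if dedupe:
            seen = set()
            uniq = []
            for t in terms:
                if t not in seen:
                    seen.add(t)
                    uniq.append(t)
            terms = uniq
        vec = [0.0] * N_CATEGORIES
        for t in terms:
            for k in range(N_CATEGORIES):
                vec[k] += self._weights[k].get(t, 0.0)
        return vec

    def to_json(self) -> str:
        return json.dumps({"weights": self._weights}, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "SwmStats":
        obj = cls.__new__(cls)
        obj._weights = [dict(w) for w in json.loads(text)["weights"]]
        if len(obj._weights) != N_CATEGORIES:
            raise ValueError("bad SwmStats JSON")
        return obj


def build_swm(
    symptoms: Sequence[str],
    corpora: Sequence[CategorySymptomCorpus],
    dedupe: bool = True,
    base: float | None = None,
) -> List[float]:
    """Accumulate the length-6 symptom weight vector for ``symptoms``.

    Unknown symptoms contribute zero everywhere.  With ``dedupe`` (the
    default, matching patient-level use) repeated terms count once.
    """
    return SwmStats(corpora, base=base).swm(symptoms, dedupe=dedupe)


def corpora_from_tsv(path) -> List[CategorySymptomCorpus]:
    """Load category corpora from TSV lines ``term<TAB>category<TAB>count``."""
    counts: List[Dict[str, int]] = [{} for _ in range(N_CATEGORIES)]
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            term, k, n = parts[0], int(parts[1]), int(parts[2])
            if not (0 <= k < N_CATEGORIES):
                raise ValueError(f"{path}:{lineno}: category {k} out of range")
            counts[k][term] = counts[k].get(term, 0) + n
    return [CategorySymptomCorpus(k, counts[k]) for k in range(N_CATEGORIES)]


def corpora_from_units(units) -> List[CategorySymptomCorpus]:
    """Aggregate category corpora from labeled training units."""
    counts: List[Dict[str, int]] = [{} for _ in range(N_CATEGORIES)]
    for u in units:
        for t in u.symptom_terms:
            counts[u.category_label][t] = counts[u.category_label].get(t, 0) + 1
    return [CategorySymptomCorpus(k, counts[k]) for k in range(N_CATEGORIES)]
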