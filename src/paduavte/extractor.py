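"""Branch B: lexicon matching, negation filtering, time-window and numeric rules.

Narrative sections are split into sentences, segmented against the
loaded lexicons, and matched; matches inside a negated clause are
flagged and excluded from downstream item flags (but kept for
provenance).  Surgery/trauma matches are anchored to a date parsed
from a TIME token in the same sentence and only fire the recent
surgery item inside the configured window.  Age, BMI and
thrombophilia are numeric rules over the structured fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from paduavte.scale import ITEM_IDS, ItemFlags
from paduavte.tokenize import (
    DEFAULT_NEGATION_TERMS,
    Lexicon,
    Token,
    parse_time,
    segment,
    split_clauses,
    split_sentences,
)

__all__ = [
    "TermMatch",
    "LabPanel",
    "EMRecord",
    "LabThresholds",
    "ExtractorConfig",
    "match_corpus",
    "filter_negated",
    "recent_surgery_flag",
    "reduced_mobility_flag",
    "hormone_flag",
    "elderly_flag",
    "obesity_flag",
    "thrombophilia_flag",
    "extract_symptoms",
    "extract_branch_b",
]


@dataclass
class TermMatch:
    """A lexicon hit in one sentence."""

    term: str
    lexicon_name: str
    sentence_index: int
    sentence: str = ""
    negated: bool = False
    anchored_date: Optional[date] = None


@dataclass
class LabPanel:
    """Coagulation labs; activities in percent, d-dimer in mg/L."""

    protein_c: Optional[float] = None
    protein_s: Optional[float] = None
    antithrombin_iii: Optional[float] = None
    d_dimer: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("protein_c", "protein_s", "antithrombin_iii", "d_dimer"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"lab {name} must be >= 0, got {v}")


@dataclass
class EMRecord:
    """One patient's document."""

    record_id: str
    record_date: date
    diagnoses: List[str] = field(default_factory=list)
    sections: Dict[str, str] = field(default_factory=dict)
    age_years: Optional[float] = None
    height_m: Optional[float] = None
    weight_kg: Optional[float] = None
    labs: LabPanel = field(default_factory=LabPanel)
    gold_flags: Optional[ItemFlags] = None

    def __post_init__(self) -> None:
        if self.record_date is None:
            raise ValueError("record_date is required")
        if not self.diagnoses and not any(v.strip() for v in self.sections.values()):
            raise ValueError("record needs at least one diagnosis or a non-empty section")


@dataclass
class LabThresholds:
    """Pathological bounds for the thrombophilia rule.

    The defaults are documented reference-range placeholders (activity
    percent lower bounds, d-dimer upper bound), all configurable.
    """

    protein_c_low: float = 70.0
    protein_s_low: float = 60.0
    antithrombin_iii_low: float = 80.0
    d_dimer_high: float = 0.5


@dataclass
class ExtractorConfig:
    window_days: int = 30
    negation_window: Optional[int] = None  # token distance; None = whole clause
    lab_thresholds: LabThresholds = field(default_factory=LabThresholds)
    elderly_age: float = 70.0
    obesity_bmi: float = 30.0


def default_negation_lexicon() -> Lexicon:
    return Lexicon("negation", set(DEFAULT_NEGATION_TERMS))


def match_corpus(tokens: Sequence[Token], lexicon: Lexicon, sentence_index: int = 0, sentence: str = "") -> List[TermMatch]:
    """One TermMatch per TERM token whose surface is a lexicon entry."""
    entries = {e.lower() for e in lexicon.entries}
    out: List[TermMatch] = []
    for tok in tokens:
        if tok.pos == "TERM" and tok.surface.lower() in entries:
            out.append(TermMatch(tok.surface, lexicon.name, sentence_index, sentence=sentence))
    return out


def filter_negated(
    matches: Sequence[TermMatch],
    tokens_per_sentence: Mapping[int, Sequence[Token]],
    sentences: Mapping[int, str],
    window: Optional[int] = None,
) -> List[TermMatch]:
    """Flag matches that fall in a negated clause.

    A match is negated when a NEG token lies in the same
    comma/semicolon-delimited clause and (if ``window`` is given)
    within ``window`` tokens before or after the matched term.  All
    matches are returned; callers drop ``negated`` ones from flags.
    """
    out: List[TermMatch] = []
    for m in matches:
        tokens = list(tokens_per_sentence.get(m.sentence_index, ()))
        sentence = sentences.get(m.sentence_index, m.sentence)
        negated = _is_negated(m, tokens, sentence, window)
        out.append(
            TermMatch(m.term, m.lexicon_name, m.sentence_index, sentence=m.sentence, negated=negated, anchored_date=m.anchored_date)
        )
    return out


def _is_negated(match: TermMatch, tokens: Sequence[Token], sentence: str, window: Optional[int]) -> bool:
    term_positions = [i for i, t in enumerate(tokens) if t.pos == "TERM" and t.surface.lower() == match.term.lower()]
    neg_positions = [i for i, t in enumerate(tokens) if t.pos == "NEG"]
    if not term_positions or not neg_positions:
        return False
    clauses = split_clauses(sentence)

    def clause_of(tok: Token) -> int:
        for ci, (s, e) in enumerate(clauses):
            if s <= tok.start < e:
                return ci
        return len(clauses) - 1

    for ti in term_positions:
        for ni in neg_positions:
            if clause_of(tokens[ti]) != clause_of(tokens[ni]):
                continue
            if window is not None and abs(ti - ni) > window:
                continue
            return True
    return False


def _anchor_dates(matches: List[TermMatch], tokens: Sequence[Token], reference_date: date) -> None:
    """Attach the nearest same-sentence TIME date to each match (in place)."""
    dated: List[tuple] = []
    for i, tok in enumerate(tokens):
        if tok.pos == "TIME":
            d = parse_time(tok, reference_date)
            if d is not None:
                dated.append((i, d))
    if not dated:
        return
    for m in matches:
        positions = [i for i, t in enumerate(tokens) if t.pos == "TERM" and t.surface.lower() == m.term.lower()]
        if not positions:
            continue
        p = positions[0]
        m.anchored_date = min(dated, key=lambda id_: abs(id_[0] - p))[1]


def recent_surgery_flag(matches: Iterable[TermMatch], reference_date: date, window_days: int = 30) -> bool:
    """True iff a non-negated surgery/trauma match is dated within the window.

    Undated mentions never fire the flag (conservative).
    """
    for m in matches:
        if m.negated or m.anchored_date is None:
            continue
        delta = (reference_date - m.anchored_date).days
        if 0 <= delta <= window_days:
            return True
    return False


def reduced_mobility_flag(matches: Iterable[TermMatch]) -> bool:
    return any(not m.negated for m in matches)


def hormone_flag(matches: Iterable[TermMatch]) -> bool:
    return any(not m.negated for m in matches)


def elderly_flag(age_years: Optional[float], threshold: float = 70.0) -> bool:
    if age_years is None:
        return False
    if age_years < 0:
        raise ValueError("age must be non-negative")
    return age_years >= threshold


def obesity_flag(height_m: Optional[float], weight_kg: Optional[float], threshold: float = 30.0) -> bool:
    if height_m is None or weight_kg is None:
        return False
    if height_m <= 0:
        raise ValueError("height must be positive")
    if weight_kg < 0:
        raise ValueError("weight must be non-negative")
    return weight_kg / height_m**2 >= threshold


def thrombophilia_flag(labs: LabPanel, thresholds: LabThresholds | None = None) -> bool:
    """Any present lab crossing its pathological bound fires the flag."""
    th = thresholds or LabThresholds()
    if labs.protein_c is not None and labs.protein_c < th.protein_c_low:
        return True
    if labs.protein_s is not None and labs.protein_s < th.protein_s_low:
        return True
    if labs.antithrombin_iii is not None and labs.antithrombin_iii < th.antithrombin_iii_low:
        return True
    if labs.d_dimer is not None and labs.d_dimer > th.d_dimer_high:
        return True
    return False


def _section_matches(
    record: EMRecord,
    lexicons: Sequence[Lexicon],
    negation: Lexicon,
    config: ExtractorConfig,
) -> Dict[str, List[TermMatch]]:
    """Run segmentation + matching + negation + date anchoring over all sections."""
    all_lex = list(lexicons) + [negation]
    by_name: Dict[str, List[TermMatch]] = {lx.name: [] for lx in lexicons}
    sentence_index = 0
    for _section, text in sorted(record.sections.items()):
        for sentence, _off in split_sentences(text):
            tokens = segment(sentence, all_lex)
            tokmap = {sentence_index: tokens}
            sentmap = {sentence_index: sentence}
            for lx in lexicons:
                matches = match_corpus(tokens, lx, sentence_index, sentence=sentence)
                matches = filter_negated(matches, tokmap, sentmap, window=config.negation_window)
                _anchor_dates(matches, tokens, record.record_date)
                by_name[lx.name].extend(matches)
            sentence_index += 1
    return by_name


def extract_symptoms(record: EMRecord, symptom_lexicon: Lexicon, negation: Lexicon | None = None, config: ExtractorConfig | None = None) -> List[str]:
    """Deduplicated non-negated symptom matches, in first-occurrence order."""
    cfg = config or ExtractorConfig()
    neg = negation or default_negation_lexicon()
    matches = _section_matches(record, [symptom_lexicon], neg, cfg)[symptom_lexicon.name]
    seen = set()
    out: List[str] = []
    for m in matches:
        key = m.term.lower()
        if not m.negated and key not in seen:
            seen.add(key)
            out.append(m.term)
    return out


def extract_branch_b(
    record: EMRecord,
    lexicons: Mapping[str, Lexicon],
    negation: Lexicon | None = None,
    config: ExtractorConfig | None = None,
) -> tuple:
    """Run the full Branch B pass over one record.

    Returns ``(flags, provenance, symptoms)`` where ``flags`` covers
    the six Branch B items (the five disease items stay false for
    Branch A to fill in) and ``symptoms`` feeds Branch A.
    """
    cfg = config or ExtractorConfig()
    neg = negation or default_negation_lexicon()
    wanted = [lexicons[n] for n in ("surgery_trauma", "hormone", "reduced_mobility", "symptom") if n in lexicons]
    by_name = _section_matches(record, wanted, neg, cfg)

    flags = {i: False for i in ITEM_IDS}
    prov: Dict[str, List[str]] = {i: [] for i in ITEM_IDS}

    surgery = by_name.get("surgery_trauma", [])
    flags["recent_surgery_trauma"] = recent_surgery_flag(surgery, record.record_date, cfg.window_days)
    for m in surgery:
        if not m.negated and m.anchored_date is not None and 0 <= (record.record_date - m.anchored_date).days <= cfg.window_days:
            prov["recent_surgery_trauma"].append(f"{m.term} on {m.anchored_date.isoformat()}: {m.sentence}")

    mobility = by_name.get("reduced_mobility", [])
    flags["reduced_mobility"] = reduced_mobility_flag(mobility)
    prov["reduced_mobility"] = [f"{m.term}: {m.sentence}" for m in mobility if not m.negated]

    hormone = by_name.get("hormone", [])
    flags["hormonal"] = hormone_flag(hormone)
    prov["hormonal"] = [f"{m.term}: {m.sentence}" for m in hormone if not m.negated]

    flags["elderly"] = elderly_flag(record.age_years, cfg.elderly_age)
    if flags["elderly"]:
        prov["elderly"].append(f"age {record.age_years:g} >= {cfg.elderly_age:g}")
    elif record.age_years is None:
        prov["elderly"].append("missing data: age")

    flags["obesity"] = obesity_flag(record.height_m, record.weight_kg, cfg.obesity_bmi)
    if flags["obesity"]:
        bmi = record.weight_kg / record.height_m**2
        prov["obesity"].append(f"BMI {bmi:.2f} >= {cfg.obesity_bmi:g}")
    elif record.height_m is None or record.weight_kg is None:
        prov["obesity"].append("missing data: height/weight")

    flags["thrombophilic"] = thrombophilia_flag(record.labs, cfg.lab_thresholds)
    if flags["thrombophilic"]:
        prov["thrombophilic"].append(f"labs {asdict(record.labs)} cross thresholds")

    symptoms = []
    seen = set()
    for m in by_name.get("symptom", []):
        key = m.term.lower()
        if not m.negated and key not in seen:
            seen.add(key)
            symptoms.append(m.term)

    # retain negated mentions as (excluded) provenance, per-item audit trail
    for item, name in (("recent_surgery_trauma", "surgery_trauma"), ("reduced_mobility", "reduced_mobility"), ("hormonal", "hormone")):
        for m in by_name.get(name, []):
            if m.negated:
                prov[item].append(f"[negated, excluded] {m.term}: {m.sentence}")

    return flags, prov, symptoms
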