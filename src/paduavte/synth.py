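"""Seeded synthetic fixtures: corpora, lexicons, training units, EMRs.

Stands in for the coding-system / knowledge-base / hospital data the
pipeline normally consumes.  Generated text is keyword-bearing
synthetic prose (both branches are lexicon/keyword driven, so no
realistic clinical language is needed).  All randomness flows through
counter-based Philox generators keyed by the spec seed, so fixtures
are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, List, Optional, Sequence

import numpy as np

from paduavte.extractor import EMRecord, LabPanel, LabThresholds
from paduavte.model import TrainingUnit
from paduavte.scale import BRANCH_A_ITEMS, ITEM_IDS, ItemFlags
from paduavte.swm import N_CATEGORIES, CategorySymptomCorpus
from paduavte.tokenize import Lexicon

__all__ = ["GeneratorSpec", "FixtureBundle", "gen_corpora", "gen_training_units", "gen_emr"]


@dataclass
class GeneratorSpec:
    seed: int = 0
    n_records: int = 100
    n_units: int = 600
    category_vocab_sizes: Sequence[int] = (12, 12, 12, 12, 12, 20)
    class_proportions: Optional[Sequence[float]] = None  # None => uniform
    item_prevalences: Dict[str, float] = field(default_factory=dict)
    negation_rate: float = 0.0
    dated_event_rate: float = 0.0  # out-of-window surgery distractors
    symptom_noise_rate: float = 0.0
    symptom_overlap: float = 0.0  # fraction of shared cross-category symptom terms
    diagnosis_ambiguity: float = 0.0  # fraction of units with shared diagnosis words
    symptoms_per_unit: int = 4
    window_days: int = 30

    def __post_init__(self) -> None:
        for name in ("negation_rate", "dated_event_rate", "symptom_noise_rate", "symptom_overlap", "diagnosis_ambiguity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for item, p in self.item_prevalences.items():
            if item not in ITEM_IDS:
                raise ValueError(f"unknown item id {item!r}")
            if not (0 <= p <= 1):
                raise ValueError(f"prevalence for {item} must be in [0, 1]")
        if len(self.category_vocab_sizes) != N_CATEGORIES:
            raise ValueError(f"need {N_CATEGORIES} vocab sizes")
        if any(s < 1 for s in self.category_vocab_sizes):
            raise ValueError("vocab sizes must be >= 1")


@dataclass
class FixtureBundle:
    corpora: List[CategorySymptomCorpus]
    lexicons: Dict[str, Lexicon]  # surgery_trauma, hormone, reduced_mobility, symptom, negation
    diagnosis_vocab: List[List[str]]  # per-category diagnosis words
    shared_diagnosis_vocab: List[str]  # ambiguous words usable by any category


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=np.uint64(seed), counter=np.uint64(stream)))


def gen_corpora(spec: GeneratorSpec) -> FixtureBundle:
    """Category symptom corpora with Zipf-like counts, plus the four lexicons."""
    rng = _rng(spec.seed, 1)
    n_shared = int(round(spec.symptom_overlap * min(spec.category_vocab_sizes)))
    shared_terms = [f"sympshared{i}" for i in range(n_shared)]
    corpora: List[CategorySymptomCorpus] = []
    all_symptoms: List[str] = []
    for k in range(N_CATEGORIES):
        size = int(spec.category_vocab_sizes[k])
        own = [f"sympcat{k}n{i}" for i in range(size - len(shared_terms))]
        terms = own + shared_terms[: max(0, size - len(own))]
        counts = {}
        for rank, t in enumerate(terms):
            base = max(1, int(round(60.0 / (rank + 1))))
            counts[t] = base + int(rng.integers(0, 3))
        corpora.append(CategorySymptomCorpus(k, counts))
        all_symptoms.extend(terms)

    surgery = {f"surgproc{i}" for i in range(8)} | {"artificial joint replacement", "open fracture repair"}
    hormone = {f"hormdrug{i}" for i in range(8)} | {"estrogen therapy"}
    mobility = {f"mobstate{i}" for i in range(6)} | {"deep coma", "strict bedrest"}
    lexicons = {
        "surgery_trauma": Lexicon("surgery_trauma", surgery),
        "hormone": Lexicon("hormone", hormone),
        "reduced_mobility": Lexicon("reduced_mobility", mobility),
        "symptom": Lexicon("symptom", set(all_symptoms)),
        "negation": Lexicon("negation", {"no", "not", "none", "denies", "without", "not seen", "not found"}),
    }
    diag_vocab = [[f"diagcat{k}w{i}" for i in range(10)] for k in range(N_CATEGORIES)]
    shared_diag = [f"diagsharedw{i}" for i in range(10)]
    return FixtureBundle(corpora, lexicons, diag_vocab, shared_diag)


def _draw_symptoms(rng: np.random.Generator, corpus: CategorySymptomCorpus, k: int) -> List[str]:
    terms = sorted(corpus.term_counts)
    weights = np.array([corpus.term_counts[t] for t in terms], dtype=np.float64)
    weights /= weights.sum()
    k = min(k, len(terms))
    idx = rng.choice(len(terms), size=k, replace=False, p=weights)
    return [terms[i] for i in idx]


def _diagnosis_text(rng: np.random.Generator, bundle: FixtureBundle, category: int, ambiguous: bool) -> str:
    vocab = bundle.shared_diagnosis_vocab if ambiguous else bundle.diagnosis_vocab[category]
    n_words = int(rng.integers(2, 5))
    idx = rng.choice(len(vocab), size=min(n_words, len(vocab)), replace=False)
    return " ".join(vocab[i] for i in idx)


def gen_training_units(spec: GeneratorSpec, bundle: FixtureBundle) -> List[TrainingUnit]:
    """Labeled (diagnosis, symptoms) units with controlled noise/ambiguity.

    Class counts follow ``class_proportions`` exactly (largest-remainder
    apportionment of ``n_units``).
    """
    rng = _rng(spec.seed, 2)
    props = np.array(spec.class_proportions if spec.class_proportions is not None else [1.0] * N_CATEGORIES, dtype=np.float64)
    props /= props.sum()
    raw = props * spec.n_units
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: spec.n_units - counts.sum()]:
        counts[i] += 1

    units: List[TrainingUnit] = []
    for k in range(N_CATEGORIES):
        for _ in range(int(counts[k])):
            ambiguous = bool(rng.random() < spec.diagnosis_ambiguity)
            text = _diagnosis_text(rng, bundle, k, ambiguous)
            symptoms = _draw_symptoms(rng, bundle.corpora[k], spec.symptoms_per_unit)
            if spec.symptom_noise_rate > 0:
                for i in range(len(symptoms)):
                    if rng.random() < spec.symptom_noise_rate:
                        other = int(rng.integers(N_CATEGORIES))
                        symptoms[i] = _draw_symptoms(rng, bundle.corpora[other], 1)[0]
            units.append(TrainingUnit(text, symptoms, k))
    order = rng.permutation(len(units))
    return [units[i] for i in order]


_ITEM_TO_CATEGORY = {item: k for k, item in enumerate(BRANCH_A_ITEMS)}


def gen_emr(spec: GeneratorSpec, bundle: FixtureBundle, reference_date: date = date(2021, 6, 1)) -> List[EMRecord]:
    """Full EMRs with planted item evidence and exact gold flags."""
    rng = _rng(spec.seed, 3)
    thresholds = LabThresholds()
    records: List[EMRecord] = []
    lex = bundle.lexicons
    surgery_terms = sorted(lex["surgery_trauma"].entries)
    hormone_terms = sorted(lex["hormone"].entries)
    mobility_terms = sorted(lex["reduced_mobility"].entries)
    symptom_terms = sorted(lex["symptom"].entries)

    for ridx in range(spec.n_records):
        planted = {item: bool(rng.random() < spec.item_prevalences.get(item, 0.0)) for item in ITEM_IDS}
        record_date = reference_date + timedelta(days=int(rng.integers(0, 30)))

        history: List[str] = []
        complaints: List[str] = ["Routine observation note."]
        examination: List[str] = []
        plan: List[str] = []
        diagnoses: List[str] = []
        prov = {i: [] for i in ITEM_IDS}

        if planted["recent_surgery_trauma"]:
            term = surgery_terms[int(rng.integers(len(surgery_terms)))]
            delta = int(rng.integers(0, spec.window_days + 1))
            d = record_date - timedelta(days=delta)
            history.append(f"On {d.isoformat()}, patient underwent {term}.")
            prov["recent_surgery_trauma"].append(f"planted {term} {d.isoformat()}")
        elif rng.random() < spec.dated_event_rate:
            term = surgery_terms[int(rng.integers(len(surgery_terms)))]
            delta = int(rng.integers(spec.window_days + 1, 365))
            d = record_date - timedelta(days=delta)
            history.append(f"On {d.isoformat()}, patient underwent {term}.")

        if planted["reduced_mobility"]:
            term = mobility_terms[int(rng.integers(len(mobility_terms)))]
            examination.append(f"Patient presents {term} since admission.")
            prov["reduced_mobility"].append(f"planted {term}")

        if planted["hormonal"]:
            term = hormone_terms[int(rng.integers(len(hormone_terms)))]
            plan.append(f"Currently taking {term} daily.")
            prov["hormonal"].append(f"planted {term}")

        if rng.random() < spec.negation_rate:
            pool = surgery_terms + hormone_terms + mobility_terms + symptom_terms
            term = pool[int(rng.integers(len(pool)))]
            examination.append(f"No {term} found.")

        age = float(rng.integers(70, 95)) if planted["elderly"] else float(rng.integers(20, 70))
        if planted["elderly"]:
            prov["elderly"].append(f"planted age {age:g}")

        height = round(1.55 + 0.35 * float(rng.random()), 2)
        if planted["obesity"]:
            bmi = 31.0 + 8.0 * float(rng.random())
            prov["obesity"].append(f"planted BMI {bmi:.1f}")
        else:
            bmi = 19.0 + 8.0 * float(rng.random())
        weight = round(bmi * height**2, 1)

        if planted["thrombophilic"]:
            labs = LabPanel(protein_c=round(thresholds.protein_c_low * (0.3 + 0.6 * float(rng.random())), 1))
            prov["thrombophilic"].append(f"planted protein C {labs.protein_c:g}")
        else:
            labs = LabPanel(
                protein_c=round(thresholds.protein_c_low + 10 + 40 * float(rng.random()), 1),
                d_dimer=round(thresholds.d_dimer_high * 0.5 * float(rng.random()), 2),
            )

        for item in BRANCH_A_ITEMS:
            if planted[item]:
                k = _ITEM_TO_CATEGORY[item]
                text = _diagnosis_text(rng, bundle, k, ambiguous=False)
                diagnoses.append(text)
                prov[item].append(f"planted diagnosis: {text}")
                for t in _draw_symptoms(rng, bundle.corpora[k], 3):
                    complaints.append(f"Reports {t} today.")
        diagnoses.append(_diagnosis_text(rng, bundle, N_CATEGORIES - 1, ambiguous=False))

        gold = ItemFlags(
            flags=dict(planted),
            provenance={i: (prov[i] if planted[i] else []) for i in ITEM_IDS},
        )
        records.append(
            EMRecord(
                record_id=f"rec{ridx:05d}",
                record_date=record_date,
                diagnoses=diagnoses,
                sections={
                    "past_history": " ".join(history),
                    "complaints": " ".join(complaints),
                    "examination": " ".join(examination),
                    "treatment_plan": " ".join(plan),
                },
                age_years=age,
                height_m=height,
                weight_kg=weight,
                labs=labs,
                gold_flags=gold,
            )
        )
    return records
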