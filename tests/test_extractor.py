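from datetime import date, timedelta

import pytest

from paduavte.extractor import (
    EMRecord,
    ExtractorConfig,
    LabPanel,
    LabThresholds,
    TermMatch,
    elderly_flag,
    extract_branch_b,
    extract_symptoms,
    filter_negated,
    hormone_flag,
    match_corpus,
    obesity_flag,
    recent_surgery_flag,
    reduced_mobility_flag,
    thrombophilia_flag,
)
from paduavte.tokenize import Lexicon, segment


@pytest.fixture
def lexicons(negation_lexicon):
    return {
        "surgery_trauma": Lexicon("surgery_trauma", {"artificial joint replacement", "fracture repair"}),
        "hormone": Lexicon("hormone", {"estrogen therapy", "hormones", "hormone"}),
        "reduced_mobility": Lexicon("reduced_mobility", {"deep coma", "strict bedrest"}),
        "symptom": Lexicon("symptom", {"fever", "cough", "abnormalities"}),
        "negation": negation_lexicon,
    }


def run_sentence(sentence, lexicon, negation, window=None):
    tokens = segment(sentence, [lexicon, negation])
    matches = match_corpus(tokens, lexicon, 0, sentence)
    return filter_negated(matches, {0: tokens}, {0: sentence}, window=window)


class TestMatchCorpus:
    def test_no_term_tokens(self, lexicons):
        tokens = segment("nothing of note here", [lexicons["symptom"], lexicons["negation"]])
        assert match_corpus(tokens, lexicons["symptom"]) == []

    def test_fig3_surgery_match(self, lexicons):
        sentence = "On April 16, 2021, he was hospitalized Hospital for artificial joint replacement"
        tokens = segment(sentence, [lexicons["surgery_trauma"], lexicons["negation"]])
        matches = match_corpus(tokens, lexicons["surgery_trauma"], 0, sentence)
        assert len(matches) == 1
        assert matches[0].term == "artificial joint replacement"

    def test_duplicate_across_sentences_distinct_index(self, lexicons):
        out = []
        for idx, sentence in enumerate(["fever today", "fever again"]):
            tokens = segment(sentence, [lexicons["symptom"], lexicons["negation"]])
            out.extend(match_corpus(tokens, lexicons["symptom"], idx, sentence))
        assert [m.sentence_index for m in out] == [0, 1]


class TestFilterNegated:
    def test_not_using_hormones(self, lexicons):
        matches = run_sentence("patient is not using hormones", lexicons["hormone"], lexicons["negation"])
        assert len(matches) == 1 and matches[0].negated

    def test_no_abnormalities_seen(self, lexicons):
        matches = run_sentence("no abnormalities seen", lexicons["symptom"], lexicons["negation"])
        assert len(matches) == 1 and matches[0].negated

    def test_cue_free_sentence_unflagged(self, lexicons):
        matches = run_sentence("patient is using hormones", lexicons["hormone"], lexicons["negation"])
        assert len(matches) == 1 and not matches[0].negated

    def test_clause_scope(self, lexicons):
        # cue in the first clause must not negate a match in the second
        matches = run_sentence("no fever, cough persists", lexicons["symptom"], lexicons["negation"])
        by_term = {m.term: m.negated for m in matches}
        assert by_term == {"fever": True, "cough": False}

    def test_token_window(self, lexicons):
        sentence = "no significant prior issues were documented regarding fever"
        whole_clause = run_sentence(sentence, lexicons["symptom"], lexicons["negation"])
        assert whole_clause[0].negated
        windowed = run_sentence(sentence, lexicons["symptom"], lexicons["negation"], window=2)
        assert not windowed[0].negated


class TestRecentSurgeryFlag:
    REF = date(2021, 4, 30)

    def make(self, d, negated=False):
        return TermMatch("fracture repair", "surgery_trauma", 0, negated=negated, anchored_date=d)

    def test_within_window(self):
        assert recent_surgery_flag([self.make(date(2021, 4, 16))], self.REF)

    def test_outside_window(self):
        assert not recent_surgery_flag([self.make(date(2021, 4, 16))], date(2021, 12, 1))

    def test_boundary_exact_window(self):
        assert recent_surgery_flag([self.make(self.REF - timedelta(days=30))], self.REF)

    def test_boundary_window_plus_one(self):
        assert not recent_surgery_flag([self.make(self.REF - timedelta(days=31))], self.REF)

    def test_future_date_does_not_fire(self):
        assert not recent_surgery_flag([self.make(self.REF + timedelta(days=3))], self.REF)

    def test_negated_excluded(self):
        assert not recent_surgery_flag([self.make(date(2021, 4, 29), negated=True)], self.REF)

    def test_undated_does_not_fire(self):
        assert not recent_surgery_flag([self.make(None)], self.REF)


class TestSimpleFlags:
    def test_reduced_mobility_positive(self):
        m = TermMatch("deep coma", "reduced_mobility", 0)
        assert reduced_mobility_flag([m])

    def test_only_negated_false(self):
        m = TermMatch("deep coma", "reduced_mobility", 0, negated=True)
        assert not reduced_mobility_flag([m])

    def test_empty_false(self):
        assert not reduced_mobility_flag([]) and not hormone_flag([])


class TestNumericFlags:
    def test_elderly_at_70(self):
        assert elderly_flag(70)

    def test_not_elderly_below(self):
        assert not elderly_flag(69.9)

    def test_elderly_missing(self):
        assert not elderly_flag(None)

    def test_obesity_true(self):
        assert obesity_flag(1.70, 88)  # BMI 30.45

    def test_obesity_false(self):
        assert not obesity_flag(1.70, 60)  # BMI 20.76

    def test_obesity_matches_direct_arithmetic(self):
        for h, w in [(1.5, 67.5), (1.8, 97.2), (1.62, 78.0)]:
            assert obesity_flag(h, w) == (w / h**2 >= 30)

    def test_bad_height_rejected(self):
        with pytest.raises(ValueError):
            obesity_flag(0, 70)

    def test_missing_anthropometrics(self):
        assert not obesity_flag(None, 70)


class TestThrombophilia:
    def test_empty_panel_false(self):
        assert not thrombophilia_flag(LabPanel())

    def test_low_protein_c_true(self):
        assert thrombophilia_flag(LabPanel(protein_c=50.0))

    def test_all_normal_false(self):
        labs = LabPanel(protein_c=90, protein_s=80, antithrombin_iii=100, d_dimer=0.3)
        assert not thrombophilia_flag(labs)

    def test_high_d_dimer_true(self):
        assert thrombophilia_flag(LabPanel(d_dimer=2.5))

    def test_custom_thresholds(self):
        labs = LabPanel(protein_c=65.0)
        assert thrombophilia_flag(labs)
        assert not thrombophilia_flag(labs, LabThresholds(protein_c_low=60.0))

    def test_negative_lab_rejected(self):
        with pytest.raises(ValueError):
            LabPanel(protein_c=-1)


def make_record(**kwargs):
    defaults = dict(
        record_id="r1",
        record_date=date(2021, 4, 30),
        sections={"complaints": "fever and cough noted."},
    )
    defaults.update(kwargs)
    return EMRecord(**defaults)


class TestExtractSymptoms:
    def test_order_and_dedupe(self, lexicons):
        rec = make_record(sections={"complaints": "fever and cough noted. fever again."})
        assert extract_symptoms(rec, lexicons["symptom"]) == ["fever", "cough"]

    def test_negated_excluded(self, lexicons):
        rec = make_record(sections={"complaints": "no fever."})
        assert extract_symptoms(rec, lexicons["symptom"]) == []

    def test_empty_sections(self, lexicons):
        rec = make_record(sections={}, diagnoses=["something"])
        assert extract_symptoms(rec, lexicons["symptom"]) == []


class TestExtractBranchB:
    def test_full_record(self, lexicons):
        rec = make_record(
            sections={
                "past_history": "On April 16, 2021, he underwent artificial joint replacement.",
                "examination": "Patient in deep coma. no fever.",
                "treatment_plan": "Continuing estrogen therapy daily.",
            },
            age_years=72,
            height_m=1.70,
            weight_kg=88.0,
            labs=LabPanel(protein_c=50.0),
        )
        flags, prov, symptoms = extract_branch_b(rec, lexicons)
        assert flags["recent_surgery_trauma"]
        assert flags["reduced_mobility"]
        assert flags["hormonal"]
        assert flags["elderly"]
        assert flags["obesity"]
        assert flags["thrombophilic"]
        assert symptoms == []  # the only symptom mention is negated
        for item in ("recent_surgery_trauma", "reduced_mobility", "hormonal"):
            assert prov[item]

    def test_deterministic(self, lexicons):
        rec = make_record(sections={"complaints": "fever, no cough, deep coma."})
        assert extract_branch_b(rec, lexicons) == extract_branch_b(rec, lexicons)

    def test_record_needs_content(self):
        with pytest.raises(ValueError):
            EMRecord(record_id="x", record_date=date(2021, 1, 1), sections={"a": " "})


class TestNegationSuiteGenerated:
    """Soundness over generated sentences: every cue-clause match flagged,
    zero false flags in cue-free sentences."""

    def test_generated_suite(self, lexicons):
        import numpy as np

        rng = np.random.default_rng(42)
        terms = sorted(lexicons["symptom"].entries)
        cues = ["no", "denies", "without", "not seen"]
        fillers = ["patient", "reports", "mild", "persistent", "since", "yesterday", "overnight"]
        for i in range(500):
            term = terms[int(rng.integers(len(terms)))]
            negated = bool(rng.integers(2))
            words = [fillers[int(rng.integers(len(fillers)))] for _ in range(int(rng.integers(0, 4)))]
            if negated:
                cue = cues[int(rng.integers(len(cues)))]
                sentence = " ".join([cue] + words + [term])
            else:
                sentence = " ".join(words + [term])
            matches = run_sentence(sentence, lexicons["symptom"], lexicons["negation"])
            assert len(matches) == 1, sentence
            assert matches[0].negated == negated, sentence
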