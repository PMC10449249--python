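import pytest

from paduavte.swm import CategorySymptomCorpus, SwmStats
from paduavte.synth import GeneratorSpec, gen_corpora, gen_training_units
from paduavte.tokenize import DEFAULT_NEGATION_TERMS, Lexicon


@pytest.fixture
def toy_corpora():
    """Two informative categories {fever,cough} / {cough}, rest empty."""
    corpora = [CategorySymptomCorpus(k, {}) for k in range(6)]
    corpora[0] = CategorySymptomCorpus(0, {"fever": 2, "cough": 1})
    corpora[1] = CategorySymptomCorpus(1, {"cough": 1})
    return corpora


@pytest.fixture
def negation_lexicon():
    return Lexicon("negation", set(DEFAULT_NEGATION_TERMS))


@pytest.fixture(scope="session")
def small_bundle():
    spec = GeneratorSpec(seed=7, n_units=120, n_records=40)
    return spec, gen_corpora(spec)


@pytest.fixture(scope="session")
def trained_model(small_bundle):
    """A small trained classifier shared across tests (session-scoped)."""
    from paduavte.model import TrainConfig, train

    spec, bundle = small_bundle
    units = gen_training_units(spec, bundle)
    stats = SwmStats(bundle.corpora)
    model = train(units, stats, TrainConfig(seed=7, max_epochs=30, patience=5))
    return model, bundle, units, stats
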