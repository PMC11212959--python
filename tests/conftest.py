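import numpy as np
import pytest

from parsability.corpus_model import Lexicon, annotate
from parsability.surprisal_scoring import ToyPCFG
from parsability.synthetic_data import SyntheticWorld, default_grammar, default_lexicon


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return default_lexicon()


@pytest.fixture(scope="session")
def grammar() -> ToyPCFG:
    return default_grammar()


@pytest.fixture(scope="session")
def world() -> SyntheticWorld:
    return SyntheticWorld(seed=20_240)


@pytest.fixture(scope="session")
def base_sentences(world):
    return world.gen_base_sentences(12)


@pytest.fixture(scope="session")
def ngram_table(world):
    return world.gen_ngram_table(2000)


@pytest.fixture
def toy_sentence(lexicon):
    return annotate("the old dog chased a cat near the tiny garden soon twice", lexicon, "t1")


# finite-language grammars for which exhaustive enumeration is exact; these
# exercise plain binary rules, ambiguity, unit chains, and >2-symbol rules
FIXTURE_GRAMMARS = {
    "deterministic": ToyPCFG([("S", ("a", "b"), 1.0)]),
    "two_way": ToyPCFG([("S", ("a", "b"), 0.5), ("S", ("a", "c"), 0.5)]),
    "unit_chain": ToyPCFG(
        [
            ("S", ("A",), 0.7),
            ("S", ("A", "B"), 0.3),
            ("A", ("x",), 1.0),
            ("B", ("y",), 0.5),
            ("B", ("z",), 0.5),
        ]
    ),
    "ambiguous": ToyPCFG(
        [
            ("S", ("X", "Y"), 0.6),
            ("S", ("Z",), 0.4),
            ("X", ("a",), 1.0),
            ("Y", ("b", "c"), 0.5),
            ("Y", ("b",), 0.5),
            ("Z", ("a", "b"), 1.0),
        ]
    ),
    "ternary": ToyPCFG(
        [
            ("S", ("a", "M", "b"), 1.0),
            ("M", ("m",), 0.25),
            ("M", ("m", "m"), 0.75),
        ]
    ),
}


@pytest.fixture(params=sorted(FIXTURE_GRAMMARS), ids=sorted(FIXTURE_GRAMMARS))
def fixture_grammar(request):
    return FIXTURE_GRAMMARS[request.param]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
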