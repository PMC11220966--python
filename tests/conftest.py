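import numpy as np
import pytest

from mrcner.corpus_io import EntitySpan, LabeledCorpus, Sentence
from mrcner.mrc_dataset import WhitespaceTokenizer, build_triples, encode_corpus
from mrcner.query_bank import QuerySet, QuerySpec, build_query_set
from mrcner.span_model import HeadParams


@pytest.fixture
def tok():
    return WhitespaceTokenizer()


@pytest.fixture
def chem_sentence_corpus():
    """The "docosahexaenoic acids" single-entity example."""
    sent = Sentence(("Fish", "contains", "docosahexaenoic", "acids"), "s0")
    return LabeledCorpus([sent], [{EntitySpan(2, 3, "CHEM")}], ("CHEM",))


@pytest.fixture
def two_type_corpus():
    s0 = Sentence(("a", "mat_01", "mat_02", "b", "pro_01"), "s0")
    s1 = Sentence(("c", "d", "pro_02"), "s1")
    return LabeledCorpus(
        [s0, s1],
        [{EntitySpan(1, 2, "MAT"), EntitySpan(4, 4, "PRO")}, {EntitySpan(2, 2, "PRO")}],
        ("MAT", "PRO"),
    )


@pytest.fixture
def two_type_queries(two_type_corpus):
    return build_query_set(two_type_corpus.label_set, "guideline")


class PlantedEncoder:
    """Oracle encoder: emits rows whose class-1 logits align with the gold
    start/end bits of known examples (keyed by their piece tuples)."""

    d = 4

    def __init__(self, examples):
        self.lookup = {ex.pieces: (ex.start_labels, ex.end_labels) for ex in examples}
        self.params = {}

    def forward(self, pieces):
        start, end = self.lookup[tuple(pieces)]
        n = len(start)
        L = np.zeros((n, 4))
        L[:, 0] = start
        L[:, 1] = 1.0 - start
        L[:, 2] = end
        L[:, 3] = 1.0 - end
        return L, {}

    def backward(self, cache, dL):
        raise NotImplementedError("planted encoder is inference-only")


def planted_head(mode: str = "conditioned") -> HeadParams:
    """Head weights that read the planted bits back out of PlantedEncoder
    rows; conditioning weights are zero."""
    q_start = np.array([[0.0, 10.0], [10.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
    q_end = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 10.0], [10.0, 0.0]])
    if mode == "conditioned":
        q_end = np.vstack([q_end, np.zeros((2, 2))])
    return HeadParams(q_start, q_end, mode)


@pytest.fixture
def planted(two_type_corpus, two_type_queries, tok):
    examples = encode_corpus(
        build_triples(two_type_corpus, two_type_queries), tok, max_len=64
    )
    return examples, PlantedEncoder(examples), planted_head()
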