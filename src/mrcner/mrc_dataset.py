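"""(Context, Query, Answer) triples and their encoded form.

A labeled corpus plus a query set becomes one triple per sentence x entity
type (negatives included: sentences without an entity of the type yield a
triple with empty answers).  Encoding lays pieces out as
``[CLS] q1..qm [SEP] x-pieces [SEP]`` with binary start/end label vectors in
piece space; long contexts are split into word-aligned windows.  Decoding
maps predicted piece spans back to word space, snapping mid-word endpoints
outward to word boundaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Protocol, Sequence

import numpy as np

from .corpus_io import EntitySpan, LabeledCorpus, Sentence
from .query_bank import QuerySet, QuerySpec, validate_query_set

logger = logging.getLogger(__name__)

CLS = "[CLS]"
SEP = "[SEP]"

DEFAULT_MAX_LEN = 512
DEFAULT_STRIDE = 128


class EncodingError(ValueError):
    pass


class TokenizerContract(Protocol):
    """Deterministic word -> non-empty subword piece list."""

    def pieces(self, word: str) -> list[str]: ...


class WhitespaceTokenizer:
    """One piece per word (identity tokenizer)."""

    def pieces(self, word: str) -> list[str]:
        return [word]


class CharChunkTokenizer:
    """Split words into fixed-size character chunks with ``##`` continuation
    markers; concatenating the pieces (modulo markers) recovers the word."""

    def __init__(self, chunk: int = 4):
        if chunk < 1:
            raise ValueError("chunk must be positive")
        self.chunk = chunk

    def pieces(self, word: str) -> list[str]:
        out = [word[: self.chunk]]
        for i in range(self.chunk, len(word), self.chunk):
            out.append("##" + word[i : i + self.chunk])
        return out


@dataclass(frozen=True)
class MRCTriple:
    sentence: Sentence
    sentence_index: int
    query: QuerySpec
    answers: frozenset[EntitySpan]

    def __post_init__(self) -> None:
        for sp in self.answers:
            if sp.label != self.query.entity_type:
                raise ValueError(
                    f"answer {sp} does not match query type {self.query.entity_type!r}"
                )


@dataclass
class EncodedExample:
    pieces: tuple[str, ...]
    start_labels: np.ndarray  # int8, length N
    end_labels: np.ndarray
    context_mask: np.ndarray  # bool, length N
    word_map: dict[int, tuple[int, int]]  # word idx -> (first, last) piece pos
    sentence_id: str
    entity_type: str
    answers: frozenset[EntitySpan]  # full triple answers, word space
    window_index: int = 0
    n_windows: int = 1

    @property
    def N(self) -> int:
        return len(self.pieces)

    def piece_to_word(self) -> dict[int, int]:
        return {
            pos: w
            for w, (first, last) in self.word_map.items()
            for pos in range(first, last + 1)
        }


def build_triples(corpus: LabeledCorpus, qs: QuerySet) -> list[MRCTriple]:
    """Exactly ``|sentences| * |labels|`` triples, sentence-major,
    label-minor; the union of answers over triples equals the annotations."""
    report = validate_query_set(qs, corpus)
    if not report["ok"]:
        raise ValueError(f"query set does not match corpus labels: {report}")
    triples: list[MRCTriple] = []
    for idx, (sent, spans) in enumerate(corpus.iter_items()):
        for label in qs.labels():
            answers = frozenset(sp for sp in spans if sp.label == label)
            triples.append(MRCTriple(sent, idx, qs[label], answers))
    return triples


def _word_windows(
    piece_lens: Sequence[int], capacity: int, stride: int
) -> list[tuple[int, int]]:
    """Word-aligned windows [start, end) whose total piece count fits
    ``capacity``; successive starts advance by >= ``stride`` pieces."""
    n = len(piece_lens)
    windows: list[tuple[int, int]] = []
    start = 0
    while True:
        used = 0
        end = start
        while end < n and used + piece_lens[end] <= capacity:
            used += piece_lens[end]
            end += 1
        if end == start:  # single word longer than capacity
            end = start + 1
        windows.append((start, end))
        if end >= n:
            return windows
        advanced = 0
        new_start = start
        while new_start < end - 1 and advanced < stride:
            advanced += piece_lens[new_start]
            new_start += 1
        start = max(new_start, start + 1)


def encode_example(
    triple: MRCTriple,
    tok: TokenizerContract,
    max_len: int = DEFAULT_MAX_LEN,
    stride: int = DEFAULT_STRIDE,
) -> list[EncodedExample]:
    """Encode one triple into one or more windowed examples.

    Label bits follow the first/last-piece rule: the start bit sits on the
    first piece of the span's start word, the end bit on the last piece of
    its end word.  Answers crossing a window boundary are dropped from that
    window with a warning (they count as FN at evaluation time).
    """
    q_pieces: list[str] = []
    for w in triple.query.text.split():
        q_pieces.extend(tok.pieces(w))
    overhead = 1 + len(q_pieces) + 1 + 1  # [CLS] q [SEP] ... [SEP]
    capacity = max_len - overhead
    if capacity < 1:
        raise EncodingError(
            f"query of {len(q_pieces)} pieces leaves no room for context "
            f"(max_len={max_len})"
        )

    word_pieces = [tok.pieces(w) for w in triple.sentence.tokens]
    piece_lens = [len(p) for p in word_pieces]
    windows = _word_windows(piece_lens, capacity, stride)

    examples: list[EncodedExample] = []
    for widx, (w_start, w_end) in enumerate(windows):
        pieces: list[str] = [CLS, *q_pieces, SEP]
        context_first = len(pieces)
        word_map: dict[int, tuple[int, int]] = {}
        for w in range(w_start, w_end):
            wp = word_pieces[w]
            if len(wp) > capacity:  # oversized word: truncate its pieces
                logger.warning(
                    "word %d of sentence %s truncated to %d pieces",
                    w, triple.sentence.sentence_id, capacity,
                )
                wp = wp[:capacity]
            first = len(pieces)
            pieces.extend(wp)
            word_map[w] = (first, len(pieces) - 1)
        context_last = len(pieces) - 1
        pieces.append(SEP)

        N = len(pieces)
        start_labels = np.zeros(N, dtype=np.int8)
        end_labels = np.zeros(N, dtype=np.int8)
        context_mask = np.zeros(N, dtype=bool)
        context_mask[context_first : context_last + 1] = True

        for sp in triple.answers:
            if sp.start in word_map and sp.end in word_map:
                start_labels[word_map[sp.start][0]] = 1
                end_labels[word_map[sp.end][1]] = 1
            elif len(windows) == 1 or (
                w_start <= sp.start < w_end or w_start <= sp.end < w_end
            ):
                logger.warning(
                    "answer %s of sentence %s crosses window %d boundary; dropped",
                    sp, triple.sentence.sentence_id, widx,
                )
        examples.append(
            EncodedExample(
                pieces=tuple(pieces),
                start_labels=start_labels,
                end_labels=end_labels,
                context_mask=context_mask,
                word_map=word_map,
                sentence_id=triple.sentence.sentence_id,
                entity_type=triple.query.entity_type,
                answers=triple.answers,
                window_index=widx,
                n_windows=len(windows),
            )
        )
    return examples


def encode_corpus(
    triples: Iterable[MRCTriple],
    tok: TokenizerContract,
    max_len: int = DEFAULT_MAX_LEN,
    stride: int = DEFAULT_STRIDE,
) -> list[EncodedExample]:
    out: list[EncodedExample] = []
    for t in triples:
        out.extend(encode_example(t, tok, max_len=max_len, stride=stride))
    return out


def decode_predictions(
    examples: Sequence[EncodedExample],
    predictions: Sequence[Iterable],
) -> dict[str, set[EntitySpan]]:
    """Map per-example predicted piece spans back to word-space annotations.

    ``predictions[i]`` holds objects with ``start``/``end`` piece positions
    for ``examples[i]``.  Mid-word endpoints snap outward to word boundaries;
    duplicates across windows and queries are unioned per sentence.
    """
    out: dict[str, set[EntitySpan]] = {}
    for ex, spans in zip(examples, predictions):
        sent_spans = out.setdefault(ex.sentence_id, set())
        p2w = ex.piece_to_word()
        for sp in spans:
            if sp.start not in p2w or sp.end not in p2w:
                logger.warning(
                    "predicted span (%d, %d) outside context of %s; dropped",
                    sp.start, sp.end, ex.sentence_id,
                )
                continue
            sent_spans.add(EntitySpan(p2w[sp.start], p2w[sp.end], ex.entity_type))
    return out


# --- line-delimited structured-text serialization ---

def write_encoded(examples: Iterable[EncodedExample]) -> Iterator[str]:
    for ex in examples:
        yield json.dumps(
            {
                "pieces": list(ex.pieces),
                "start_labels": ex.start_labels.tolist(),
                "end_labels": ex.end_labels.tolist(),
                "context_mask": ex.context_mask.astype(int).tolist(),
                "word_map": {str(k): list(v) for k, v in ex.word_map.items()},
                "sentence_id": ex.sentence_id,
                "entity_type": ex.entity_type,
                "answers": sorted([s.start, s.end, s.label] for s in ex.answers),
                "window_index": ex.window_index,
                "n_windows": ex.n_windows,
            }
        )


def read_encoded(stream: Iterable[str]) -> list[EncodedExample]:
    out = []
    for line in stream:
        if not line.strip():
            continue
        rec = json.loads(line)
        out.append(
            EncodedExample(
                pieces=tuple(rec["pieces"]),
                start_labels=np.asarray(rec["start_labels"], dtype=np.int8),
                end_labels=np.asarray(rec["end_labels"], dtype=np.int8),
                context_mask=np.asarray(rec["context_mask"], dtype=bool),
                word_map={int(k): tuple(v) for k, v in rec["word_map"].items()},
                sentence_id=rec["sentence_id"],
                entity_type=rec["entity_type"],
                answers=frozenset(
                    EntitySpan(s, e, lab) for s, e, lab in rec["answers"]
                ),
                window_index=rec["window_index"],
                n_windows=rec["n_windows"],
            )
        )
    return out
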