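"""Reading, writing and validating BIO/CoNLL-style tagged corpora.

The word-level data model is 0-based with end-inclusive spans.  BIO is the
only supported tagging scheme; nested or overlapping spans cannot be
serialized to a single tag sequence and raise :class:`RepresentationError`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

_DOCSTART = "-DOCSTART-"


class ConllParseError(ValueError):
    """Malformed CoNLL input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class RepresentationError(ValueError):
    """Span set cannot be represented in the requested encoding (BIO)."""


@dataclass(frozen=True)
class EntitySpan:
    """A typed entity occupying words ``start..end`` (inclusive)."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid span bounds ({self.start}, {self.end})")
        if not self.label:
            raise ValueError("span label must be non-empty")

    def contains(self, other: "EntitySpan") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[str, ...]
    sentence_id: str

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError(f"sentence {self.sentence_id!r} has no tokens")
        if any(t == "" for t in self.tokens):
            raise ValueError(f"sentence {self.sentence_id!r} contains an empty token")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class LabeledCorpus:
    """Sentences plus per-sentence typed span annotations.

    ``annotations[i]`` holds the spans of ``sentences[i]``; ``label_set`` is
    the union of observed labels plus any declared-but-unseen types.
    """

    sentences: list[Sentence]
    annotations: list[set[EntitySpan]]
    label_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sentences) != len(self.annotations):
            raise ValueError("sentences and annotations length mismatch")
        declared = set(self.label_set)
        for sent, spans in zip(self.sentences, self.annotations):
            for sp in spans:
                if sp.end >= len(sent):
                    raise ValueError(
                        f"span {sp} exceeds sentence {sent.sentence_id!r} "
                        f"of length {len(sent)}"
                    )
                if sp.label not in declared:
                    raise ValueError(
                        f"span label {sp.label!r} not in label_set {self.label_set}"
                    )

    def __len__(self) -> int:
        return len(self.sentences)

    def iter_items(self) -> Iterator[tuple[Sentence, set[EntitySpan]]]:
        return iter(zip(self.sentences, self.annotations))


@dataclass(frozen=True)
class TagSequence:
    tags: tuple[str, ...]
    scheme: str = "BIO"

    def __post_init__(self) -> None:
        if self.scheme != "BIO":
            raise ValueError(f"unsupported scheme {self.scheme!r}")
        for t in self.tags:
            if t != "O" and not (t.startswith("B-") or t.startswith("I-")):
                raise ValueError(f"malformed BIO tag {t!r}")


def bio_to_spans(tags: TagSequence | Sequence[str], *, strict: bool = False) -> set[EntitySpan]:
    """Convert a BIO tag sequence to its span set.

    Maximal runs ``B-X (I-X)*`` become one span.  An orphan ``I-X`` (no
    preceding ``B-X``/``I-X`` of the same label) is leniently repaired as a
    span start; with ``strict=True`` it raises instead.
    """
    if isinstance(tags, TagSequence):
        tags = tags.tags
    spans: set[EntitySpan] = set()
    start: int | None = None
    label: str | None = None

    def flush(end: int) -> None:
        nonlocal start, label
        if start is not None:
            spans.add(EntitySpan(start, end, label))
            start, label = None, None

    for i, tag in enumerate(tags):
        if tag == "O":
            flush(i - 1)
        elif tag.startswith("B-"):
            flush(i - 1)
            start, label = i, tag[2:]
        elif tag.startswith("I-"):
            if label == tag[2:]:
                continue
            if strict:
                raise ValueError(f"orphan {tag!r} at position {i}")
            logger.warning("orphan %r at position %d repaired as span start", tag, i)
            flush(i - 1)
            start, label = i, tag[2:]
        else:
            raise ValueError(f"malformed BIO tag {tag!r} at position {i}")
    flush(len(tags) - 1)
    return spans


def spans_to_bio(spans: Iterable[EntitySpan], length: int) -> TagSequence:
    """Inverse of :func:`bio_to_spans` for flat (non-overlapping) span sets."""
    spans = sorted(spans, key=lambda s: (s.start, s.end))
    for a, b in zip(spans, spans[1:]):
        if a.overlaps(b):
            raise RepresentationError(
                f"spans {a} and {b} overlap; BIO cannot represent nesting"
            )
    tags = ["O"] * length
    for sp in spans:
        if sp.end >= length:
            raise ValueError(f"span {sp} exceeds length {length}")
        tags[sp.start] = f"B-{sp.label}"
        for i in range(sp.start + 1, sp.end + 1):
            tags[i] = f"I-{sp.label}"
    return TagSequence(tuple(tags))


def read_conll(
    stream: Iterable[str],
    declared_labels: Iterable[str] | None = None,
    *,
    strict_bio: bool = False,
) -> LabeledCorpus:
    """Parse two-column "token tag" lines into a :class:`LabeledCorpus`.

    Sentences are separated by blank lines; the separator is any run of
    whitespace (last field is the tag).  ``-DOCSTART-`` rows are skipped.
    """
    sentences: list[Sentence] = []
    annotations: list[set[EntitySpan]] = []
    tokens: list[str] = []
    tags: list[str] = []
    seen_labels: list[str] = []

    def flush() -> None:
        if not tokens:
            return
        sent = Sentence(tuple(tokens), sentence_id=f"s{len(sentences)}")
        spans = bio_to_spans(tags, strict=strict_bio)
        for sp in spans:
            if sp.label not in seen_labels:
                seen_labels.append(sp.label)
        sentences.append(sent)
        annotations.append(spans)
        tokens.clear()
        tags.clear()

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            flush()
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ConllParseError(
                f"expected 'token tag', got {line.strip()!r}", lineno
            )
        token, tag = fields[0], fields[-1]
        if token == _DOCSTART:
            continue
        if tag != "O" and not (tag.startswith("B-") or tag.startswith("I-")):
            raise ConllParseError(f"unknown tag scheme prefix in {tag!r}", lineno)
        tokens.append(token)
        tags.append(tag)
    flush()

    labels = list(seen_labels)
    if declared_labels is not None:
        for lab in declared_labels:
            if lab not in labels:
                labels.append(lab)
    return LabeledCorpus(sentences, annotations, tuple(labels))


def write_conll(corpus: LabeledCorpus) -> Iterator[str]:
    """Emit "token tag" lines with blank-line sentence breaks.

    Raises :class:`RepresentationError` for sentences with nested or
    overlapping spans (BIO cannot hold them; use the span file format).
    """
    for sent, spans in corpus.iter_items():
        try:
            tagseq = spans_to_bio(spans, len(sent))
        except RepresentationError as exc:
            raise RepresentationError(
                f"sentence {sent.sentence_id!r}: {exc}"
            ) from exc
        for token, tag in zip(sent.tokens, tagseq.tags):
            yield f"{token}\t{tag}"
        yield ""


def corpus_stats(corpus: LabeledCorpus) -> dict:
    """Exact sentence/annotation counts plus a per-label breakdown."""
    per_label: dict[str, int] = {lab: 0 for lab in corpus.label_set}
    total = 0
    for spans in corpus.annotations:
        for sp in spans:
            per_label[sp.label] += 1
            total += 1
    return {
        "sentences": len(corpus.sentences),
        "annotations": total,
        "entity_types": len(corpus.label_set),
        "per_label": per_label,
    }


def format_stats(stats: dict) -> str:
    """Tab-separated summary (annotation / sentence / entity-type counts)."""
    lines = ["metric\tvalue"]
    lines.append(f"Annotation\t{stats['annotations']}")
    lines.append(f"Sentences\t{stats['sentences']}")
    lines.append(f"Entity types\t{stats['entity_types']}")
    for lab, n in stats["per_label"].items():
        lines.append(f"label:{lab}\t{n}")
    return "\n".join(lines)


# --- span file: line-delimited JSON, holds nested corpora BIO cannot ---

def write_span_file(corpus: LabeledCorpus) -> Iterator[str]:
    import json

    yield json.dumps({"label_set": list(corpus.label_set)})
    for sent, spans in corpus.iter_items():
        rec = {
            "sentence_id": sent.sentence_id,
            "tokens": list(sent.tokens),
            "spans": sorted([s.start, s.end, s.label] for s in spans),
        }
        yield json.dumps(rec)


def read_span_file(stream: Iterable[str]) -> LabeledCorpus:
    import json

    lines = [ln for ln in stream if ln.strip()]
    if not lines:
        return LabeledCorpus([], [], ())
    header = json.loads(lines[0])
    sentences: list[Sentence] = []
    annotations: list[set[EntitySpan]] = []
    for ln in lines[1:]:
        rec = json.loads(ln)
        sentences.append(Sentence(tuple(rec["tokens"]), rec["sentence_id"]))
        annotations.append({EntitySpan(s, e, lab) for s, e, lab in rec["spans"]})
    return LabeledCorpus(sentences, annotations, tuple(header["label_set"]))
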