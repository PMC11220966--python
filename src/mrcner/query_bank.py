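"""Natural-language query construction and management, one query per entity type.

Six construction strategies are supported: ``keywords``, ``template``,
``wikipedia`` (locally supplied definition text), ``synonyms``,
``keywords_synonyms`` and ``guideline``.  Query sets are plain-text (YAML)
configuration, never scraped from the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import yaml

from .corpus_io import LabeledCorpus

STRATEGIES = (
    "keywords",
    "template",
    "wikipedia",
    "synonyms",
    "keywords_synonyms",
    "guideline",
)

TEMPLATE_SLOT = "<kw>"


class QuerySetError(ValueError):
    pass


@dataclass(frozen=True)
class QuerySpec:
    entity_type: str
    strategy: str
    text: str

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if not self.text:
            raise ValueError(f"empty query text for {self.entity_type!r}")


@dataclass
class QuerySet:
    specs: dict[str, QuerySpec]  # label -> spec, insertion-ordered
    name: str = "default"

    def __post_init__(self) -> None:
        for label, spec in self.specs.items():
            if spec.entity_type != label:
                raise QuerySetError(
                    f"key {label!r} does not match spec entity_type {spec.entity_type!r}"
                )

    def __len__(self) -> int:
        return len(self.specs)

    def __getitem__(self, label: str) -> QuerySpec:
        return self.specs[label]

    def labels(self) -> tuple[str, ...]:
        return tuple(self.specs)


def _as_text(value) -> str:
    if isinstance(value, str):
        return value
    return ", ".join(value)


def build_query(entity_type: str, strategy: str, lexicon: Mapping) -> QuerySpec:
    """Assemble a query deterministically from per-strategy raw material.

    ``lexicon`` keys used per strategy: ``keywords`` (string or list),
    ``template`` (string containing the ``<kw>`` slot), ``wikipedia``
    (definition text), ``synonyms`` (string or list), ``guideline`` (text,
    returned verbatim).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")

    def require(key: str) -> str:
        value = lexicon.get(key)
        text = _as_text(value) if value is not None else ""
        if not text:
            raise QuerySetError(
                f"lexicon entry {key!r} missing or empty for label {entity_type!r}"
            )
        return text

    if strategy == "keywords":
        text = require("keywords")
    elif strategy == "template":
        template = require("template")
        if TEMPLATE_SLOT not in template:
            raise QuerySetError(f"template for {entity_type!r} lacks slot {TEMPLATE_SLOT!r}")
        text = template.replace(TEMPLATE_SLOT, require("keywords"))
    elif strategy == "wikipedia":
        text = require("wikipedia")
    elif strategy == "synonyms":
        text = require("synonyms")
    elif strategy == "keywords_synonyms":
        text = require("keywords") + ", " + require("synonyms")
    else:  # guideline: verbatim
        text = require("guideline")
    return QuerySpec(entity_type, strategy, text)


def load_query_set(
    stream, expected_labels: Iterable[str] | None = None, name: str = "default"
) -> QuerySet:
    """Load a label -> {strategy, text} mapping from YAML text.

    Accepted layouts::

        MAT: {strategy: guideline, text: "..."}
        PRO: "plain text"            # strategy defaults to guideline

    Duplicate labels are a conflict error; with ``expected_labels`` given,
    missing labels are a completeness error.
    """
    raw = yaml.safe_load(stream if isinstance(stream, str) else stream.read())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise QuerySetError("query-set config must be a mapping of label -> query")
    if "queries" in raw:  # optional wrapper with a name
        name = raw.get("name", name)
        raw = raw["queries"]

    specs: dict[str, QuerySpec] = {}
    for label, value in raw.items():
        label = str(label)
        if label in specs:
            raise QuerySetError(f"duplicate query for label {label!r}")
        if isinstance(value, str):
            specs[label] = QuerySpec(label, "guideline", value)
        else:
            specs[label] = QuerySpec(
                label, value.get("strategy", "guideline"), value.get("text", "")
            )
    if expected_labels is not None:
        missing = [lab for lab in expected_labels if lab not in specs]
        if missing:
            raise QuerySetError(f"query set incomplete; missing labels: {missing}")
    return QuerySet(specs, name=name)


def dump_query_set(qs: QuerySet) -> str:
    payload = {
        "name": qs.name,
        "queries": {
            lab: {"strategy": sp.strategy, "text": sp.text}
            for lab, sp in qs.specs.items()
        },
    }
    return yaml.safe_dump(payload, sort_keys=False, allow_unicode=True)


def validate_query_set(qs: QuerySet, corpus: LabeledCorpus) -> dict:
    """Report-only bijection check between query labels and corpus labels."""
    corpus_labels = set(corpus.label_set)
    query_labels = set(qs.labels())
    missing = sorted(corpus_labels - query_labels)
    extra = sorted(query_labels - corpus_labels)
    return {"ok": not missing and not extra, "missing": missing, "extra": extra}


# ---------------------------------------------------------------------------
# Shipped defaults
# ---------------------------------------------------------------------------

#: Annotation-guideline queries for the seven materials-science entity types
#: of the Matscholar-style label inventory.
MATSCHOLAR_GUIDELINE_QUERIES: dict[str, str] = {
    "MAT": "Any inorganic solid or alloy, any non-gaseous element",
    "SPL": "Names for crystal structures/phases",
    "DSC": "Special descriptions of the type/shape of the sample",
    "PRO": "Anything measurable that can have a unit and a value",
    "APL": (
        "Any high-level application such as photovoltaics, or any specific "
        "device such as field-effect transistor"
    ),
    "CMT": "Any method used to characterize a material",
    "SMT": "Any technique for synthesizing a material",
}

#: Strategy-variant material for the MAT label, one entry per strategy.
MAT_STRATEGY_LEXICON: dict[str, object] = {
    "keywords": "inorganic material",
    "template": f"Which {TEMPLATE_SLOT} is mentioned in the text?",
    "wikipedia": (
        "Materials made from inorganic substances alone or in combination "
        "with other substances"
    ),
    "synonyms": "Inorganic material",
    "guideline": "Look up any inorganic solids or alloys, any non-gaseous elements.",
}

#: Single-label guideline query for chemical-NER-shaped corpora.
CHEMICAL_GUIDELINE_QUERIES: dict[str, str] = {
    "CHEM": "Any chemical compound, drug, element or chemical substance mention",
}


def default_query_set(name: str) -> QuerySet:
    """Shipped query sets: ``matscholar-guideline`` and ``chemical-guideline``."""
    banks = {
        "matscholar-guideline": MATSCHOLAR_GUIDELINE_QUERIES,
        "chemical-guideline": CHEMICAL_GUIDELINE_QUERIES,
    }
    if name not in banks:
        raise KeyError(f"unknown query set {name!r}; available: {sorted(banks)}")
    specs = {
        lab: QuerySpec(lab, "guideline", text) for lab, text in banks[name].items()
    }
    return QuerySet(specs, name=name)


def synthetic_lexicon(entity_type: str) -> dict[str, object]:
    """Per-strategy raw material for synthetic corpus labels."""
    kw = f"{entity_type.lower()} entity"
    return {
        "keywords": kw,
        "template": f"Which {TEMPLATE_SLOT} is mentioned in the text?",
        "wikipedia": f"A token of the {entity_type} vocabulary appearing in context",
        "synonyms": f"{entity_type.lower()} mention",
        "guideline": f"Look up any span of {entity_type} vocabulary words.",
    }


def build_query_set(
    labels: Iterable[str],
    strategy: str,
    lexicons: Mapping[str, Mapping] | None = None,
    name: str | None = None,
) -> QuerySet:
    """Build one query per label under a single strategy.

    Without explicit ``lexicons`` the synthetic lexicon is used, which keeps
    ablation runs over strategies self-contained.
    """
    specs = {}
    for lab in labels:
        lex = lexicons[lab] if lexicons is not None else synthetic_lexicon(lab)
        specs[lab] = build_query(lab, strategy, lex)
    return QuerySet(specs, name=name or strategy)
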