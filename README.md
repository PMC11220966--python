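# mrcner

Query-based span-extraction named entity recognition, in pure scientific
Python (numpy). Token-tagged NER corpora (two-column CoNLL/BIO files) are
recast as (context, query, answer) triples — one natural-language query per
entity type — and entity spans are extracted by paired start/end binary
classifiers over an encoder representation. Because each entity type is
queried independently and every position can be a start and/or an end, the
framework handles nested entities that single-sequence BIO tagging cannot
represent.

## What is here

| module | role |
| --- | --- |
| `mrcner.corpus_io` | CoNLL/BIO reading and writing, BIO ↔ span conversion, corpus statistics, a JSON-lines span format for nested corpora |
| `mrcner.query_bank` | per-type query construction under six strategies (keywords, template, wikipedia definition, synonyms, keywords+synonyms, annotation guideline), YAML query-set configs, shipped default sets |
| `mrcner.mrc_dataset` | sentence × type triple construction, `[CLS] query [SEP] context [SEP]` encoding with binary start/end label vectors, sliding windows for long contexts, decoding back to word space |
| `mrcner.span_model` | start/end softmax heads (conditioned and base end-head variants), index-set extraction by row argmax, nearest-preceding-start span matching, the trainable tiny encoder and a pretrained-transformer plug-in contract |
| `mrcner.training` | focal / cross-entropy / label-smoothing losses with analytic gradients, AdamW fine-tuning loop with warmup and dev-based model selection, corpus-level inference, checkpoints |
| `mrcner.evaluation` | entity-level exact-match precision/recall/F1 (micro + per label), mean ± std / max aggregation over repeated runs |
| `mrcner.synthetic_data` | seeded corpus generator with disjoint per-type vocabularies (lexically separable, so a capable model can reach F1 = 1.0), optional nested entities, and a fixed nested fixture |
| `mrcner.cli` | `mrcner` command-line tool and experiment drivers |

Training is implemented with hand-derived gradients in numpy — no deep
learning framework is required. Pretrained transformer encoders can be
plugged in for feature extraction when `torch`/`transformers` are installed,
but all tests and experiments run on the self-contained tiny encoder.

## Command-line usage

```bash
# make a synthetic corpus (CoNLL when flat, span file when nested)
mrcner gen-synth --out corpus.conll --n-sentences 200 --seed 7

# inspect it
mrcner stats --corpus corpus.conll

# convert to encoded (context, query, answer) examples
mrcner convert --corpus corpus.conll --out encoded.jsonl --max-len 128

# full experiment from a YAML config: train N seeded runs, score, aggregate
mrcner train --config experiment.yaml --runs 3 --seed 7

# ablations (identical seeds across variants)
mrcner compare-losses  --config experiment.yaml --losses focal,cross_entropy
mrcner compare-queries --config experiment.yaml --strategies keywords,guideline

# inference and scoring
mrcner predict --checkpoint out/checkpoint_run0.npz --corpus corpus.conll --out pred.jsonl
mrcner evaluate --pred pred.jsonl --gold gold.jsonl
```

A minimal `experiment.yaml` for a synthetic run:

```yaml
out_dir: out
synthetic:
  n_sentences: 300
  seed: 7
strategy: guideline
train:
  learning_rate: 0.01   # tiny encoder trains from scratch; pretrained
  epochs: 15            # fine-tuning would use the 2e-5 default instead
  runs: 3
  focal_alpha: 0.75
```

For a real corpus replace `synthetic:` with `train_path` / `dev_path` /
`test_path` (CoNLL or span files) and point `query_path` at a YAML mapping
of `label -> {strategy, text}` (see `mrcner.query_bank.dump_query_set`).
Every experiment writes a `manifest.json`; `mrcner.cli.replay_manifest`
re-runs it bit-identically.

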