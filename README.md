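# layerlm

Token-aligned multi-layer language-model retrieval. Documents are stored
as a base token sequence plus any number of *artifact layers* (concepts,
lemmas, POS tags, ...) and *relation layers* (e.g. dependency arcs), all
aligned to the base layer by token spans. Queries can mix layers freely
and are scored with Dirichlet-smoothed query likelihood:

- **term queries** on any layer (`hiv`, `cui:C0019196`),
- **list queries** `#l(cui:C0019158|hepatitis)` — members scored
  individually, or acting as a disjunctive matcher inside a phrase,
- **cross-layer phrase queries** `#p(window|ordered|c1|c2|...)` with
  ordered/unordered window semantics measured on base-layer positions,
- **relation queries** `#r(dep|lemma:give|pos:NNP)` matching labeled
  span-to-span relations whose endpoints overlap artifacts of interest,
- sequential-dependence (MRF) expansion `#p(8|true|a|b)^0.1 ...` with
  configurable weights (0.85 / 0.1 / 0.05) and window schedule (4 tokens
  per component, phrases capped at 5 components),
- ranked retrieval and MAP evaluation over TREC-style topic/qrels/run
  files.

A synthetic-corpus generator produces layered documents with
clinical-NLP-like structure (dictionary-tagged multi-word concepts with
CUI/TUI layers, 1:1 lemma/POS layers, random dependency trees) together
with topics and ground-truth qrels, so the whole pipeline is testable
without any restricted clinical collection.

## CLI

```sh
# generate a corpus with topics and judgments
layerlm simulate --seed 42 --n-docs 100 --out-docs docs.jsonl \
    --out-topics topics.tsv --out-qrels qrels.txt

# build the per-layer positional index (JSON, versioned)
layerlm index --input docs.jsonl --output index.json

# inspect a query / its SDM expansion
layerlm expand --query "cui:C0019196 cui:C0019158" --sdm

# rank and evaluate
layerlm search --index index.json --topics topics.tsv --sdm \
    --mu 2000 --k 1000 --output run.txt
layerlm eval --run run.txt --qrels qrels.txt --per-topic

# or end-to-end from one YAML config
layerlm experiment --config experiment.yaml --formulation TXT-MRF
```

The experiment YAML mirrors `layerlm.cli.RunConfig`: paths for
`docs_path` / `topics_path` / `qrels_path` / `run_path`, a `formulation`
(`TXT`/`CUI`/`MIX`/`CUI-LS`/`PH-LS` × `BOW`/`MRF`; `-MRF` applies
sequential-dependence expansion), `mu`, `k`, and `seed`. Topic files
supply the pre-rewritten query string per topic for the chosen
formulation.

## Data formats

- **Documents**: JSONL, one document per line —
  `{"doc_id": ..., "tokens": [...], "layers": {name: [[value, start,
  length], ...]}, "relations": {name: [[label, src_start, src_len,
  tgt_start, tgt_len], ...]}}`. Spans are 0-based start + length in
  base-layer tokens, end-exclusive.
- **Topics**: TSV `topic_id<TAB>query text`.
- **Qrels / runs**: standard TREC formats.

## Layout

- `src/layerlm/layer_model.py` — spans, artifacts, documents, validation
- `src/layerlm/annotation_io.py` — tokenizer, JSONL / TREC file I/O
- `src/layerlm/indexing.py` — per-layer positional indexes + statistics
- `src/layerlm/query_language.py` — AST, parser, renderer, SDM expansion
- `src/layerlm/scoring_engine.py` — Dirichlet term/list/phrase/relation
  scoring and ranking
- `src/layerlm/evaluation.py` — average precision and MAP
- `src/layerlm/synthetic_data.py` — corpus / topic / qrels generator
- `src/layerlm/cli.py` — subcommands and the experiment driver
- `tests/oracle.py` — independent brute-force reference used to verify
  every count, probability, score, and MAP value produced by the engine
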