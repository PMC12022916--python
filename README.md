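# rxnsplits

Out-of-distribution evaluation for reaction product predictors: benchmark
split construction, strict and relaxed top-k accuracy metrics, iterated
prediction, and fingerprint-based distribution-shift diagnostics — plus a
synthetic literature-structured corpus generator and a template-retrieval
baseline so the whole battery runs end to end without proprietary data.

## The problem

Reaction predictors are usually scored on random train/test partitions of a
literature-derived corpus. But literature corpora are not i.i.d.: a patent
reports a *substrate-scope series* of near-duplicate reactions, author
teams reuse chemistry across documents, reaction classes rise and fall over
the years, and new classes are discovered and adopted. A random split puts
siblings of every test reaction into training, so measured accuracy says
little about the real deployment question — *will the model work on new
chemistry?* `rxnsplits` is for people who build or evaluate reaction
predictors and want their held-out sets to actually be held out.

It provides, over any corpus of reaction SMILES with document / author /
year / class metadata:

- **Splits with hard leakage guarantees** — record-level (random),
  document-level, author-component, time-cutoff series with per-year test
  sets and exact training-size control, class hold-outs with a paired
  limited-exposure baseline, sibling-class ablations, and prospective
  named-reaction test sets. An independent `audit_split` re-verifies every
  invariant (no shared canonical reaction key across sides, no straddling
  document or author, year bounds, size control, class exclusions).
- **Top-k accuracy** under a strict ⇒ stereo-agnostic ⇒ formula-level
  relaxation chain on canonical SMILES, with per-record match ranks, and
  multi-round **iterated prediction** (feed the top-1 product back in).
- **Shift diagnostics**: for each test reaction, the mean cosine distance
  to its 5 nearest training reactions in reactant-fingerprint space
  (substrate novelty) or difference-fingerprint space (transform novelty),
  using counted Morgan fingerprints (radius 2, 2048 bits).
- **A synthetic corpus generator** that emulates the generative structure
  above — labs with chemical styles, scope series, popularity drift, class
  discovery years — and **a retrieval baseline** that can only replay
  transforms it saw in training, so every OOD failure mode is demonstrable
  on a laptop.

## Worked example

```python
import rxnsplits.experiments as ex

corpus = ex.benchmark_corpus(seed=1)          # ~5,000 reactions, 600 documents
print(len(corpus), "reactions,", len(corpus.by_doc), "documents")

trend = ex.split_family_trend(corpus, seed=1)  # retrieval baseline, 5 split seeds
for name in ("random", "document", "author"):
    print(f"{name:9s} top-1 {100*trend[name][1]:5.1f}%  top-5 {100*trend[name][5]:5.1f}%")

shift = ex.shift_trend(corpus, seed=1)
print("reactant-space median NN distance:",
      {k: round(v, 3) for k, v in shift["reactant"].items()})
```

prints

```
4575 reactions, 598 documents
random    top-1  96.2%  top-5 100.0%
document  top-1  87.5%  top-5 100.0%
author    top-1  75.3%  top-5 100.0%
reactant-space median NN distance: {'random': 0.046, 'author': 0.113}
```

Read: the *same* predictor on the *same* corpus looks 21 points better
under a random split than under an author split, and the author-split test
set sits more than twice as far from training in fingerprint space — the
random number is the mirage, the gap is the finding. The same battery
shows accuracy decaying on test years past a training cutoff, a held-out
reaction class dropping to 0% against 100% for a baseline that saw 150
in-class examples, and two-round iterated prediction recovering
double-addition products (0% → 100%) from a library that only knows the
single-addition steps.

The same workflow is available from the shell:

```bash
rxnsplits synth --config configs/default.yaml --out corpus.jsonl
rxnsplits split --corpus corpus.jsonl --strategy author --test-fraction 0.2 --seed 1 --out split.json
rxnsplits audit --corpus corpus.jsonl split.json
rxnsplits baseline predict --corpus corpus.jsonl --split split.json --k 5 --out preds.jsonl
rxnsplits eval --corpus corpus.jsonl --split split.json --predictions preds.jsonl --ks 1,3,5
rxnsplits shift --corpus corpus.jsonl --split split.json --space reaction --m 5
```

Corpora are CSV/TSV/JSONL with columns `rxn_smiles` (`reactants>agents>products`),
`doc_id`, `authors` (`;`-separated), `year`, `class_code`, and optional
`transform`.

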