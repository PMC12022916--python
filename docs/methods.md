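# Methods

`rxnsplits` measures how reaction-product predictors behave when the test
distribution differs from training. It does not train predictive models; it
constructs the out-of-distribution (OOD) evaluations themselves — splits,
metrics, and diagnostics — and ships a deliberately simple retrieval
baseline plus a synthetic corpus generator so the whole battery runs end to
end without proprietary reaction data.

## Data model and canonicalization

A reaction record holds the reaction SMILES parts (reactants, agents,
products) and the "hidden" literature metadata splits key on: document id,
author list, publication year, and a hierarchical reaction-class code
(`a.b.c`, with `0.0` meaning uncategorized). Class matching is by code
prefix on `.` boundaries (`3.1` matches `3.1.2`, not `3.10.2`).

Every record derives a canonical key: each molecule is canonicalized with
RDKit's canonical SMILES, molecules within a part are sorted
lexicographically, and the parts are joined as `R>A>P`. The key is invariant
to molecule ordering and SMILES dialect, and idempotent. Agents participate
in the key: two reactions that differ only in conditions are treated as
distinct, since conditions can change the product. The canonicalizer
identity is recorded in corpus metadata so mixed-canonicalization corpora
are detectable.

Deduplication keeps one record per canonical key — the earliest year, then
the lexicographically smallest document id, then record id. The earliest
report is the natural "first disclosure" for time-based splits.

## Split families and leakage guarantees

* **Reaction (random) split** — uniform over records; the in-distribution
  reference.
* **Document split** — whole documents assigned to one side. Group
  assignment shuffles groups by seed and adds a group to the test side only
  when that moves the realized test count strictly closer to the target,
  stopping at the target; this keeps the realized fraction the closest
  achievable in one greedy pass while remaining deterministic.
* **Author split** — connected components of the author–document
  co-occurrence graph are assigned wholesale, so no author *and* no
  document straddles the partition. Author identity is exact string match
  of author names (no disambiguation data exists in the corpus; a known
  limitation). A corpus whose graph is one giant component cannot be
  author-split; the error reports component sizes.
* **Time-split series** — per-year held-out test sets are sampled first;
  each cutoff's training set is then drawn from records with year ≤ cutoff,
  excluding all test records, and optionally subsampled to an exact
  training size so accuracy differences across cutoffs reflect recency
  rather than volume. Size-controlled sets are sampled independently per
  cutoff (not nested), keeping each uniform over its pool.
* **Class hold-out** — all records of a class (by code prefix) are removed
  from training; a paired "intrinsic difficulty" baseline instead moves a
  fixed number of class records into training. Both variants share an
  identical class test set, and an in-distribution context test set from
  the remaining classes is carried along. Uncategorized (`0.0`) records
  are dropped by default. Ablation variants build three nested training
  sets against one subclass test set: everything, siblings-only (subclass
  removed), and whole-parent-class removed.
* **Named-reaction prospective test set** — all records of a class that
  appear in no training set of a time-split series.

Every construction is re-verified by an independent auditor that rescans
the corpus: record- and canonical-key-level train/test disjointness,
document/author integrity, year bounds, exact size control, and class
exclusion counts. The auditors share no code with the splitters beyond the
corpus indexes.

## Matching policies and top-k accuracy

A prediction is correct when the recorded product multiset appears among
the k highest-ranked candidates, compared on canonical SMILES. Three
policies form a relaxation chain (strict ⇒ stereo-agnostic ⇒
formula-level, so accuracies are ordered at every k):

* **strict** — canonical product multisets identical;
* **stereo-agnostic** — identical after removing all tetrahedral and
  double-bond stereochemistry from both sides (only products are compared,
  so only product stereochemistry is stripped);
* **formula-level** — equal multisets of molecular formulas. This accepts
  all constitutional isomers, deliberately slightly broader than a
  regioisomer-only rule, because "same connectivity except attachment
  position" has no crisp general definition; the over-relaxation is the
  documented trade.

Candidates that collide after policy normalization are collapsed keeping
the best rank before the k cutoff, so beam-style outputs that merge under
stereo stripping neither waste nor inflate slots. Records with no
prediction list count as misses. An unparseable candidate is a miss; an
unparseable ground truth is a hard error.

Ranking depth defaults to 5 (top-1/3/5 reports), matching the beam width
customary for sequence-based product predictors.

## Iterated prediction

Multi-step transformations can be reachable by composing single steps even
when the composite transform was never seen. `iterate_predict` feeds the
top-1 product of round r−1 back as a reactant for round r under a carry
rule. The default, `replace_largest`, substitutes the previous product for
the heavy-atom-largest reactant and keeps everything else — the transformed
substrate is typically the largest species, and reagents (e.g. a second
organometallic equivalent) must survive to the next round. The rule is
configurable (`product_only` feeds the bare product) because the right
choice is substrate-dependent.

## Distribution-shift diagnostics

For each test record we report the mean cosine distance to its m nearest
training records (m = 5) in one of two spaces: the summed hashed circular
(Morgan) count fingerprint of the reactants (substrate novelty), or the
difference fingerprint, products minus reactants (transform novelty).
Defaults are radius 2, width 2048, counted rather than binary — the
community default for both uses — and agents are excluded so that
solvent/catalyst encoding does not masquerade as chemistry; both are
configurable. Neighbor search is exact, computed in blocks to bound
memory; ties are broken by a stable sort on (distance, training record
id). Cosine distance on the nonnegative reactant vectors lies in [0, 1];
on signed difference vectors it can reach 2, and a zero difference vector
(a null transform) is assigned distance 1 to any nonzero vector by the
underlying convention of treating zero norms as unit norms.

## Synthetic corpus generator

The generator emulates the structure of patent-derived reaction corpora
rather than their chemistry:

* **Documents and authors.** 600 documents over 1998–2022 by default,
  written by a pool of 240 recurring authors organized into 40 labs with
  rare (1%) cross-lab collaborations, so the co-authorship graph has many
  nontrivial components. Teams of 2–4 are drawn within a lab.
* **Lab style.** Each lab has a favorite reaction class, favorite
  decoration subsets, a preferred scaffold core per substrate family, and
  house partner reagents reused across its documents. These stable
  signatures are what make author-component splits genuinely OOD while
  document splits still find same-lab support in training.
* **Scope series.** A document applies (mostly) one transform to one
  scaffold whose scope site is scanned through a no-repeat decoration
  sequence; a second decoration site and the partner substrate are fixed
  per document. Intra-document reactions are therefore near-duplicates in
  fingerprint space — the leakage that makes random splits overoptimistic.
* **Transforms.** Ten toy reaction-SMARTS templates across three top-level
  classes: N-alkylation, ether formation, amide coupling, esterification,
  two sibling aryl couplings differing only in the leaving group
  (bromide/chloride), an aryl amination, and a single/double
  organomagnesium-addition pair whose composition property (single
  addition applied twice equals the double addition) backs the iterated-
  prediction experiments.
* **Chemoselectivity challenges.** Several substrate families are
  deliberately polyfunctional (aryl bromides carry a ring chloride, amines
  a free alcohol, alcohols a free amine, esters an aryl ketone), and some
  scope decorations are themselves reactive. On such substrates several
  transforms apply and the predictor must rank them; possession of the
  right template alone is not enough. Competing sibling classes are
  configured with comparable integrated popularity so that this ranking is
  decided by training-set similarity rather than by raw class frequency.
* **Popularity drift and discovery.** Class popularity interpolates
  linearly across the year range; classes can be unavailable before an
  introduction year. Defaults include a late-introduced class (2015) for
  discovery-style experiments. The scope-varied substituent is placed
  ortho to the reacting group so difference fingerprints retain local
  substrate context instead of collapsing to one point per class.
* 2% of records get the uncategorized label `0.0` (the planted generative
  class remains available via `planted_truth`). Corpora are deduplicated
  on return and satisfy every corpus invariant as generated.

What the generator does **not** emulate: real substrate diversity (a few
hundred scaffold/decoration combinations versus millions of molecules),
yields and conditions, atom-mapping noise, misclassified reactions, or
realistic class frequency profiles. Passing trends on these corpora
demonstrate that the splitters, metrics, and diagnostics measure what they
claim under a literature-shaped generative process — not that any
particular real-world predictor will show the same gaps.

## Retrieval baseline

The baseline collects the distinct transform strings in a training split
(planted by the generator; real corpora would need user-supplied
templates), stores each template's supporting reactant fingerprints, and at
query time applies every applicable template, scoring candidate product
sets by `max cosine similarity to the template's support × log(1 + support
count)`, with ties broken by the canonical product string. It cannot emit a
transform it never saw — exactly the extrapolation failure mode under
study — and its similarity term is what links accuracy to training-set
proximity. Template induction from atom-mapping is intentionally out of
scope.

## Experiment battery and problem sizes

The shipped experiments (`rxnsplits.experiments`) run on desk-scale
corpora chosen to finish in minutes on one CPU while keeping every trend
statistically visible: a ~5,000-reaction / 600-document benchmark corpus
for the split-family, time, class-holdout, and shift experiments; 50
corpora of ~1,900 reactions each for the leakage-audit sweep; and a
~1,900-reaction three-class corpus for the iterated-prediction
demonstration. Split-level accuracies are averaged over five split seeds so
reported trends reflect the strategy rather than one draw; all seeds derive
from a single base seed. Time-split experiments use cutoffs 2006/2012/2018,
five test years, 120 test records per year, and size-controlled training
sets of 1,200; the class hold-out uses the chloro-coupling subclass with a
150-example baseline (the intrinsic-difficulty design scales the canonical
1000-example subset to a corpus two orders of magnitude smaller than a
patent corpus).

## Numerical and degenerate-input choices

Randomness flows through `numpy.random.default_rng` seeded per operation;
all derived seeds stay below 2³¹. Molecule canonicalization and fingerprint
computation are memoized (substrate pools are small relative to corpus
sizes). Group assignment, neighbor ties, duplicate candidate collapse, and
prediction-score ties all have documented deterministic tie-breaks. Empty
corpora, single-document corpora, single-component author graphs,
undersized test years, and oversized training-size requests raise explicit
errors naming the offending entity.

## Known limitations

* Author identity is exact string match; no disambiguation.
* The formula-level policy is broader than a strict regioisomer rule.
* The retrieval baseline reads planted transform labels; it measures
  generalization structure, not chemical plausibility.
* Difference-fingerprint distances depend on the fingerprint radius
  reaching decoration sites; transforms whose changed atoms are remote
  from all substituents collapse toward zero distance.
* Synthetic trends quantify the toolkit's discriminative power, not the
  absolute difficulty of any real corpus.
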