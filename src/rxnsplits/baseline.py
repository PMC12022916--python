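"""Template-retrieval baseline predictor.

A deliberately simple predictor that makes generalization structure visible
without any neural training: it collects the distinct transform templates
observed in a training split, remembers the reactant fingerprints of the
records that support each template, and at prediction time applies every
applicable template to the query reactants, ranking the resulting candidate
product sets by

    score = (max cosine similarity between the query reactant fingerprint
             and the template's support fingerprints) * log(1 + support count)

with deterministic ties broken by the canonical product string. Because the
library can only ever replay transforms seen in training, it exhibits —
honestly — the extrapolation failure mode that out-of-distribution splits
are designed to expose: a held-out reaction class is unpredictable, a new
class introduced after a time cutoff is unpredictable, and ambiguous
substrates are resolved by similarity to (possibly leaked) training
neighbors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Corpus
from .evaluation import PredictionSet
from .shift import FingerprintParams, _mol_counts
from .templates import TEMPLATES_BY_ID, TransformTemplate


def _reactants_fp(reactants: Sequence[str], params: FingerprintParams) -> np.ndarray:
    vec = np.zeros(params.width, dtype=np.float64)
    for s in reactants:
        vec += _mol_counts(s, params)
    return vec


@dataclass
class LibraryEntry:
    template: TransformTemplate
    support_count: int
    #: row-normalized reactant fingerprints of supporting training records
    support_unit: np.ndarray
    support_ids: tuple[str, ...] = ()


@dataclass
class TemplateLibrary:
    """The distinct transforms of a training split with their support."""

    entries: dict[str, LibraryEntry]
    params: FingerprintParams = field(default_factory=FingerprintParams)
    provenance: dict = field(default_factory=dict)

    @property
    def transform_ids(self) -> list[str]:
        return sorted(self.entries)

    def as_predictor(self):
        """Adapter to the predictor contract: (reactants, agents, k) -> ranked
        candidate product strings."""
        return lambda reactants, agents, k: predict(self, reactants, agents, k)

    def save(self, path: str | Path) -> None:
        out = {
            "provenance": self.provenance,
            "params": {
                "radius": self.params.radius,
                "width": self.params.width,
                "counted": self.params.counted,
            },
            "entries": {
                tid: {
                    "support_count": e.support_count,
                    "support_ids": list(e.support_ids),
                }
                for tid, e in self.entries.items()
            },
        }
        Path(path).write_text(json.dumps(out, indent=1))


def fit_library(
    corpus: Corpus,
    train_ids: Iterable[str],
    params: FingerprintParams = FingerprintParams(),
    templates: dict[str, TransformTemplate] | None = None,
) -> TemplateLibrary:
    """Build a template library from the training records.

    Every training record must carry a ``transform`` string naming a known
    template (synthetic corpora plant these; real corpora would need
    user-supplied templates via ``templates``). The library contains exactly
    the distinct transforms observed, each with the fingerprints of its
    supporting records — so a class held out of training is guaranteed
    absent from the library.
    """
    templates = templates or TEMPLATES_BY_ID
    train_ids = sorted(train_ids)
    by_transform: dict[str, list[str]] = {}
    for rid in train_ids:
        t = corpus[rid].transform
        if t is None:
            raise ValueError(
                f"record {rid!r} carries no transform string; the retrieval "
                "baseline needs synthetic corpora or explicit templates"
            )
        by_transform.setdefault(t, []).append(rid)
    if not by_transform:
        raise ValueError(
            "no training record carries a transform string; use a synthetic "
            "corpus or supply explicit template files"
        )
    entries = {}
    for tid, rids in by_transform.items():
        if tid not in templates:
            raise KeyError(f"transform {tid!r} has no registered template")
        mat = np.vstack(
            [_reactants_fp(corpus[r].reactants, params) for r in rids]
        )
        norms = np.linalg.norm(mat, axis=1)
        norms[norms == 0] = 1.0
        entries[tid] = LibraryEntry(
            template=templates[tid],
            support_count=len(rids),
            support_unit=mat / norms[:, None],
            support_ids=tuple(rids),
        )
    return TemplateLibrary(
        entries=entries,
        params=params,
        provenance={"n_train": len(train_ids), "predictor": "template_retrieval"},
    )


def predict(
    library: TemplateLibrary,
    reactants: Sequence[str],
    agents: Sequence[str] = (),
    k: int = 5,
) -> list[str]:
    """Ranked candidate product sets (dot-joined SMILES) for one query.

    Applies every applicable library template; an empty list is a legal
    miss (no applicable template — exactly what happens to a query whose
    transform was never seen in training). Candidates inherit their
    template's score; within a template, and across exact score ties, the
    lexicographically smallest canonical product string wins.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = _reactants_fp(reactants, library.params)
    qn = np.linalg.norm(q)
    if qn == 0:
        qn = 1.0
    scored: list[tuple[float, str]] = []
    for tid in sorted(library.entries):
        entry = library.entries[tid]
        try:
            cands = entry.template.candidate_products(reactants)
        except Exception:
            continue
        if not cands:
            continue
        sim = float(np.max(entry.support_unit @ (q / qn)))
        score = sim * math.log1p(entry.support_count)
        for cand in cands:
            scored.append((score, cand))
    # best score first; ties by canonical product string; duplicates keep
    # their best-scoring occurrence
    scored.sort(key=lambda t: (-t[0], t[1]))
    out: list[str] = []
    seen: set[str] = set()
    for _, cand in scored:
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
        if len(out) == k:
            break
    return out


def predict_split(
    library: TemplateLibrary,
    corpus: Corpus,
    test_ids: Iterable[str],
    k: int = 5,
) -> PredictionSet:
    """Run the baseline over a whole test set."""
    cands = {
        rid: predict(library, corpus[rid].reactants, corpus[rid].agents, k)
        for rid in sorted(test_ids)
    }
    prov = dict(library.provenance)
    prov["k"] = k
    return PredictionSet(candidates=cands, provenance=prov)
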