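"""Top-k accuracy under strict and relaxed matching, and iterated prediction.

A prediction is judged correct when the recorded major product set appears
among a predictor's k highest-ranked candidates, with the comparison made on
canonicalized SMILES. Three matching policies form a relaxation chain:

``strict``
    canonical product multisets identical (stereochemistry included);
``stereo_agnostic``
    identical after deleting all tetrahedral and double-bond stereo marks;
``formula_level``
    equal multisets of molecular formulas — regioisomeric (and, more
    broadly, constitutional-isomeric) products count as correct.

For any candidate/truth pair, strict ⇒ stereo-agnostic ⇒ formula-level, so
reported accuracies are ordered the same way at every k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .corpus import Corpus

POLICIES = ("strict", "stereo_agnostic", "formula_level")

#: ranking depth default, matching a beam width of 5
DEFAULT_KS = (1, 3, 5)


class GroundTruthParseError(ValueError):
    pass


def _mols(smiles: str) -> list[Chem.Mol] | None:
    mols = []
    for part in smiles.split("."):
        m = Chem.MolFromSmiles(part)
        if m is None:
            return None
        mols.append(m)
    return mols


def normalize_products(smiles: str, policy: str = "strict") -> str | None:
    """Map a dot-joined product set to its policy-specific normal form.

    Returns ``None`` for unparseable input (callers treat that as a
    non-matching candidate). Normal forms: sorted canonical SMILES (strict),
    sorted stereo-stripped canonical SMILES (stereo_agnostic), or the sorted
    molecular-formula multiset (formula_level).
    """
    mols = _mols(smiles)
    if mols is None:
        return None
    if policy == "strict":
        parts = [Chem.MolToSmiles(m) for m in mols]
    elif policy == "stereo_agnostic":
        parts = []
        for m in mols:
            Chem.RemoveStereochemistry(m)
            parts.append(Chem.MolToSmiles(m))
    elif policy == "formula_level":
        parts = [rdMolDescriptors.CalcMolFormula(m) for m in mols]
    else:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    return ".".join(sorted(parts))


def _match(candidate: str, truth: str, policy: str) -> bool:
    t = normalize_products(truth, policy)
    if t is None:
        raise GroundTruthParseError(f"ground truth does not parse: {truth!r}")
    c = normalize_products(candidate, policy)
    return c is not None and c == t


def match_strict(candidate: str, truth: str) -> bool:
    """Exact match of canonical product multisets."""
    return _match(candidate, truth, "strict")


def match_stereo_agnostic(candidate: str, truth: str) -> bool:
    """Match after removing all stereochemical information from both sides."""
    return _match(candidate, truth, "stereo_agnostic")


def match_formula_level(candidate: str, truth: str) -> bool:
    """Match of molecular-formula multisets (regioisomers count as correct)."""
    return _match(candidate, truth, "formula_level")


@dataclass
class PredictionSet:
    """Ranked candidate product sets per test record (rank 1 = best)."""

    candidates: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for rid in sorted(self.candidates):
                fh.write(
                    json.dumps({"record_id": rid, "candidates": self.candidates[rid]})
                    + "\n"
                )

    @staticmethod
    def load(path: str | Path, provenance: dict | None = None) -> "PredictionSet":
        cands = {}
        with Path(path).open() as fh:
            for line in fh:
                if line.strip():
                    row = json.loads(line)
                    cands[row["record_id"]] = list(row["candidates"])
        return PredictionSet(cands, provenance or {})


@dataclass
class EvalReport:
    """Per-policy, per-k accuracies with per-record match ranks."""

    accuracy: dict[str, dict[int, float]]
    n_evaluated: int
    match_ranks: dict[str, dict[str, int | None]]
    ks: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "ks": list(self.ks),
            "accuracy": {
                pol: {str(k): v for k, v in accs.items()}
                for pol, accs in self.accuracy.items()
            },
        }


def _dedup_ranked(normed: list[str | None]) -> list[str | None]:
    """Collapse duplicate normal forms keeping the best rank (beam candidates
    can collide after stereo stripping; collisions must not eat k slots)."""
    seen: set[str] = set()
    out: list[str | None] = []
    for n in normed:
        if n is None or n not in seen:
            out.append(n)
            if n is not None:
                seen.add(n)
    return out


def match_rank(
    candidates: Sequence[str], truth: str, policy: str
) -> int | None:
    """1-based rank of the first candidate matching the truth, after
    policy normalization and duplicate collapse; None when absent."""
    t = normalize_products(truth, policy)
    if t is None:
        raise GroundTruthParseError(f"ground truth does not parse: {truth!r}")
    normed = _dedup_ranked([normalize_products(c, policy) for c in candidates])
    for i, n in enumerate(normed, start=1):
        if n == t:
            return i
    return None


def topk_accuracy(
    predictions: PredictionSet,
    corpus: Corpus,
    test_ids: Iterable[str],
    ks: Sequence[int] = DEFAULT_KS,
    policies: Sequence[str] = POLICIES,
) -> EvalReport:
    """Fraction of test records whose recorded product set appears in the
    first k candidates, for each k and matching policy.

    Records with no prediction list count as misses. Unknown ``test_ids``
    raise; candidate parse failures silently count as non-matches.
    """
    test_ids = sorted(test_ids)
    if any(k < 1 for k in ks):
        raise ValueError("all ks must be positive")
    missing = [r for r in test_ids if r not in corpus]
    if missing:
        raise KeyError(f"test ids not in corpus: {missing[:5]}")
    ranks: dict[str, dict[str, int | None]] = {p: {} for p in policies}
    for rid in test_ids:
        truth = ".".join(corpus[rid].products)
        cands = predictions.candidates.get(rid, [])
        for policy in policies:
            ranks[policy][rid] = match_rank(cands, truth, policy)
    n = len(test_ids)
    accuracy = {
        policy: {
            k: (
                sum(1 for r in ranks[policy].values() if r is not None and r <= k) / n
                if n
                else 0.0
            )
            for k in ks
        }
        for policy in policies
    }
    return EvalReport(
        accuracy=accuracy, n_evaluated=n, match_ranks=ranks, ks=tuple(ks)
    )


# ---------------------------------------------------------------------------
# Iterated prediction
# ---------------------------------------------------------------------------

Predictor = Callable[[Sequence[str], Sequence[str], int], list[str]]


def _heavy_atoms(smiles: str) -> int:
    m = Chem.MolFromSmiles(smiles)
    return m.GetNumHeavyAtoms() if m is not None else -1


def carry_replace_largest(
    reactants: Sequence[str], product: str
) -> list[str]:
    """Default carry rule between prediction rounds: the previous round's
    top-1 product replaces the heavy-atom-largest reactant (the transformed
    substrate is typically the largest species); all other reactants are
    retained."""
    if not reactants:
        return product.split(".")
    largest = max(range(len(reactants)), key=lambda i: _heavy_atoms(reactants[i]))
    out = [r for i, r in enumerate(reactants) if i != largest]
    return product.split(".") + out


CARRY_RULES: dict[str, Callable[[Sequence[str], str], list[str]]] = {
    "replace_largest": carry_replace_largest,
    "product_only": lambda reactants, product: product.split("."),
}


def iterate_predict(
    predictor: Predictor,
    reactants: Sequence[str],
    agents: Sequence[str],
    rounds: int = 1,
    k: int = 5,
    carry_rule: str = "replace_largest",
) -> tuple[list[str], dict]:
    """Feed the top-1 product of each round back in as a reactant.

    With ``rounds=1`` this is a direct predictor call. For later rounds the
    input reactant list is rebuilt from the previous round's top-1 candidate
    via ``carry_rule``. Returns the final round's ranked candidate list and
    a provenance dict (rounds completed, intermediate top-1 products, and a
    ``truncated`` flag when an intermediate round produced no candidates).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    carry = CARRY_RULES[carry_rule]
    current = list(reactants)
    provenance: dict = {
        "carry_rule": carry_rule,
        "rounds_requested": rounds,
        "intermediate_top1": [],
        "truncated": False,
    }
    result: list[str] = []
    for r in range(rounds):
        result = predictor(current, agents, k)
        if not result:
            provenance["truncated"] = True
            provenance["rounds_completed"] = r + 1
            return result, provenance
        if r < rounds - 1:
            provenance["intermediate_top1"].append(result[0])
            current = carry(current, result[0])
    provenance["rounds_completed"] = rounds
    return result, provenance
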