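"""Distribution-shift diagnostics in fingerprint space.

How far is each test reaction from the chemistry the model trained on? We
measure this as the mean cosine distance from each test record to its m
nearest training records (m = 5 by default) in one of two spaces:

``reactant``
    the sum of hashed circular (Morgan) substructure count vectors over the
    reactants — how novel the substrates are;
``reaction``
    the difference fingerprint, product counts minus reactant counts — how
    novel the transform is, largely independent of the substrate.

Counted (not binary) fingerprints with radius 2 hashed to 2048 bits are the
community default for both uses. Agents are excluded from both spaces by
default so that solvent/catalyst encoding does not masquerade as chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.metrics.pairwise import cosine_distances

from .corpus import Corpus, ReactionRecord


@dataclass(frozen=True)
class FingerprintParams:
    radius: int = 2
    width: int = 2048
    counted: bool = True
    include_agents: bool = False


_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(params: FingerprintParams):
    key = (params.radius, params.width)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=params.radius, fpSize=params.width
        )
    return _GENERATORS[key]


@lru_cache(maxsize=500_000)
def _mol_sparse(
    smiles: str, radius: int, width: int, counted: bool
) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Sparse (bit, value) fingerprint of one molecule, memoized — corpora
    reuse a modest pool of substrates, so this dominates throughput."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = _generator(FingerprintParams(radius=radius, width=width))
    if counted:
        nz = gen.GetCountFingerprint(mol).GetNonzeroElements()
        return tuple(nz.keys()), tuple(float(v) for v in nz.values())
    bits = tuple(gen.GetFingerprint(mol).GetOnBits())
    return bits, tuple(1.0 for _ in bits)


def _mol_counts(smiles: str, params: FingerprintParams) -> np.ndarray:
    bits, vals = _mol_sparse(smiles, params.radius, params.width, params.counted)
    vec = np.zeros(params.width, dtype=np.float64)
    vec[list(bits)] = vals
    return vec


def _part_fingerprint(
    smiles_list: Sequence[str], params: FingerprintParams, label: str
) -> np.ndarray:
    vec = np.zeros(params.width, dtype=np.float64)
    for s in smiles_list:
        try:
            vec += _mol_counts(s, params)
        except ValueError as exc:
            raise ValueError(f"{label}: {exc}") from exc
    return vec


def reactant_fingerprint(
    record: ReactionRecord, params: FingerprintParams = FingerprintParams()
) -> np.ndarray:
    """Sum of per-reactant hashed circular count vectors; permutation
    invariant over reactants; agents excluded unless configured in."""
    vec = _part_fingerprint(record.reactants, params, f"record {record.record_id}")
    if params.include_agents:
        vec += _part_fingerprint(record.agents, params, f"record {record.record_id}")
    return vec


def reaction_fingerprint(
    record: ReactionRecord, params: FingerprintParams = FingerprintParams()
) -> np.ndarray:
    """Difference fingerprint: product count vector minus reactant count
    vector. Encodes the transform — identical transforms applied to
    different substrates land nearby."""
    label = f"record {record.record_id}"
    return _part_fingerprint(record.products, params, label) - _part_fingerprint(
        record.reactants, params, label
    )


_SPACES = {"reactant": reactant_fingerprint, "reaction": reaction_fingerprint}


@dataclass
class ShiftProfile:
    """Per-test-record mean distance to the m nearest training records."""

    space: str
    m: int
    distances: dict[str, float]
    params: FingerprintParams = field(default_factory=FingerprintParams)

    @property
    def values(self) -> np.ndarray:
        return np.array([self.distances[r] for r in sorted(self.distances)])

    def summary(self) -> dict:
        v = self.values
        return {
            "space": self.space,
            "m": self.m,
            "n_test": len(v),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
        }


def fingerprint_matrix(
    corpus: Corpus,
    record_ids: Sequence[str],
    space: str,
    params: FingerprintParams = FingerprintParams(),
) -> np.ndarray:
    if space not in _SPACES:
        raise ValueError(f"unknown space {space!r}; expected one of {sorted(_SPACES)}")
    fp = _SPACES[space]
    return np.vstack([fp(corpus[r], params) for r in record_ids])


def nn_distance_profile(
    train_ids: Iterable[str],
    test_ids: Iterable[str],
    corpus: Corpus,
    space: str = "reactant",
    m: int = 5,
    params: FingerprintParams = FingerprintParams(),
    block_size: int = 512,
) -> ShiftProfile:
    """Mean cosine distance from each test record to its m nearest training
    records, by exact (non-approximate) search.

    Distances to all training records are computed in blocks to bound
    memory; the m smallest are kept after a stable sort by (distance,
    training record id), which fixes tie handling deterministically.
    """
    train_ids = sorted(train_ids)
    test_ids = sorted(test_ids)
    if m < 1:
        raise ValueError("m must be >= 1")
    if not train_ids or not test_ids:
        raise ValueError("train and test sets must be nonempty")
    if m > len(train_ids):
        raise ValueError(f"m={m} exceeds training-set size {len(train_ids)}")
    test_mat = fingerprint_matrix(corpus, test_ids, space, params)
    # keep, per test record, the m best (distance, train_id) pairs seen so far
    best: list[list[tuple[float, str]]] = [[] for _ in test_ids]
    for start in range(0, len(train_ids), block_size):
        chunk_ids = train_ids[start : start + block_size]
        chunk = fingerprint_matrix(corpus, chunk_ids, space, params)
        d = cosine_distances(test_mat, chunk)
        for i in range(len(test_ids)):
            merged = best[i] + [
                (float(d[i, j]), chunk_ids[j]) for j in range(len(chunk_ids))
            ]
            merged.sort(key=lambda t: (t[0], t[1]))
            best[i] = merged[:m]
    distances = {
        rid: float(np.mean([d for d, _ in best[i]])) for i, rid in enumerate(test_ids)
    }
    return ShiftProfile(space=space, m=m, distances=distances, params=params)


def compare_splits(
    profiles: Sequence[ShiftProfile],
    names: Sequence[str] | None = None,
    n_bins: int = 20,
) -> dict:
    """Order split profiles by median distance (easy to hard) and emit
    per-split medians plus histogram bin counts for plotting."""
    if not profiles:
        raise ValueError("no profiles")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.space != ref.space or p.params != ref.params:
            raise ValueError("profiles must share fingerprint space and params")
    names = list(names) if names is not None else [f"split{i}" for i in range(len(profiles))]
    hi = max(float(p.values.max()) for p in profiles) or 1.0
    edges = np.linspace(0.0, hi, n_bins + 1)
    entries = []
    for name, p in zip(names, profiles):
        counts, _ = np.histogram(p.values, bins=edges)
        entries.append(
            {"name": name, **p.summary(), "hist_counts": counts.tolist()}
        )
    entries.sort(key=lambda e: (e["median"], e["name"]))
    return {
        "space": ref.space,
        "m": ref.m,
        "bin_edges": edges.tolist(),
        "ranking": [e["name"] for e in entries],
        "splits": entries,
    }
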