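"""Reaction corpus data model, canonicalization, deduplication, and I/O.

A corpus is a collection of literature-derived reaction records. Each record
carries the reaction itself (reactants, agents, products as SMILES) plus the
"hidden" metadata that out-of-distribution splits key on: the source document,
its author list, the publication year, and a hierarchical reaction-class code
(NameRxn-style ``"a.b.c"``, with ``"0.0"`` meaning uncategorized).

Every record exposes a ``canonical_key`` — the reaction string rebuilt from
RDKit-canonical molecule SMILES with the molecules of each part sorted — so
that chemically identical reactions compare equal regardless of input SMILES
dialect or molecule ordering. Deduplication and all train/test leakage audits
operate on this key.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

CLASS_CODE_RE = re.compile(r"^\d+(\.\d+){0,2}$")
UNCATEGORIZED = "0.0"

#: identity of the molecule canonicalization routine; stored in corpus
#: metadata so corpora canonicalized by different routines are detectable.
CANONICALIZER = f"rdkit-{Chem.rdBase.rdkitVersion}-canonical-smiles"


class SmilesParseError(ValueError):
    """A SMILES string failed to parse; carries the offending string."""

    def __init__(self, smiles: str, part: str = "") -> None:
        self.smiles = smiles
        self.part = part
        where = f" in {part}" if part else ""
        super().__init__(f"unparseable SMILES{where}: {smiles!r}")


class SchemaError(ValueError):
    pass


@lru_cache(maxsize=1_000_000)
def _canonicalize_cached(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def canonicalize_molecule(smiles: str, part: str = "") -> str:
    out = _canonicalize_cached(smiles)
    if out is None:
        raise SmilesParseError(smiles, part)
    return out


def canonicalize_part(smiles_list: Sequence[str], part: str = "") -> list[str]:
    """Canonicalize each molecule and sort lexicographically (multiset form)."""
    return sorted(canonicalize_molecule(s, part) for s in smiles_list)


def canonicalize_reaction(
    reactants: Sequence[str],
    agents: Sequence[str],
    products: Sequence[str],
) -> str:
    """Build the canonical ``"R>A>P"`` reaction string.

    Each part lists canonical molecule SMILES in lexicographic order joined by
    ``"."``. The result is invariant to the ordering of molecules within a
    part and to the SMILES dialect of the inputs, and is idempotent.
    """
    r = canonicalize_part(reactants, "reactants")
    a = canonicalize_part(agents, "agents")
    p = canonicalize_part(products, "products")
    return f"{'.'.join(r)}>{'.'.join(a)}>{'.'.join(p)}"


def parse_reaction_smiles(rxn: str) -> tuple[list[str], list[str], list[str]]:
    """Split an ``"R>A>P"`` reaction SMILES into its molecule lists."""
    parts = rxn.split(">")
    if len(parts) != 3:
        raise ValueError(f"reaction SMILES must have 3 '>'-separated parts: {rxn!r}")
    return tuple([m for m in part.split(".") if m] for part in parts)  # type: ignore[return-value]


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction with its hidden literature metadata."""

    record_id: str
    reactants: tuple[str, ...]
    agents: tuple[str, ...]
    products: tuple[str, ...]
    doc_id: str
    authors: tuple[str, ...]
    year: int
    class_code: str
    transform: str | None = None
    canonical_key: str = field(default="", compare=False)

    @staticmethod
    def create(
        record_id: str,
        reactants: Sequence[str],
        agents: Sequence[str],
        products: Sequence[str],
        doc_id: str,
        authors: Sequence[str],
        year: int,
        class_code: str,
        transform: str | None = None,
    ) -> "ReactionRecord":
        """Validate fields and derive the canonical key."""
        if not products:
            raise ValueError(f"record {record_id!r}: products must be nonempty")
        if not authors:
            raise ValueError(f"record {record_id!r}: authors must be nonempty")
        if not CLASS_CODE_RE.match(class_code):
            raise ValueError(
                f"record {record_id!r}: invalid class code {class_code!r}"
            )
        key = canonicalize_reaction(reactants, agents, products)
        return ReactionRecord(
            record_id=record_id,
            reactants=tuple(reactants),
            agents=tuple(agents),
            products=tuple(products),
            doc_id=doc_id,
            authors=tuple(authors),
            year=int(year),
            class_code=class_code,
            transform=transform,
            canonical_key=key,
        )

    @property
    def rxn_smiles(self) -> str:
        return (
            ".".join(self.reactants)
            + ">"
            + ".".join(self.agents)
            + ">"
            + ".".join(self.products)
        )


def class_prefix_match(class_code: str, prefix: str) -> bool:
    """Hierarchical prefix match on ``"."`` boundaries.

    ``"3.1"`` matches ``"3.1"`` and ``"3.1.2"`` but not ``"3.10.2"``.
    """
    return class_code == prefix or class_code.startswith(prefix + ".")


class Corpus:
    """An id-keyed collection of :class:`ReactionRecord` with metadata indexes."""

    def __init__(
        self, records: Iterable[ReactionRecord], metadata: dict | None = None
    ) -> None:
        self._records: dict[str, ReactionRecord] = {}
        for rec in records:
            if rec.record_id in self._records:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            self._records[rec.record_id] = rec
        self.metadata: dict = {"canonicalizer": CANONICALIZER}
        if metadata:
            self.metadata.update(metadata)
        self._build_indexes()

    def _build_indexes(self) -> None:
        self.by_doc: dict[str, list[str]] = {}
        self.by_author: dict[str, list[str]] = {}
        self.by_year: dict[int, list[str]] = {}
        self.by_class: dict[str, list[str]] = {}
        for rid, rec in self._records.items():
            self.by_doc.setdefault(rec.doc_id, []).append(rid)
            for a in rec.authors:
                self.by_author.setdefault(a, []).append(rid)
            self.by_year.setdefault(rec.year, []).append(rid)
            self.by_class.setdefault(rec.class_code, []).append(rid)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ReactionRecord]:
        return iter(self._records.values())

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._records

    def __getitem__(self, record_id: str) -> ReactionRecord:
        return self._records[record_id]

    @property
    def record_ids(self) -> list[str]:
        return list(self._records)

    def subset(self, record_ids: Iterable[str]) -> "Corpus":
        return Corpus(
            (self._records[r] for r in record_ids), metadata=dict(self.metadata)
        )

    def ids_with_class_prefix(self, prefix: str) -> set[str]:
        return {
            rid
            for code, rids in self.by_class.items()
            if class_prefix_match(code, prefix)
            for rid in rids
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._records == other._records


def deduplicate(corpus: Corpus) -> tuple[Corpus, dict]:
    """Retain one record per canonical reaction key.

    When a key occurs in several documents, the record with the earliest year
    is kept; remaining ties are broken by lexicographically smallest
    ``doc_id``, then ``record_id`` (the earliest report is the natural first
    disclosure for time-based splits). Idempotent. Returns the deduplicated
    corpus and a report with the dropped-record count.
    """
    best: dict[str, ReactionRecord] = {}
    for rec in corpus:
        prev = best.get(rec.canonical_key)
        if prev is None or (rec.year, rec.doc_id, rec.record_id) < (
            prev.year,
            prev.doc_id,
            prev.record_id,
        ):
            best[rec.canonical_key] = rec
    kept = sorted(best.values(), key=lambda r: r.record_id)
    report = {
        "input_records": len(corpus),
        "kept_records": len(kept),
        "dropped_records": len(corpus) - len(kept),
    }
    meta = dict(corpus.metadata)
    meta["deduplicated"] = True
    return Corpus(kept, metadata=meta), report


# ---------------------------------------------------------------------------
# I/O:  CSV / TSV / JSONL with columns
#   record_id, rxn_smiles, doc_id, authors (";"-joined), year, class_code,
#   [transform]
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ["rxn_smiles", "doc_id", "authors", "year", "class_code"]

_FORMATS = {"csv", "tsv", "jsonl"}


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    suffix = Path(path).suffix.lstrip(".").lower()
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer format from {path}; pass format=")


def _record_from_row(row: dict, line_no: int) -> ReactionRecord:
    try:
        reactants, agents, products = parse_reaction_smiles(str(row["rxn_smiles"]))
        authors = [a for a in str(row["authors"]).split(";") if a]
        transform = row.get("transform")
        if transform is not None and (transform == "" or pd.isna(transform)):
            transform = None
        return ReactionRecord.create(
            record_id=str(row["record_id"]),
            reactants=reactants,
            agents=agents,
            products=products,
            doc_id=str(row["doc_id"]),
            authors=authors,
            year=int(row["year"]),
            class_code=str(row["class_code"]),
            transform=transform,
        )
    except (ValueError, KeyError) as exc:
        raise ValueError(f"line {line_no}: {exc}") from exc


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from CSV, TSV, or JSONL.

    Raises :class:`SchemaError` listing missing required columns, and
    row-level ``ValueError`` (with line number) for malformed reactions.
    """
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "jsonl":
        rows = []
        with path.open() as fh:
            for i, line in enumerate(fh, start=1):
                if line.strip():
                    rows.append((json.loads(line), i))
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype=str)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        rows = [(row, i + 2) for i, row in enumerate(df.to_dict(orient="records"))]
    records = []
    for row, line_no in rows:
        if fmt == "jsonl":
            missing = [c for c in REQUIRED_COLUMNS if c not in row]
            if missing:
                raise SchemaError(f"line {line_no}: missing fields: {missing}")
        if "record_id" not in row or row["record_id"] in (None, "") or (
            not isinstance(row["record_id"], str) and pd.isna(row["record_id"])
        ):
            row = dict(row)
            row["record_id"] = f"r{line_no}"
        records.append(_record_from_row(dict(row), line_no))
    return Corpus(records)


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    path = Path(path)
    rows = [
        {
            "record_id": rec.record_id,
            "rxn_smiles": rec.rxn_smiles,
            "doc_id": rec.doc_id,
            "authors": ";".join(rec.authors),
            "year": rec.year,
            "class_code": rec.class_code,
            "transform": rec.transform,
        }
        for rec in sorted(corpus, key=lambda r: r.record_id)
    ]
    if fmt == "jsonl":
        with path.open("w") as fh:
            for row in rows:
                if row["transform"] is None:
                    row = {k: v for k, v in row.items() if k != "transform"}
                fh.write(json.dumps(row) + "\n")
    else:
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
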