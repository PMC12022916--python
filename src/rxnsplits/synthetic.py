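"""Synthetic literature-structured reaction corpus generator.

Real reaction corpora are not i.i.d. samples of chemistry: authors come
together to write documents, each document reports a substrate-scope series
of closely related examples of (usually) one transform, reaction classes
rise and fall in popularity over the years, and genuinely new classes appear
at some discovery year and are then adopted. This module emulates exactly
that generative structure with a small curated library of toy transforms
(:mod:`rxnsplits.templates`) applied to decorated scaffold families, so that
every splitter, metric, and shift diagnostic can be exercised end to end —
and so that random record-level splits are *leaky by construction* while
document/author/time/class splits are genuinely harder.

Structure emulated
------------------
* documents get a publication year, an author team drawn from a recurring
  pool (so co-authorship components are nontrivial), and a dominant
  reaction class sampled from a year-dependent popularity schedule;
* each lab (research group) carries stable preferences — a favorite class,
  favorite decorations and scaffold cores, house partner reagents — that
  recur across the documents it writes, the reason author-component splits
  are harder than document-level ones;
* within a document, one scaffold core is decorated with varying
  substituents across reactions (the scope series);
* some decorations are themselves reactive (a chloride, a free alcohol or
  amine, a ketone), so several transforms can apply to one reactant set and
  a predictor must rank them — the substrate-level ambiguity that makes
  extrapolation measurable;
* classes can be introduced at a configured year (``intro_year``) with a
  linearly drifting popularity weight, emulating discovery and adoption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import yaml

from .corpus import Corpus, ReactionRecord, deduplicate, UNCATEGORIZED
from .templates import TEMPLATES_BY_ID, apply_template  # noqa: F401  (re-exported)

GENERATOR_TAG = "rxnsplits.synthetic_corpus"


@dataclass(frozen=True)
class ClassSpec:
    """One reaction class in the popularity schedule.

    Popularity drifts linearly from ``weight_start`` (at the first corpus
    year) to ``weight_end`` (at the last); the class is unavailable before
    ``intro_year``.
    """

    class_code: str
    transform_id: str
    weight_start: float = 1.0
    weight_end: float = 1.0
    intro_year: int | None = None

    def weight(self, year: int, year_range: tuple[int, int]) -> float:
        if self.intro_year is not None and year < self.intro_year:
            return 0.0
        y0, y1 = year_range
        t = 0.0 if y1 == y0 else (year - y0) / (y1 - y0)
        return max(0.0, self.weight_start + t * (self.weight_end - self.weight_start))


@dataclass(frozen=True)
class SubstrateFamily:
    """A scaffold generator: format strings with an ``{x}`` (scope-varied)
    and usually a ``{y}`` (document-fixed) decoration site, or literal
    SMILES when ``decorate`` is false."""

    name: str
    scaffolds: tuple[str, ...]
    decorate: bool = True

    def build(self, scaffold_idx: int, x: str | None = None, y: str | None = None) -> str:
        scaffold = self.scaffolds[scaffold_idx % len(self.scaffolds)]
        if not self.decorate:
            return scaffold
        return scaffold.format(x=x, y=y)


#: Several families are deliberately polyfunctional: aryl bromides carry a
#: ring chloride (bromo- vs chloro-coupling chemoselectivity), amines carry
#: a free aliphatic alcohol and alcohols a free primary amine (amidation vs
#: esterification), phenols carry an aminomethyl group, and methyl esters an
#: aryl ketone (ester addition vs ketone addition). On such substrates more
#: than one transform is applicable, so a predictor must *rank* chemistry —
#: exactly the situation where training-set composition decides accuracy.
#: The scope-varied {x} substituent sits ortho to the reacting group so
#: that it falls inside the circular-fingerprint radius of the reaction
#: center: difference (transform) fingerprints then carry local substrate
#: context instead of collapsing to one point per reaction class.
DEFAULT_FAMILIES: dict[str, SubstrateFamily] = {
    f.name: f
    for f in (
        SubstrateFamily("aryl_bromide", ("Brc1c({x})cc({y})cc1Cl", "Brc1c({x})cc(Cl)cc1{y}", "Cc1c({y})c(Cl)cc({x})c1Br", "Brc1c({x})cc(Cl)c({y})n1")),
        SubstrateFamily("aryl_chloride", ("Clc1c({x})cc({y})cc1", "Clc1c({x})cc(C)cc1{y}", "Cc1c({y})cc({x})cc1Cl", "Clc1c({x})cc({y})cn1")),
        SubstrateFamily("boronic_acid", ("OB(O)c1c({x})cc({y})cc1", "OB(O)c1cc({x})cc({y})c1", "OB(O)c1c({x})cc({y})cn1")),
        SubstrateFamily("primary_amine", ("NCc1c({x})cc({y})cc1CCO", "NCCc1c({x})cc({y})c(CCO)c1", "NCc1c({x})cc(CCO)c({y})n1")),
        SubstrateFamily("alkyl_bromide", ("BrCc1c({x})cc({y})cc1", "BrCCc1c({x})cc({y})cc1C")),
        SubstrateFamily("phenol", ("Oc1c({x})cc({y})cc1CN", "Oc1c({x})cc(CN)cc1{y}", "Oc1c({x})cc(CN)c({y})n1")),
        SubstrateFamily("carboxylic_acid", ("OC(=O)c1c({x})cc({y})cc1", "OC(=O)Cc1c({x})cc({y})cc1", "OC(=O)c1c({x})cc({y})cn1")),
        SubstrateFamily("alcohol", ("OCc1c({x})cc({y})cc1CN", "OCCc1c({x})cc({y})c(CN)c1", "OCCCc1c({x})cc(CN)c({y})c1")),
        SubstrateFamily("methyl_ester", ("COC(=O)c1c({x})cc({y})cc1C(C)=O", "COC(=O)Cc1c({x})cc({y})cc1C(C)=O")),
        SubstrateFamily("aryl_ketone", ("CC(=O)c1c({x})cc({y})cc1", "CCC(=O)c1c({x})cc({y})cc1C")),
        SubstrateFamily("grignard", ("C[Mg]Br", "CC[Mg]Br", "CCC[Mg]Br", "CCCC[Mg]Br"), decorate=False),
    )
}

#: which substrate family fills each slot of each transform
SLOT_FAMILIES: dict[str, tuple[str, ...]] = {
    "amine_alkylation": ("primary_amine", "alkyl_bromide"),
    "williamson_ether": ("phenol", "alkyl_bromide"),
    "amide_coupling": ("carboxylic_acid", "primary_amine"),
    "fischer_esterification": ("carboxylic_acid", "alcohol"),
    "suzuki_bromo": ("aryl_bromide", "boronic_acid"),
    "suzuki_chloro": ("aryl_chloride", "boronic_acid"),
    "buchwald_hartwig": ("aryl_bromide", "primary_amine"),
    "grignard_ester_single": ("methyl_ester", "grignard"),
    "grignard_ketone_addition": ("aryl_ketone", "grignard"),
    "grignard_ester_double": ("methyl_ester", "grignard", "grignard"),
}

#: reactive substituents: each creates a site where a *different* transform
#: also applies, so candidate ranking — not mere template possession —
#: decides accuracy on the substrates carrying them.
REACTIVE_DECORATIONS: dict[str, float] = {
    "Cl": 3.5, "CO": 3.5, "CN": 3.5, "C(C)=O": 3.5,
}

#: small substituents scanned across a document's scope series (the {x}
#: site): siblings within a document differ only by one of these, keeping
#: intra-document fingerprint similarity very high.
DEFAULT_SCOPE_DECORATIONS: dict[str, float] = {
    "C": 1.0, "CC": 1.0, "CCC": 1.0, "C(C)C": 1.0, "OC": 1.0,
    "OCC": 1.0, "F": 1.0, "C#N": 1.0, "C(F)(F)F": 1.0, "N(C)C": 1.0,
    **REACTIVE_DECORATIONS,
}

#: bulky substituents fixed per document (the {y} site and the partner
#: substrate): these carry enough fingerprint mass that reactions from
#: different documents are measurably farther apart than scope siblings.
DEFAULT_CONTEXT_DECORATIONS: dict[str, float] = {
    "C": 1.0, "CC(C)C": 1.0, "C(C)(C)C": 1.0, "OC": 1.0, "OC(C)C": 1.0,
    "OCC(C)C": 1.0, "F": 1.0, "C#N": 1.0, "C(F)(F)F": 1.0, "OC(F)(F)F": 1.0,
    "N(C)C": 1.0, "C9CC9": 1.0, "C9CCCC9": 1.0, "C9CCCCC9": 1.0,
    "N9CCOCC9": 1.0, "N9CCCC9": 1.0, "OCCOC": 1.0, "CCCC": 1.0,
    "OCC9CC9": 1.0, "CC9CCCCC9": 1.0,
    **REACTIVE_DECORATIONS,
}

DEFAULT_CLASS_TABLE: tuple[ClassSpec, ...] = (
    ClassSpec("1.6.1", "amine_alkylation", 1.0, 0.8),
    ClassSpec("1.7.1", "williamson_ether", 0.95, 0.75),
    ClassSpec("2.1.1", "amide_coupling", 1.2, 1.5),
    ClassSpec("2.1.2", "fischer_esterification", 1.2, 1.3),
    ClassSpec("3.1.1", "suzuki_bromo", 0.3, 1.5),
    ClassSpec("3.1.2", "suzuki_chloro", 0.4, 1.6, intro_year=2003),
    ClassSpec("3.2.1", "buchwald_hartwig", 0.2, 1.2, intro_year=2000),
    ClassSpec("10.1.1", "grignard_ester_single", 0.9, 0.6),
    ClassSpec("10.1.2", "grignard_ketone_addition", 0.8, 0.7),
    ClassSpec("10.2.1", "grignard_ester_double", 0.1, 0.8, intro_year=2015),
)


@dataclass
class GeneratorConfig:
    """All knobs of the generative model, with literature-shaped defaults.

    The defaults describe a mid-sized patent-like corpus: 600 documents over
    25 years, written by a pool of 240 recurring authors organized into 30
    research groups ("labs") with rare cross-lab collaborations (so the
    co-authorship graph has many nontrivial connected components), each
    document reporting a 5–12 reaction scope series, ten reaction classes
    (two sibling aryl-coupling subclasses; one class introduced late, in
    2015), and a 2% rate of uncategorized ("0.0") class labels.
    """

    n_documents: int = 600
    authors_pool_size: int = 240
    n_labs: int = 40
    cross_lab_collab_prob: float = 0.01
    team_size: tuple[int, int] = (2, 4)
    reactions_per_document: tuple[int, int] = (5, 12)
    year_range: tuple[int, int] = (1998, 2022)
    class_table: tuple[ClassSpec, ...] = DEFAULT_CLASS_TABLE
    intra_document_same_class_prob: float = 0.9
    author_class_loyalty: float = 0.4
    author_decoration_loyalty: float = 0.8
    author_core_loyalty: float = 0.9
    author_partner_loyalty: float = 0.75
    author_pref_decorations: int = 6
    uncategorized_prob: float = 0.02
    scope_decorations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCOPE_DECORATIONS)
    )
    context_decorations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_DECORATIONS)
    )
    substrate_families: dict[str, SubstrateFamily] = field(
        default_factory=lambda: dict(DEFAULT_FAMILIES)
    )
    dedupe: bool = True
    seed: int = 0

    def validate(self) -> None:
        y0, y1 = self.year_range
        if y1 < y0:
            raise ValueError("empty year_range")
        if not self.class_table:
            raise ValueError("class_table is empty")
        for year in range(y0, y1 + 1):
            if not any(cs.weight(year, self.year_range) > 0 for cs in self.class_table):
                raise ValueError(f"no class with positive weight available in {year}")
        for cs in self.class_table:
            if cs.transform_id not in TEMPLATES_BY_ID:
                raise ValueError(f"unknown transform_id {cs.transform_id!r}")
            if cs.transform_id not in SLOT_FAMILIES:
                raise ValueError(f"no slot families for {cs.transform_id!r}")
        if self.team_size[0] < 1 or self.team_size[1] > self.authors_pool_size:
            raise ValueError("team_size out of range for the author pool")
        if self.n_labs < 1 or self.n_labs > self.authors_pool_size:
            raise ValueError("n_labs must be in [1, authors_pool_size]")
        if self.team_size[1] > self.authors_pool_size // self.n_labs + 1:
            raise ValueError("labs are too small for the configured team size")
        if self.reactions_per_document[0] < 1:
            raise ValueError("reactions_per_document must be >= 1")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["class_table"] = [asdict(cs) for cs in self.class_table]
        d["substrate_families"] = {
            k: {"scaffolds": list(v.scaffolds), "decorate": v.decorate}
            for k, v in self.substrate_families.items()
        }
        Path(path).write_text(yaml.safe_dump(d))

    @staticmethod
    def from_yaml(path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "class_table" in d:
            d["class_table"] = tuple(ClassSpec(**cs) for cs in d["class_table"])
        if "substrate_families" in d:
            d["substrate_families"] = {
                k: SubstrateFamily(name=k, scaffolds=tuple(v["scaffolds"]), decorate=v.get("decorate", True))
                for k, v in d["substrate_families"].items()
            }
        for key in ("team_size", "reactions_per_document", "year_range"):
            if key in d:
                d[key] = tuple(d[key])
        return GeneratorConfig(**d)


def _sample_class(
    rng: np.random.Generator, config: GeneratorConfig, year: int
) -> ClassSpec:
    weights = np.array(
        [cs.weight(year, config.year_range) for cs in config.class_table]
    )
    total = weights.sum()
    return config.class_table[rng.choice(len(weights), p=weights / total)]


def generate_corpus(config: GeneratorConfig | None = None) -> Corpus:
    """Sample a full corpus from the generative model; deterministic given
    ``config.seed``. Deduplicated on return (unless ``config.dedupe`` is
    off), so the result satisfies every corpus invariant as-is."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    pools = {}
    for which, table in (
        ("scope", config.scope_decorations),
        ("context", config.context_decorations),
    ):
        names = list(table)
        w = np.array([table[d] for d in names], dtype=float)
        pools[which] = (names, w / w.sum())

    authors = [f"A{i:04d}" for i in range(config.authors_pool_size)]
    labs = [
        [authors[i] for i in range(config.authors_pool_size) if i % config.n_labs == lab]
        for lab in range(config.n_labs)
    ]
    # chemical style is a *lab-level* trait (the group's favorite class,
    # decorations, scaffold cores, and house partner reagents recur across
    # all documents the lab writes): this is what makes author-component
    # splits genuinely out-of-distribution while document splits still find
    # same-lab support in training
    lab_pref_class = {
        lab: config.class_table[rng.integers(len(config.class_table))]
        for lab in range(config.n_labs)
    }
    lab_pref_deco: dict[tuple[int, str], list[str]] = {}
    for lab in range(config.n_labs):
        for which, (names, p) in pools.items():
            n_pref = min(config.author_pref_decorations, len(names))
            lab_pref_deco[lab, which] = [
                names[i]
                for i in rng.choice(len(names), size=n_pref, replace=False, p=p)
            ]

    def draw_decoration(lab: int, which: str) -> str:
        names, p = pools[which]
        if rng.random() < config.author_decoration_loyalty:
            prefs = lab_pref_deco[lab, which]
            return prefs[int(rng.integers(len(prefs)))]
        return names[rng.choice(len(names), p=p)]

    lab_pref_core: dict[tuple[int, str], int] = {
        (lab, fam.name): int(rng.integers(len(fam.scaffolds)))
        for lab in range(config.n_labs)
        for fam in config.substrate_families.values()
    }
    lab_partner: dict[tuple[int, str], str] = {}

    def draw_core(lab: int, fam_name: str) -> int:
        fam = config.substrate_families[fam_name]
        if rng.random() < config.author_core_loyalty:
            return lab_pref_core[lab, fam_name]
        return int(rng.integers(len(fam.scaffolds)))

    records: list[ReactionRecord] = []
    truth: dict[str, dict] = {}
    rid_counter = 0
    y0, y1 = config.year_range
    for d in range(config.n_documents):
        doc_id = f"D{d:05d}"
        year = int(rng.integers(y0, y1 + 1))
        lab_idx = int(rng.integers(config.n_labs))
        lab = labs[lab_idx]
        size = min(
            int(rng.integers(config.team_size[0], config.team_size[1] + 1)), len(lab)
        )
        team = [lab[i] for i in rng.choice(len(lab), size=size, replace=False)]
        if config.n_labs > 1 and rng.random() < config.cross_lab_collab_prob:
            other = labs[(lab_idx + 1 + int(rng.integers(config.n_labs - 1))) % config.n_labs]
            team.append(other[int(rng.integers(len(other)))])

        pref = lab_pref_class[lab_idx]
        if rng.random() < config.author_class_loyalty and pref.weight(year, config.year_range) > 0:
            doc_class = pref
        else:
            doc_class = _sample_class(rng, config, year)

        # per-document substrate state: one scaffold core and one fixed
        # {y}-decoration per family, plus a fixed partner substrate per
        # family — the scope series varies only the {x}-decoration of the
        # first slot, walking a shuffled no-repeat sequence that leads with
        # the author's preferred decorations.
        doc_state: dict[str, tuple[int, str]] = {}
        partner: dict[str, str] = {}
        scope_seq: dict[str, list[str]] = {}

        def _family_state(fam_name: str) -> tuple[int, str]:
            if fam_name not in doc_state:
                fam = config.substrate_families[fam_name]
                doc_state[fam_name] = (
                    draw_core(lab_idx, fam_name),
                    draw_decoration(lab_idx, "context"),
                )
            return doc_state[fam_name]

        def _next_scope_decoration(fam_name: str) -> str:
            seq = scope_seq.get(fam_name)
            if not seq:
                # weighted no-repeat walk of the scope pool: heavier
                # (reactive) and author-preferred substituents come first,
                # so most scope series exercise an ambiguous example early
                # without ever duplicating a reaction
                names, p = pools["scope"]
                w = p * np.where(
                    np.isin(names, lab_pref_deco[lab_idx, "scope"]), 2.5, 1.0
                )
                order = rng.choice(len(names), size=len(names), replace=False, p=w / w.sum())
                seq = [names[i] for i in order]
                scope_seq[fam_name] = seq
            return seq.pop(0)

        def substrate(family_name: str, vary: bool) -> str:
            fam = config.substrate_families[family_name]
            if not fam.decorate:
                if family_name not in partner:
                    partner[family_name] = fam.build(draw_core(lab_idx, family_name))
                return partner[family_name]
            if vary:
                core, y = _family_state(family_name)
                return fam.build(core, x=_next_scope_decoration(family_name), y=y)
            if family_name not in partner:
                key = (lab_idx, family_name)
                if key in lab_partner and rng.random() < config.author_partner_loyalty:
                    partner[family_name] = lab_partner[key]
                else:
                    partner[family_name] = fam.build(
                        draw_core(lab_idx, family_name),
                        x=draw_decoration(lab_idx, "context"),
                        y=draw_decoration(lab_idx, "context"),
                    )
                    lab_partner.setdefault(key, partner[family_name])
            return partner[family_name]

        n_rxn = int(
            rng.integers(
                config.reactions_per_document[0], config.reactions_per_document[1] + 1
            )
        )
        for _ in range(n_rxn):
            if rng.random() < config.intra_document_same_class_prob:
                cls = doc_class
            else:
                cls = _sample_class(rng, config, year)
            template = TEMPLATES_BY_ID[cls.transform_id]
            fams = SLOT_FAMILIES[cls.transform_id]
            substrates = [
                substrate(fam, vary=(i == 0)) for i, fam in enumerate(fams)
            ]
            products = template.apply(substrates)
            class_code = (
                UNCATEGORIZED
                if rng.random() < config.uncategorized_prob
                else cls.class_code
            )
            rid = f"r{rid_counter:06d}"
            rid_counter += 1
            records.append(
                ReactionRecord.create(
                    record_id=rid,
                    reactants=substrates,
                    agents=list(template.agents),
                    products=products,
                    doc_id=doc_id,
                    authors=team,
                    year=year,
                    class_code=class_code,
                    transform=cls.transform_id,
                )
            )
            truth[rid] = {
                "class_code": cls.class_code,
                "transform_id": cls.transform_id,
                "doc_id": doc_id,
                "authors": tuple(team),
                "year": year,
            }

    corpus = Corpus(records, metadata={"generator": GENERATOR_TAG, "seed": config.seed})
    if config.dedupe:
        corpus, report = deduplicate(corpus)
        corpus.metadata["dedup_report"] = report
        corpus.metadata["generator"] = GENERATOR_TAG
        truth = {rid: truth[rid] for rid in corpus.record_ids}
    corpus.metadata["planted_truth"] = truth
    return corpus


def planted_truth(corpus: Corpus) -> dict[str, dict]:
    """Ground-truth generative labels (class, transform, document, authors,
    year) for every record of a corpus generated by this module."""
    if corpus.metadata.get("generator") != GENERATOR_TAG:
        raise ValueError("corpus was not generated by the synthetic_corpus module")
    return corpus.metadata["planted_truth"]
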