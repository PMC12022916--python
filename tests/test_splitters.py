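"""Split construction and leakage guarantees."""

import numpy as np
import pytest

from rxnsplits.corpus import Corpus, class_prefix_match
from rxnsplits.splitters import (
    ClassHoldoutSpec,
    Split,
    audit_split,
    audit_time_series,
    author_components,
    make_ablation_variants,
    make_class_holdout,
    make_named_reaction_testset,
    make_time_series,
    split_on_authors,
    split_on_documents,
    split_on_reactions,
)
from conftest import make_record

MOLS = ["CCO", "CCC", "CCN", "CCCl", "CCBr", "CC(C)O", "CCCO", "CCCN", "CCCC",
        "CC(C)N", "CC(C)Cl", "CCOC", "CCCOC", "CCSC", "CC(C)S", "CCCS"]


def distinct_corpus(n, doc_of=None, authors_of=None, year_of=None, class_of=None):
    """n records, all chemically distinct (reactant index pairs)."""
    records = []
    for i in range(n):
        records.append(
            make_record(
                f"r{i}",
                reactants=(MOLS[i % 16], MOLS[(i // 16) % 16]),
                products=(MOLS[(i + 5) % 16],),
                agents=(MOLS[(i // 256) % 16],),
                doc=doc_of(i) if doc_of else f"D{i}",
                authors=authors_of(i) if authors_of else (f"A{i}",),
                year=year_of(i) if year_of else 2000 + (i % 20),
                class_code=class_of(i) if class_of else "1.1.1",
            )
        )
    return Corpus(records)


class TestReactionSplit:
    def test_sizes_and_disjointness(self):
        c = distinct_corpus(100)
        sp = split_on_reactions(c, 0.2, 7)
        assert len(sp.test_ids) == 20 and len(sp.train_ids) == 80
        assert not sp.test_ids & sp.train_ids
        assert audit_split(sp, c) == []

    def test_deterministic_given_seed(self):
        c = distinct_corpus(60)
        a, b = split_on_reactions(c, 0.3, 5), split_on_reactions(c, 0.3, 5)
        assert a.test_ids == b.test_ids and a.train_ids == b.train_ids
        assert split_on_reactions(c, 0.3, 6).test_ids != a.test_ids

    def test_monte_carlo_uniformity(self):
        # each record's test-membership frequency over many seeds is
        # binomial around the test fraction
        c = distinct_corpus(100)
        n_seeds, frac = 200, 0.2
        counts = {r: 0 for r in c.record_ids}
        for s in range(n_seeds):
            for r in split_on_reactions(c, frac, s).test_ids:
                counts[r] += 1
        se = np.sqrt(frac * (1 - frac) / n_seeds)
        freqs = np.array(list(counts.values())) / n_seeds
        assert np.all(np.abs(freqs - frac) < 5 * se)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_out_of_range(self, bad):
        with pytest.raises(ValueError):
            split_on_reactions(distinct_corpus(10), bad, 0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            split_on_reactions(Corpus([]), 0.2, 0)


class TestDocumentSplit:
    def test_enumerated_small_case(self):
        # docs {D1:{r0,r1}, D2:{r2}, D3:{r3}}, fraction 0.25: the only valid
        # outcomes are test = {r2} or {r3}
        doc_of = lambda i: ["D1", "D1", "D2", "D3"][i]
        c = distinct_corpus(4, doc_of=doc_of)
        outcomes = {frozenset(split_on_documents(c, 0.25, s).test_ids) for s in range(20)}
        assert outcomes <= {frozenset({"r2"}), frozenset({"r3"})}

    def test_no_document_straddles(self, synth_corpus):
        sp = split_on_documents(synth_corpus, 0.2, 3)
        for rids in synth_corpus.by_doc.values():
            sides = {("test" if r in sp.test_ids else "train") for r in rids}
            assert len(sides) == 1
        assert audit_split(sp, synth_corpus) == []

    def test_singleton_docs_hit_fraction_exactly(self):
        c = distinct_corpus(10)  # each record its own document
        sp = split_on_documents(c, 0.5, 1)
        assert len(sp.test_ids) == 5

    def test_single_document_error(self):
        c = distinct_corpus(5, doc_of=lambda i: "D1")
        with pytest.raises(ValueError):
            split_on_documents(c, 0.2, 0)


def brute_force_components(corpus):
    """Union-find over documents sharing an author (independent oracle)."""
    docs = sorted(corpus.by_doc)
    parent = {d: d for d in docs}

    def find(d):
        while parent[d] != d:
            parent[d] = parent[parent[d]]
            d = parent[d]
        return d

    for rids in corpus.by_author.values():
        ds = sorted({corpus[r].doc_id for r in rids})
        for other in ds[1:]:
            parent[find(other)] = find(ds[0])
    comps = {}
    for d in docs:
        comps.setdefault(find(d), set()).add(d)
    return {frozenset(v) for v in comps.values()}


class TestAuthorSplit:
    def test_components_match_brute_force(self):
        authors_of = lambda i: [("Ada", "Bob"), ("Bob", "Cleo"), ("Dan",)][i]
        c = distinct_corpus(3, doc_of=lambda i: f"D{i}", authors_of=authors_of)
        comps = {frozenset(x) for x in author_components(c)}
        assert comps == brute_force_components(c)
        assert comps == {frozenset({"D0", "D1"}), frozenset({"D2"})}

    def test_coauthored_documents_co_assigned(self):
        authors_of = lambda i: [("Ada", "Bob"), ("Bob", "Cleo"), ("Dan",), ("Eve",)][i]
        c = distinct_corpus(4, doc_of=lambda i: f"D{i}", authors_of=authors_of)
        for s in range(10):
            sp = split_on_authors(c, 0.4, s)
            side0 = "r0" in sp.test_ids
            assert ("r1" in sp.test_ids) == side0

    def test_synth_components_match_brute_force(self, synth_corpus):
        assert {frozenset(x) for x in author_components(synth_corpus)} == (
            brute_force_components(synth_corpus)
        )

    def test_disjoint_authors_reduce_to_document_behavior(self):
        c = distinct_corpus(8, doc_of=lambda i: f"D{i % 4}", authors_of=lambda i: (f"A{i % 4}",))
        sp = split_on_authors(c, 0.5, 2)
        for rids in c.by_doc.values():
            assert len({r in sp.test_ids for r in rids}) == 1

    def test_no_author_straddles(self, synth_corpus):
        sp = split_on_authors(synth_corpus, 0.2, 1)
        for rids in synth_corpus.by_author.values():
            assert len({r in sp.test_ids for r in rids}) == 1
        assert audit_split(sp, synth_corpus) == []

    def test_single_component_error_lists_sizes(self):
        c = distinct_corpus(4, doc_of=lambda i: f"D{i}", authors_of=lambda i: ("Ada", f"B{i}"))
        with pytest.raises(ValueError, match="component"):
            split_on_authors(c, 0.5, 0)


class TestTimeSeries:
    def make(self, **kw):
        c = distinct_corpus(200, year_of=lambda i: 2000 + (i % 10))
        args = dict(test_years=[2004, 2008], cutoffs=[2003, 2006, 2009],
                    test_size_per_year=5, train_size=40, seed=1)
        args.update(kw)
        return c, make_time_series(c, **args)

    def test_year_bound_and_disjointness(self):
        c, series = self.make()
        assert audit_time_series(series, c) == []
        for cut, train in series.train_sets.items():
            assert all(c[r].year <= cut for r in train)
        tests = set().union(*series.test_sets.values())
        assert not tests & series.all_train_ids()

    def test_exact_size_control(self):
        c, series = self.make()
        assert all(len(t) == 40 for t in series.train_sets.values())
        assert all(len(t) == 5 for t in series.test_sets.values())

    def test_uncontrolled_pool_is_everything_before_cutoff(self):
        c, series = self.make(train_size=None)
        reserved = set().union(*series.test_sets.values())
        for cut, train in series.train_sets.items():
            expected = {r for r in c.record_ids if c[r].year <= cut} - reserved
            assert train == expected

    def test_small_test_year_error_names_year(self):
        c = distinct_corpus(20, year_of=lambda i: 2000 + (i % 10))
        with pytest.raises(ValueError, match="2004"):
            make_time_series(c, [2004], [2006], 5, None, 0)

    def test_small_cutoff_pool_error_names_cutoff(self):
        with pytest.raises(ValueError, match="2003"):
            self.make(train_size=150)


class TestClassHoldout:
    def corpus(self):
        class_of = lambda i: ["3.1.2", "3.1.1", "2.1.1", "0.0"][i % 4]
        return distinct_corpus(200, class_of=class_of)

    def test_baseline_and_holdout_contracts(self):
        c = self.corpus()
        spec = ClassHoldoutSpec(holdout_prefix="3.1.2", baseline_n=20)
        base, hold, shared = make_class_holdout(c, spec, 0.2, 3)
        in_class = lambda r: class_prefix_match(c[r].class_code, "3.1.2")
        assert sum(map(in_class, base.train_ids)) == 20
        assert sum(map(in_class, hold.train_ids)) == 0
        assert base.test_ids == hold.test_ids == shared
        assert all(map(in_class, shared))
        assert audit_split(base, c) == [] and audit_split(hold, c) == []

    def test_uncategorized_dropped(self):
        c = self.corpus()
        base, hold, shared = make_class_holdout(
            c, ClassHoldoutSpec("3.1.2", baseline_n=10), 0.2, 1
        )
        covered = base.train_ids | hold.train_ids | shared | set(base.params["id_test_ids"])
        assert all(c[r].class_code != "0.0" for r in covered)

    def test_wider_exclusion_prefix(self):
        c = self.corpus()
        spec = ClassHoldoutSpec("3.1.2", train_exclusion_prefix="3.1", baseline_n=10)
        _, hold, _ = make_class_holdout(c, spec, 0.2, 1)
        assert not any(class_prefix_match(c[r].class_code, "3.1") for r in hold.train_ids)

    def test_too_few_class_records(self):
        c = self.corpus()
        with pytest.raises(ValueError):
            make_class_holdout(c, ClassHoldoutSpec("3.1.2", baseline_n=50), 0.2, 0)
        with pytest.raises(ValueError):
            make_class_holdout(c, ClassHoldoutSpec("9.9.9"), 0.2, 0)


class TestAblationVariants:
    def test_nesting_and_exclusions(self):
        class_of = lambda i: ["3.1.2", "3.1.1", "2.1.1", "1.6.1"][i % 4]
        c = distinct_corpus(120, class_of=class_of)
        all_cls, siblings, excluded = make_ablation_variants(c, "3.1.2", "3.1", 1)
        assert all_cls.test_ids == siblings.test_ids == excluded.test_ids
        assert all_cls.train_ids >= siblings.train_ids >= excluded.train_ids
        codes = lambda sp: {c[r].class_code for r in sp.train_ids}
        assert "3.1.2" in codes(all_cls)
        assert "3.1.1" in codes(siblings) and "3.1.2" not in codes(siblings)
        assert not any(class_prefix_match(x, "3.1") for x in codes(excluded))

    def test_subclass_must_extend_parent(self):
        c = distinct_corpus(20, class_of=lambda i: "3.1.2")
        with pytest.raises(ValueError):
            make_ablation_variants(c, "2.1.1", "3.1", 0)


class TestNamedReactionTestset:
    def test_set_arithmetic_oracle(self):
        c = distinct_corpus(100, year_of=lambda i: 2000 + (i % 10),
                            class_of=lambda i: "3.2.1" if i % 3 == 0 else "1.1.1")
        series = make_time_series(c, [2008], [2003, 2006], 4, 20, 2)
        named = make_named_reaction_testset(c, "3.2.1", series)
        class_ids = c.ids_with_class_prefix("3.2.1")
        assert named == class_ids - series.all_train_ids()
        assert len(named) == len(class_ids) - len(class_ids & series.all_train_ids())
        assert not named & series.all_train_ids()

    def test_class_absent_from_training_returns_all(self):
        c = distinct_corpus(60, year_of=lambda i: 2000 + (i % 10),
                            class_of=lambda i: "9.9.9" if c_late(i) else "1.1.1")
        series = make_time_series(c, [2008], [2002], 3, None, 0)
        named = make_named_reaction_testset(c, "9.9.9", series)
        expected = c.ids_with_class_prefix("9.9.9") - series.all_train_ids()
        assert named == expected


def c_late(i):
    return 2000 + (i % 10) > 2005


class TestAuditSplit:
    def test_detects_canonical_key_leak(self):
        r1 = make_record("r1", reactants=("OCC",), products=("O=CC",), doc="D1")
        r2 = make_record("r2", reactants=("CCO",), products=("CC=O",), doc="D2")
        r3 = make_record("r3", reactants=("CCN",), products=("CCCl",), doc="D3")
        c = Corpus([r1, r2, r3])
        sp = Split("leaky", "reaction", frozenset({"r1", "r3"}), frozenset({"r2"}), 0)
        assert any("canonical key" in p for p in audit_split(sp, c))

    def test_detects_document_straddle(self, tiny_corpus):
        sp = Split("bad", "document", frozenset({"r0"}), frozenset({"r1"}), 0)
        assert any("straddles" in p for p in audit_split(sp, tiny_corpus))

    def test_detects_missing_ids(self, tiny_corpus):
        sp = Split("bad", "reaction", frozenset({"r0"}), frozenset({"zzz"}), 0)
        assert any("not in corpus" in p for p in audit_split(sp, tiny_corpus))

    def test_manifest_round_trip(self, tmp_path, tiny_corpus):
        sp = split_on_reactions(tiny_corpus, 0.25, 9)
        sp.save(tmp_path / "m.json")
        back = Split.load(tmp_path / "m.json")
        assert back.train_ids == sp.train_ids and back.test_ids == sp.test_ids
        assert back.params == sp.params and back.strategy == sp.strategy
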