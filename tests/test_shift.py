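"""Fingerprint spaces and nearest-neighbor shift diagnostics."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from rxnsplits.corpus import Corpus
from rxnsplits.shift import (
    FingerprintParams,
    compare_splits,
    nn_distance_profile,
    reactant_fingerprint,
    reaction_fingerprint,
)
from conftest import make_record


class TestReactantFingerprint:
    def test_permutation_invariance(self):
        a = make_record("a", reactants=("CCO", "CC"), products=("CCC",))
        b = make_record("b", reactants=("CC", "CCO"), products=("CCC",))
        assert np.array_equal(reactant_fingerprint(a), reactant_fingerprint(b))

    def test_single_atom_smoke(self):
        rec = make_record("a", reactants=("C",), products=("CO",))
        v = reactant_fingerprint(rec)
        assert v.sum() > 0 and np.count_nonzero(v) <= 2

    def test_matches_direct_hashed_morgan_counts(self):
        # independent oracle: hashed environment counts computed directly
        rec = make_record("a", reactants=("CCO",), products=("CC=O",))
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        nz = gen.GetCountFingerprint(Chem.MolFromSmiles("CCO")).GetNonzeroElements()
        expected = np.zeros(2048)
        for bit, count in nz.items():
            expected[bit] = count
        assert np.array_equal(reactant_fingerprint(rec), expected)

    def test_agents_excluded_by_default(self):
        a = make_record("a", reactants=("CCO",), agents=("c1ccccc1",), products=("CC=O",))
        b = make_record("b", reactants=("CCO",), products=("CC=O",))
        assert np.array_equal(reactant_fingerprint(a), reactant_fingerprint(b))
        with_agents = reactant_fingerprint(a, FingerprintParams(include_agents=True))
        assert not np.array_equal(with_agents, reactant_fingerprint(a))


class TestReactionFingerprint:
    def test_null_transform_gives_zero_vector(self):
        rec = make_record("a", reactants=("CCO", "CC"), products=("CC", "CCO"))
        assert not reaction_fingerprint(rec).any()

    def test_same_transform_on_homologs_is_close(self):
        # one oxidation applied to two homologous alcohols vs an unrelated
        # amide formation: transform vectors of the homologs must be closer
        from sklearn.metrics.pairwise import cosine_distances

        ox1 = make_record("a", reactants=("CCCCCO",), products=("CCCCC=O",))
        ox2 = make_record("b", reactants=("CCCCCCO",), products=("CCCCCC=O",))
        other = make_record(
            "c", reactants=("CC(=O)O", "NCC"), products=("CCNC(C)=O",)
        )
        f = lambda r: reaction_fingerprint(r).reshape(1, -1)
        d_homolog = cosine_distances(f(ox1), f(ox2))[0, 0]
        assert d_homolog < cosine_distances(f(ox1), f(other))[0, 0]
        assert d_homolog < cosine_distances(f(ox2), f(other))[0, 0]

    def test_product_multiplicity_changes_vector(self):
        one = make_record("a", reactants=("CCO",), products=("CC=O",))
        two = make_record("b", reactants=("CCO",), products=("CC=O", "CC=O"))
        assert not np.array_equal(reaction_fingerprint(one), reaction_fingerprint(two))


def brute_force_profile(corpus, train_ids, test_ids, space, m):
    """Quadratic-scan oracle with the documented tie rule."""
    from sklearn.metrics.pairwise import cosine_distances

    fp = reactant_fingerprint if space == "reactant" else reaction_fingerprint
    out = {}
    for t in sorted(test_ids):
        pairs = []
        for tr in sorted(train_ids):
            d = cosine_distances(
                fp(corpus[t]).reshape(1, -1), fp(corpus[tr]).reshape(1, -1)
            )[0, 0]
            pairs.append((float(d), tr))
        pairs.sort(key=lambda p: (p[0], p[1]))
        out[t] = float(np.mean([d for d, _ in pairs[:m]]))
    return out


class TestNNDistanceProfile:
    def test_identical_reactants_distance_zero(self):
        recs = [
            make_record("t", reactants=("CCO", "CC"), products=("CCC",)),
            make_record("x", reactants=("CC", "CCO"), products=("CCN",), doc="D2"),
            make_record("y", reactants=("CCCCCCCC",), products=("CCC",), doc="D3"),
        ]
        c = Corpus(recs)
        prof = nn_distance_profile(["x", "y"], ["t"], c, space="reactant", m=1)
        assert prof.distances["t"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_fingerprints_distance_one(self):
        # an alkane and an arene share no radius-2 environments, so their
        # count vectors are orthogonal and the cosine distance is exactly 1
        a = make_record("a", reactants=("CCCCC",), products=("CCC",))
        b = make_record("b", reactants=("c1ccccc1",), products=("CCC",), doc="D2")
        assert reactant_fingerprint(a) @ reactant_fingerprint(b) == 0
        c = Corpus([a, b])
        prof = nn_distance_profile(["a"], ["b"], c, space="reactant", m=1)
        assert prof.distances["b"] == pytest.approx(1.0)

    @pytest.mark.parametrize("space", ["reactant", "reaction"])
    def test_matches_quadratic_scan_oracle(self, synth_corpus, space):
        ids = sorted(synth_corpus.record_ids)[:60]
        train, test = ids[:45], ids[45:]
        prof = nn_distance_profile(train, test, synth_corpus, space=space, m=5,
                                   block_size=7)
        expected = brute_force_profile(synth_corpus, train, test, space, 5)
        for rid in test:
            assert prof.distances[rid] == pytest.approx(expected[rid], abs=1e-9)

    def test_distances_within_unit_interval_reactant_space(self, synth_corpus):
        ids = sorted(synth_corpus.record_ids)[:40]
        prof = nn_distance_profile(ids[:30], ids[30:], synth_corpus, m=3)
        assert all(0.0 <= d <= 1.0 + 1e-12 for d in prof.distances.values())

    def test_invariant_to_train_ordering(self, synth_corpus):
        ids = sorted(synth_corpus.record_ids)[:40]
        train, test = ids[:30], ids[30:]
        a = nn_distance_profile(train, test, synth_corpus, m=3)
        b = nn_distance_profile(list(reversed(train)), test, synth_corpus, m=3)
        assert a.distances == b.distances

    def test_m_larger_than_train_rejected(self, tiny_corpus):
        ids = sorted(tiny_corpus.record_ids)
        with pytest.raises(ValueError):
            nn_distance_profile(ids[:2], ids[2:], tiny_corpus, m=3)


class TestCompareSplits:
    def _profile(self, values, space="reactant"):
        from rxnsplits.shift import ShiftProfile

        return ShiftProfile(space=space, m=5,
                            distances={f"r{i}": v for i, v in enumerate(values)})

    def test_identical_profiles_tie(self):
        rep = compare_splits([self._profile([0.2, 0.4]), self._profile([0.2, 0.4])],
                             names=["a", "b"])
        medians = [s["median"] for s in rep["splits"]]
        assert medians[0] == medians[1]

    def test_ordering_easy_to_hard(self):
        rep = compare_splits(
            [self._profile([1.0, 1.0]), self._profile([0.0, 0.0])],
            names=["hard", "easy"],
        )
        assert rep["ranking"] == ["easy", "hard"]

    def test_medians_match_recount_and_hist_sums(self):
        vals = [0.1, 0.5, 0.3, 0.9, 0.2]
        rep = compare_splits([self._profile(vals)], names=["s"])
        assert rep["splits"][0]["median"] == pytest.approx(float(np.median(vals)))
        assert sum(rep["splits"][0]["hist_counts"]) == len(vals)

    def test_mismatched_spaces_rejected(self):
        with pytest.raises(ValueError):
            compare_splits([self._profile([0.1]), self._profile([0.1], space="reaction")])


class TestSplitShiftOrdering:
    def test_author_split_is_farther_than_random_split(self, synth_corpus):
        # the structural premise: holding out whole co-authorship components
        # moves test reactions away from the training distribution
        from rxnsplits.splitters import split_on_authors, split_on_reactions

        spr = split_on_reactions(synth_corpus, 0.2, 5)
        spa = split_on_authors(synth_corpus, 0.2, 5)
        for space in ("reactant", "reaction"):
            pr = nn_distance_profile(spr.train_ids, spr.test_ids, synth_corpus,
                                     space=space, m=5)
            pa = nn_distance_profile(spa.train_ids, spa.test_ids, synth_corpus,
                                     space=space, m=5)
            assert pa.summary()["median"] >= pr.summary()["median"]
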