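import pytest

from rxnsplits.corpus import Corpus, ReactionRecord
from rxnsplits.synthetic import GeneratorConfig, generate_corpus


def make_record(
    rid,
    reactants=("CCO",),
    products=("CC=O",),
    agents=(),
    doc="D1",
    authors=("A1",),
    year=2005,
    class_code="1.1.1",
    transform=None,
):
    return ReactionRecord.create(
        record_id=rid,
        reactants=list(reactants),
        agents=list(agents),
        products=list(products),
        doc_id=doc,
        authors=list(authors),
        year=year,
        class_code=class_code,
        transform=transform,
    )


@pytest.fixture
def tiny_corpus():
    """Four documents, controlled metadata, chemically distinct reactions."""
    mols = ["CCO", "CCC", "CCN", "CCCl", "CCBr", "CC(C)O", "CCCO", "CCCN"]
    records = []
    docs = [("D1", ("Ada", "Bob"), 1999), ("D2", ("Bob", "Cleo"), 2003),
            ("D3", ("Dan",), 2010), ("D4", ("Eve",), 2015)]
    i = 0
    for doc, authors, year in docs:
        for _ in range(2):
            records.append(
                make_record(
                    f"r{i}",
                    reactants=(mols[i % len(mols)],),
                    products=(mols[(i + 3) % len(mols)],),
                    doc=doc,
                    authors=authors,
                    year=year,
                    class_code=["1.1.1", "2.1.2", "3.1.1", "3.1.2"][i % 4],
                )
            )
            i += 1
    return Corpus(records)


@pytest.fixture(scope="session")
def synth_corpus():
    """A small literature-structured corpus shared across test modules."""
    return generate_corpus(GeneratorConfig(n_documents=120, seed=2024))
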