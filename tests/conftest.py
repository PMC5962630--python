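import pytest

from polyclave import (Dependency, Descriptor, KnowledgeBase, TaxonConcept,
                       INAPPLICABLE, load_fixture)


@pytest.fixture(scope="session")
def coccinella():
    """The packaged six-species Coccinella comparison matrix."""
    return load_fixture("coccinella_table4")


@pytest.fixture(scope="session")
def ladybird_taxa():
    return load_fixture("ladybird_taxa")


@pytest.fixture(scope="session")
def ladybird_descriptors():
    return load_fixture("ladybird_descriptors")


def make_binary_split_kb(n_on, n_off, n_inapplicable=0, name="split"):
    """A base with one binary descriptor splitting taxa n_on vs n_off, plus
    optionally some taxa for which the descriptor is inapplicable (driven by
    a presence/absence parent descriptor)."""
    n = n_on + n_off + n_inapplicable
    taxa = [TaxonConcept(id=f"t{i:03d}", name=f"Taxon {i}") for i in range(n)]
    descriptors = [
        Descriptor(id=1, name="structure", states=("Present", "Absent")),
        Descriptor(id=2, name="character", states=("A", "B"),
                   dependency=Dependency(parent_id=1,
                                         triggering_states=frozenset(["Present"]))),
    ]
    descriptions = {}
    for i, t in enumerate(taxa):
        if i < n_on:
            descriptions[(t.id, 1)] = frozenset(["Present"])
            descriptions[(t.id, 2)] = frozenset(["A"])
        elif i < n_on + n_off:
            descriptions[(t.id, 1)] = frozenset(["Present"])
            descriptions[(t.id, 2)] = frozenset(["B"])
        else:
            descriptions[(t.id, 1)] = frozenset(["Absent"])
            descriptions[(t.id, 2)] = INAPPLICABLE
    return KnowledgeBase(name=name, descriptors=descriptors, taxa=taxa,
                         descriptions=descriptions)
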