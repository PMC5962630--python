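"""Random knowledge bases with the structure of a real colour-pattern key.

The generator emulates the statistical shape of the ladybird base: its default
parameters are 66 taxa described by 21 descriptors whose state counts are the
published per-descriptor counts (98 states in total, between 2 and 12 each,
mean 4.67), a dependency forest targeting the published role counts (5
independent descriptors, 4 parents, 14 children, 2 both parent and child),
polymorphic cells, and a fully described matrix (no unknowns) in which no two
taxa share a description.

Dependent descriptors are INAPPLICABLE exactly when the drawn parent cell
misses the triggering states, so generated bases always pass the consistency
check with zero dependency violations.  Everything is driven by one seed and
is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from random import Random
from typing import Sequence

import networkx as nx

from .kb import (INAPPLICABLE, UNKNOWN, Dependency, Descriptor, KnowledgeBase,
                 TaxonConcept)
from .fixtures import load_fixture

__all__ = ["SynthParams", "InfeasibleParamsError", "generate_kb",
           "generate_planted_kb", "ladybird_state_counts"]


class InfeasibleParamsError(ValueError):
    """The requested base cannot be generated (e.g. too few distinct
    descriptions available for the requested number of taxa)."""


def ladybird_state_counts() -> list:
    """Published per-descriptor state counts of the ladybird base (sum 98)."""
    return [int(n) for n in load_fixture("ladybird_descriptors")["n_states"]]


@dataclass(frozen=True)
class SynthParams:
    """Generator controls.  The defaults are the ladybird-base profile.

    ``state_counts`` may be a per-descriptor list; None means the ladybird
    counts when n_descriptors is 21, otherwise counts drawn uniformly from
    2..12.  ``dependency`` is the target (n_independent, n_parents,
    n_children, n_both); None means the ladybird targets for 21 descriptors,
    otherwise no dependencies.  Descriptors left over by the dependency
    targets become independent.
    """

    n_taxa: int = 66
    n_descriptors: int = 21
    state_counts: Sequence | None = None
    polymorphism_prob: float = 0.15
    unknown_prob: float = 0.0
    dependency: tuple | None = None
    enforce_distinct: bool = True
    seed: int = 0
    max_retries: int = 100

    def resolved_state_counts(self, rng: Random) -> list:
        if self.state_counts is not None:
            counts = [int(c) for c in self.state_counts]
            if len(counts) != self.n_descriptors:
                raise InfeasibleParamsError(
                    f"{len(counts)} state counts for {self.n_descriptors} descriptors")
        elif self.n_descriptors == 21:
            counts = ladybird_state_counts()
        else:
            counts = [rng.randint(2, 12) for _ in range(self.n_descriptors)]
        if any(c < 2 for c in counts):
            raise InfeasibleParamsError("every descriptor needs >= 2 states")
        return counts

    def resolved_dependency(self) -> tuple:
        if self.dependency is not None:
            dep = tuple(int(x) for x in self.dependency)
        elif self.n_descriptors == 21:
            dep = (5, 4, 14, 2)
        else:
            dep = (self.n_descriptors, 0, 0, 0)
        ni, n_parents, n_children, n_both = dep
        if not (0 <= n_both <= min(n_parents, n_children)):
            raise InfeasibleParamsError("n_both exceeds parents or children")
        if n_parents > 0 and n_children < n_parents:
            raise InfeasibleParamsError("each parent needs at least one child")
        if n_parents > 0 and n_parents == n_both:
            raise InfeasibleParamsError(
                "every parent is also a child: no root for the forest")
        used = ni + (n_parents - n_both) + (n_children - n_both) + n_both
        if used > self.n_descriptors:
            raise InfeasibleParamsError(
                f"dependency targets need {used} descriptors, "
                f"have {self.n_descriptors}")
        return dep

    def validate(self) -> None:
        if self.n_taxa < 0 or self.n_descriptors < 1:
            raise InfeasibleParamsError("need >= 0 taxa and >= 1 descriptor")
        for p in (self.polymorphism_prob, self.unknown_prob):
            if not 0.0 <= p <= 1.0:
                raise InfeasibleParamsError("probabilities must lie in [0, 1]")
        self.resolved_dependency()


def _build_forest(params: SynthParams, rng: Random, ids: list) -> dict:
    """Assign roles and parents; returns {child_id: parent_id}."""
    _, n_parents, n_children, n_both = params.resolved_dependency()
    if n_parents == 0:
        return {}
    shuffled = rng.sample(ids, len(ids))
    pure_parents = shuffled[: n_parents - n_both]
    both = shuffled[n_parents - n_both: n_parents]
    pure_children = shuffled[n_parents: n_parents + (n_children - n_both)]
    if not pure_parents and both:
        raise InfeasibleParamsError("a dependency forest needs a root parent")

    parent_of: dict = {}
    for i, b in enumerate(both):
        parent_of[b] = rng.choice(pure_parents + both[:i])
    for c in pure_children:
        parent_of[c] = rng.choice(pure_parents + both)

    # every designated parent must actually have a child
    capable = pure_parents + both
    child_count = {p: 0 for p in capable}
    for child, p in parent_of.items():
        child_count[p] += 1
    for p in capable:
        if child_count[p] == 0:
            donors = [c for c in pure_children
                      if child_count[parent_of[c]] > 1 and parent_of[c] != p]
            if not donors:
                raise InfeasibleParamsError("cannot satisfy parent targets")
            c = donors[0]
            child_count[parent_of[c]] -= 1
            parent_of[c] = p
            child_count[p] += 1
    return parent_of


def _draw_row(rng: Random, descriptors: list, topo: list, params: SynthParams) -> dict:
    """One taxon's cells, drawn parent-first along the dependency forest."""
    by_id = {d.id: d for d in descriptors}
    row: dict = {}
    for did in topo:
        d = by_id[did]
        if d.dependency is not None:
            parent_cell = row[d.dependency.parent_id]
            if not (isinstance(parent_cell, frozenset)
                    and parent_cell & d.dependency.triggering_states):
                row[did] = INAPPLICABLE
                continue
        if params.unknown_prob and rng.random() < params.unknown_prob:
            row[did] = UNKNOWN
            continue
        size = 2 if rng.random() < params.polymorphism_prob else 1
        row[did] = frozenset(rng.sample(d.states, min(size, d.n_states)))
    return row


def generate_kb(params: SynthParams | None = None, **overrides) -> KnowledgeBase:
    """Generate a reproducible random knowledge base.

    With ``enforce_distinct`` the rows of duplicated descriptions are redrawn
    (bounded by ``max_retries``) until no two taxa share a description;
    parameters that cannot yield enough distinct descriptions raise
    InfeasibleParamsError.
    """
    if params is None:
        params = SynthParams(**overrides)
    elif overrides:
        raise TypeError("pass either params or keyword overrides, not both")
    params.validate()
    rng = Random(params.seed)

    ids = list(range(1, params.n_descriptors + 1))
    counts = params.resolved_state_counts(rng)
    parent_of = _build_forest(params, rng, ids)

    descriptors = []
    vocab = {i: tuple(f"d{i}_s{j}" for j in range(1, counts[k] + 1))
             for k, i in enumerate(ids)}
    for i in ids:
        dep = None
        if i in parent_of:
            p = parent_of[i]
            dep = Dependency(parent_id=p,
                             triggering_states=frozenset([rng.choice(vocab[p])]))
        descriptors.append(Descriptor(id=i, name=f"Descriptor {i}",
                                      states=vocab[i], dependency=dep))

    graph = nx.DiGraph()
    graph.add_nodes_from(ids)
    graph.add_edges_from((p, c) for c, p in parent_of.items())
    topo = list(nx.topological_sort(graph))

    taxa = [TaxonConcept(id=f"t{i:03d}", name=f"Taxon {i}",
                         genus=f"genus{(i - 1) // 3 + 1}", tribe="synthetic")
            for i in range(1, params.n_taxa + 1)]
    rows = {t.id: _draw_row(rng, descriptors, topo, params) for t in taxa}

    if params.enforce_distinct and params.n_taxa > 1:
        for _ in range(params.max_retries):
            seen: dict = {}
            clashing = []
            for t in taxa:
                vec = tuple(sorted((d, _canon(c)) for d, c in rows[t.id].items()))
                if vec in seen:
                    clashing.append(t.id)
                else:
                    seen[vec] = t.id
            if not clashing:
                break
            for tid in clashing:
                rows[tid] = _draw_row(rng, descriptors, topo, params)
        else:
            raise InfeasibleParamsError(
                f"could not draw {params.n_taxa} distinct descriptions in "
                f"{params.max_retries} retries; the descriptive model is too small")

    descriptions = {(tid, did): cell
                    for tid, row in rows.items() for did, cell in row.items()}
    return KnowledgeBase(name=f"synthetic(seed={params.seed})",
                         descriptors=descriptors, taxa=taxa,
                         descriptions=descriptions)


def _canon(cell):
    if isinstance(cell, frozenset):
        return ("S", tuple(sorted(cell)))
    return repr(cell)


def generate_planted_kb(n_planted: int = 5, n_constant: int = 3) -> tuple:
    """Base with a known minimal sufficient descriptor set, for oracle tests.

    Builds n_planted binary descriptors and n_planted + 1 taxa: a reference
    taxon and, per planted descriptor, one taxon differing from the reference
    on that descriptor alone — so each planted descriptor is the only
    separator of one pair and the unique minimum cover is the full planted
    set.  ``n_constant`` additional descriptors are constant noise.  Returns
    (kb, planted_ids).
    """
    if n_planted < 1:
        raise ValueError("need at least one planted descriptor")
    planted = list(range(1, n_planted + 1))
    constant = list(range(n_planted + 1, n_planted + n_constant + 1))
    descriptors = [Descriptor(id=i, name=f"Planted {i}",
                              states=(f"d{i}_s1", f"d{i}_s2")) for i in planted]
    descriptors += [Descriptor(id=i, name=f"Constant {i}",
                               states=(f"d{i}_s1", f"d{i}_s2")) for i in constant]
    taxa = [TaxonConcept(id=f"t{i:03d}", name=f"Taxon {i}", genus="genus1",
                         tribe="synthetic") for i in range(n_planted + 1)]
    constant_states = {i: frozenset([f"d{i}_s1"]) for i in constant}
    descriptions = {}
    for k, t in enumerate(taxa):
        for i in planted:
            flipped = (k == i)  # taxon k differs from reference on descriptor k
            descriptions[(t.id, i)] = frozenset([f"d{i}_s2" if flipped
                                                 else f"d{i}_s1"])
        for i in constant:
            descriptions[(t.id, i)] = constant_states[i]
    kb = KnowledgeBase(name=f"planted(k={n_planted})", descriptors=descriptors,
                       taxa=taxa, descriptions=descriptions)
    return kb, set(planted)
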