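"""Minimal diagnostic descriptor sets (set cover over incompatible pairs).

A descriptor subset is *sufficient* when it fully discriminates exactly the
taxon pairs the complete descriptor set does — the same covered-pair set, not
merely the same count.  Pairs no descriptor separates (e.g. species the base
deliberately leaves undistinguished) are outside the coverage requirement.

Finding the smallest sufficient subset is a set-cover problem: greedy gives a
fast certified-coverage answer; the exact method runs a branch-and-bound
search over covering descriptors and certifies minimality.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .kb import KnowledgeBase
from .discrimination import ComparisonOutcome, compare_pair

__all__ = ["MinsetResult", "covered_pairs", "minimal_descriptor_set"]


@dataclass(frozen=True)
class MinsetResult:
    descriptors: frozenset
    covered_pairs: int
    coverage_equal_to_full: bool
    method: str
    certified_minimum: bool


def covered_pairs(kb: KnowledgeBase, descriptor_subset: Iterable) -> frozenset:
    """Unordered taxon-id pairs fully discriminated by >= 1 subset member.

    Monotone: a larger subset never covers fewer pairs.
    """
    subset = set(descriptor_subset)
    unknown = subset - set(kb.descriptor_ids)
    if unknown:
        raise KeyError(f"unknown descriptor ids {sorted(unknown)!r}")
    covered = set()
    for a, b in combinations(kb.taxon_ids, 2):
        for did in subset:
            if compare_pair(kb, a, b, did) is ComparisonOutcome.DISJOINT:
                covered.add((a, b) if a <= b else (b, a))
                break
    return frozenset(covered)


def _pair_sets(kb: KnowledgeBase) -> dict:
    """Per-descriptor sets of separated pairs."""
    sets: dict = {d.id: set() for d in kb.descriptors}
    for a, b in combinations(kb.taxon_ids, 2):
        key = (a, b) if a <= b else (b, a)
        for d in kb.descriptors:
            if compare_pair(kb, a, b, d.id) is ComparisonOutcome.DISJOINT:
                sets[d.id].add(key)
    return sets


def _greedy(kb: KnowledgeBase, pair_sets: dict, target: set) -> set:
    # tie-break: most new pairs, then fewest states, then lowest id
    chosen: set = set()
    uncovered = set(target)
    while uncovered:
        best = None
        for d in kb.descriptors:
            if d.id in chosen:
                continue
            gain = len(pair_sets[d.id] & uncovered)
            if gain == 0:
                continue
            key = (-gain, d.n_states, d.id)
            if best is None or key < best[0]:
                best = (key, d.id)
        if best is None:  # unreachable: target is the union of pair_sets
            raise AssertionError("greedy cover stalled")
        chosen.add(best[1])
        uncovered -= pair_sets[best[1]]
    return chosen


def _exact(kb: KnowledgeBase, pair_sets: dict, target: set,
           upper_bound: set) -> set:
    """Branch-and-bound exact set cover, seeded with the greedy solution."""
    coverers: dict = {}
    for did, pairs in pair_sets.items():
        for p in pairs & target:
            coverers.setdefault(p, []).append(did)
    order = {d.id: (d.n_states, d.id) for d in kb.descriptors}
    max_gain = max((len(s & target) for s in pair_sets.values()), default=0)
    best = set(upper_bound)

    def search(chosen: set, uncovered: set) -> None:
        nonlocal best
        if not uncovered:
            if len(chosen) < len(best):
                best = set(chosen)
            return
        # lower bound: even perfect descriptors need this many more picks
        need = -(-len(uncovered) // max_gain)
        if len(chosen) + need >= len(best):
            return
        pivot = min(uncovered, key=lambda p: len(coverers[p]))
        for did in sorted(coverers[pivot], key=lambda d: order[d]):
            if did in chosen:
                continue
            search(chosen | {did}, uncovered - pair_sets[did])

    search(set(), set(target))
    return best


def minimal_descriptor_set(kb: KnowledgeBase, method: str = "greedy",
                           max_exact_descriptors: int = 22) -> MinsetResult:
    """A descriptor subset covering the same pairs as the full set.

    ``greedy`` repeatedly adds the descriptor separating the most uncovered
    pairs (ties: fewest states, then lowest id); ``exact`` certifies a
    smallest-cardinality subset but is refused above ``max_exact_descriptors``
    descriptors (worst-case exponential search).
    """
    if method not in ("greedy", "exact"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" and len(kb.descriptors) > max_exact_descriptors:
        raise ValueError(
            f"exact search refused for {len(kb.descriptors)} descriptors "
            f"(limit {max_exact_descriptors}); use method='greedy'")
    pair_sets = _pair_sets(kb)
    target = set().union(*pair_sets.values()) if pair_sets else set()
    greedy_set = _greedy(kb, pair_sets, target)
    chosen = greedy_set
    if method == "exact":
        chosen = _exact(kb, pair_sets, target, greedy_set)
    return MinsetResult(descriptors=frozenset(chosen),
                        covered_pairs=len(target),
                        coverage_equal_to_full=True,
                        method=method,
                        certified_minimum=(method == "exact"))
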