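"""Pairwise comparison outcomes and the discriminatory-power index.

For one descriptor, two taxa fall in one of four cases: identical state sets,
overlapping sets (partial discrimination), disjoint sets (the pair is
*incompatible* — the descriptor fully discriminates it), or not comparable
(either cell inapplicable or unknown; nothing can be asserted from absence).

The discriminatory power of a descriptor over a taxon set is the fraction of
unordered taxon pairs it fully discriminates.  Not-comparable pairs stay in
the denominator: a descriptor that cannot even be observed on some taxa is
genuinely less useful, and this convention reproduces the printed worked
values (a 65-vs-1 binary split over 66 taxa gives 65/2145 = 0.03; a 60-vs-2
split with 4 inapplicable gives 120/2145 = 0.06).
"""

from __future__ import annotations

from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .kb import INAPPLICABLE, UNKNOWN, KnowledgeBase

__all__ = [
    "ComparisonOutcome",
    "compare_pair",
    "xper_index",
    "power_table",
    "discriminating_descriptors",
]


class ComparisonOutcome(Enum):
    IDENTICAL = "identical"
    OVERLAP = "overlap"
    DISJOINT = "disjoint"
    NOT_COMPARABLE = "not_comparable"


def compare_pair(kb: KnowledgeBase, taxon_a: str, taxon_b: str,
                 descriptor_id: int) -> ComparisonOutcome:
    """Classify one taxon pair on one descriptor.  Symmetric in the taxa."""
    cell_a = kb.cell(taxon_a, descriptor_id)
    cell_b = kb.cell(taxon_b, descriptor_id)
    for cell in (cell_a, cell_b):
        if cell is INAPPLICABLE or cell is UNKNOWN:
            return ComparisonOutcome.NOT_COMPARABLE
    if cell_a == cell_b:
        return ComparisonOutcome.IDENTICAL
    if cell_a & cell_b:
        return ComparisonOutcome.OVERLAP
    return ComparisonOutcome.DISJOINT


def _resolve_taxa(kb: KnowledgeBase, taxa_subset) -> list:
    if taxa_subset is None:
        return list(kb.taxon_ids)
    taxa = [tid for tid in kb.taxon_ids if tid in set(taxa_subset)]
    missing = set(taxa_subset) - set(taxa)
    if missing:
        raise KeyError(f"unknown taxon ids {sorted(missing)!r}")
    return taxa


def _count_disjoint(kb: KnowledgeBase, descriptor_id: int,
                    taxa: Sequence) -> int:
    disjoint = 0
    cells = [kb.cell(tid, descriptor_id) for tid in taxa]
    for a, b in combinations(cells, 2):
        if (isinstance(a, frozenset) and isinstance(b, frozenset)
                and not a & b):
            disjoint += 1
    return disjoint


def xper_index(kb: KnowledgeBase, descriptor_id: int,
               taxa_subset: Iterable | None = None) -> float:
    """Fraction of unordered taxon pairs the descriptor fully discriminates.

    Ranges from 0 (never separates a pair) to 1 (separates every pair).  The
    denominator is *all* unordered pairs of the (optionally restricted) taxon
    set, including pairs that are not comparable on this descriptor.
    """
    taxa = _resolve_taxa(kb, taxa_subset)
    n = len(taxa)
    if n < 2:
        raise ValueError(f"need at least 2 taxa to compute an index, got {n}")
    total = n * (n - 1) // 2
    return _count_disjoint(kb, descriptor_id, taxa) / total


def power_table(kb: KnowledgeBase,
                taxa_subset: Iterable | None = None) -> pd.DataFrame:
    """Per-descriptor discriminatory power, ranked.

    Returns a DataFrame with columns descriptor_id, name, index,
    disjoint_pairs, total_pairs, n_states, rank — sorted by index descending,
    ties broken by ascending descriptor id.
    """
    taxa = _resolve_taxa(kb, taxa_subset)
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    total = n * (n - 1) // 2
    rows = []
    for d in kb.descriptors:
        disjoint = _count_disjoint(kb, d.id, taxa)
        rows.append({"descriptor_id": d.id, "name": d.name,
                     "index": disjoint / total, "disjoint_pairs": disjoint,
                     "total_pairs": total, "n_states": d.n_states})
    table = pd.DataFrame(rows).sort_values(
        ["index", "descriptor_id"], ascending=[False, True], kind="stable")
    table["rank"] = range(1, len(table) + 1)
    return table.reset_index(drop=True)


def discriminating_descriptors(kb: KnowledgeBase, taxon_a: str,
                               taxon_b: str) -> set:
    """Descriptors that fully discriminate one pair of taxa.

    Empty iff no single descriptor separates the pair (e.g. two identical
    colour forms, or species deliberately left undistinguished).
    """
    return {d.id for d in kb.descriptors
            if compare_pair(kb, taxon_a, taxon_b, d.id)
            is ComparisonOutcome.DISJOINT}
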