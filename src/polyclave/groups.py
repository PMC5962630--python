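"""Within-group and between-group comparison of taxon descriptions.

Within a group (typically a genus) each descriptor is summarised by the union
and intersection of the members' state sets and classified as *informative*
(at least two members have unequal cells) or *constant*.  Here an
INAPPLICABLE cell counts as a distinct value of its own: a descriptor that is
recorded for some members and structurally absent in others does vary within
the group.  UNKNOWN cells carry no information and are excluded.

Note the deliberate asymmetry with the discriminatory-power index, where a
not-comparable pair never counts as discriminated: informativeness asks
whether members *differ*, the index asks whether a pair can be *told apart*
by observing the character.

Between groups, the variability table reports per group the number of
informative descriptors, as a percentage of all descriptors and weighted by
the number of items (colour forms) in the group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import pandas as pd

from .kb import (INAPPLICABLE, UNKNOWN, KnowledgeBase, _Marker, round_half_up)

__all__ = [
    "DescriptorGroupSummary",
    "group_summary",
    "informative_descriptors",
    "group_matrix",
    "variability_table",
]


@dataclass(frozen=True)
class DescriptorGroupSummary:
    """Union/intersection/informativeness of one descriptor over a group."""

    descriptor_id: int
    union: frozenset
    union_includes_inapplicable: bool
    intersection: Union[frozenset, _Marker]
    informative: bool


def _known_cells(kb: KnowledgeBase, taxa: list, descriptor_id: int) -> list:
    return [kb.cell(tid, descriptor_id) for tid in taxa
            if kb.cell(tid, descriptor_id) is not UNKNOWN]


def group_summary(kb: KnowledgeBase, taxa_group: Iterable) -> list:
    """Per-descriptor union, intersection and informative flag for a group.

    The intersection is the set of states shared by *every* member with a
    known cell; it is the INAPPLICABLE marker when the descriptor is
    inapplicable to all of them, and empty when applicability is mixed (no
    state is common to members that include a structural absence).
    """
    taxa = [tid for tid in kb.taxon_ids if tid in set(taxa_group)]
    missing = set(taxa_group) - set(taxa)
    if missing:
        raise KeyError(f"unknown taxon ids {sorted(missing)!r}")
    if not taxa:
        raise ValueError("empty taxon group")

    out = []
    for d in kb.descriptors:
        cells = _known_cells(kb, taxa, d.id)
        state_sets = [c for c in cells if isinstance(c, frozenset)]
        any_na = any(c is INAPPLICABLE for c in cells)

        union = frozenset().union(*state_sets) if state_sets else frozenset()
        if cells and not state_sets:          # inapplicable across the board
            intersection: Union[frozenset, _Marker] = INAPPLICABLE
        elif any_na or not state_sets:
            intersection = frozenset()
        else:
            inter = set(state_sets[0])
            for c in state_sets[1:]:
                inter &= c
            intersection = frozenset(inter)

        # distinct known values, with INAPPLICABLE as a value of its own
        values = {c if isinstance(c, frozenset) else INAPPLICABLE for c in cells}
        informative = len(values) >= 2

        out.append(DescriptorGroupSummary(
            descriptor_id=d.id, union=union,
            union_includes_inapplicable=any_na,
            intersection=intersection, informative=informative))
    return out


def informative_descriptors(kb: KnowledgeBase, taxa_group: Iterable) -> set:
    return {s.descriptor_id for s in group_summary(kb, taxa_group)
            if s.informative}


def _render_cell(kb: KnowledgeBase, descriptor, cell) -> str:
    if cell is UNKNOWN:
        return ""
    if cell is INAPPLICABLE:
        return "not applicable"
    ordered = [s for s in descriptor.states if s in cell]
    ordered += sorted(cell - set(descriptor.states))
    return "; ".join(ordered)


def group_matrix(kb: KnowledgeBase, taxa_group: Iterable) -> pd.DataFrame:
    """Printable comparison table: descriptor rows, member columns, plus
    UNION / INTERSECTION / informative columns."""
    taxa = [tid for tid in kb.taxon_ids if tid in set(taxa_group)]
    summaries = {s.descriptor_id: s for s in group_summary(kb, taxa_group)}
    rows = []
    for d in kb.descriptors:
        s = summaries[d.id]
        row = {"descriptor": f"{d.id}. {d.name}"}
        for tid in taxa:
            row[tid] = _render_cell(kb, d, kb.cell(tid, d.id))
        union = _render_cell(kb, d, s.union) if s.union else ""
        if s.union_includes_inapplicable:
            union = (union + "; not applicable") if union else "not applicable"
        row["UNION"] = union
        if s.intersection is INAPPLICABLE:
            row["INTERSECTION"] = "not applicable"
        else:
            row["INTERSECTION"] = _render_cell(kb, d, s.intersection)
        row["informative"] = s.informative
        rows.append(row)
    return pd.DataFrame(rows)


def variability_table(kb: KnowledgeBase, group_by: str = "genus") -> pd.DataFrame:
    """Between-group variability, one row per value of a taxon attribute.

    Columns: group, n_species (distinct scientific names), n_forms (items in
    the group, i.e. colour forms studied), n_discriminating (informative
    descriptors within the group), pct_discriminating (percent of all
    descriptors, half-up to integer) and weighted (n_discriminating / n_forms,
    half-up to one decimal).  Groups with a single item cannot be compared
    internally and get missing values.  Rows are sorted multi-species groups
    first, then alphabetically, matching the printed presentation.
    """
    groups: dict = {}
    for t in kb.taxa:
        key = getattr(t, group_by, None)
        if key is None or key == "":
            raise ValueError(f"taxon {t.id!r} lacks attribute {group_by!r}")
        groups.setdefault(key, []).append(t)

    n_desc = len(kb.descriptors)
    rows = []
    for label in sorted(groups):
        members = groups[label]
        n_items = len(members)
        n_species = len({t.name for t in members})
        if n_items >= 2:
            n_disc = len(informative_descriptors(kb, [t.id for t in members]))
            pct = int(round_half_up(100.0 * n_disc / n_desc))
            weighted = round_half_up(n_disc / n_items, 1)
        else:
            n_disc = pd.NA
            pct = pd.NA
            weighted = pd.NA
        rows.append({"group": label, "n_species": n_species,
                     "n_forms": n_items, "n_discriminating": n_disc,
                     "pct_discriminating": pct, "weighted": weighted})
    table = pd.DataFrame(rows)
    table = table.astype({"n_discriminating": "Int64",
                          "pct_discriminating": "Int64",
                          "weighted": "Float64"})
    table["_single"] = table["n_species"] < 2
    table = table.sort_values(["_single", "group"], kind="stable")
    return table.drop(columns="_single").reset_index(drop=True)


def format_variability(table: pd.DataFrame) -> pd.DataFrame:
    """Render the variability table the way comparison tables are printed:
    single-species groups get an em-dash in the comparison columns."""
    out = table.copy()
    for col in ("n_discriminating", "pct_discriminating", "weighted"):
        out[col] = out[col].astype(object)
    for i, row in out.iterrows():
        if row["n_species"] < 2 or pd.isna(row["n_discriminating"]):
            out.loc[i, ["n_discriminating", "pct_discriminating", "weighted"]] = "–"
        else:
            out.loc[i, "pct_discriminating"] = f"{row['pct_discriminating']}%"
    return out
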