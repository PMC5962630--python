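"""Single-access (branching) identification key induction and statistics.

A single-access key is a tree of questions: each internal node asks one
descriptor, each branch fixes one observed state, each leaf names the taxa
compatible with every choice on the path.  The builder is greedy: at every
node it picks, among the descriptors that are applicable to and known for all
remaining taxa and not yet asked on the path, the one with the highest
discriminatory-power index restricted to the remaining taxa (ties: fewer
states, then lower id).

Polymorphic taxa follow every branch whose state they possess, so one taxon
can be reachable along several paths — the per-taxon statistics (number of
paths, shortest/longest/mean path length) quantify that.  A leaf with more
than one taxon is *unresolved*: its taxa cannot be told apart by any
descriptor that is observable for all of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean

import pandas as pd

from .kb import UNKNOWN, KnowledgeBase, is_applicable

__all__ = ["KeyNode", "KeyStats", "build_key", "key_statistics", "export_key"]


@dataclass
class KeyNode:
    """Internal node (descriptor_id + branches) or leaf (taxa + resolved)."""

    descriptor_id: int | None = None
    branches: dict | None = None          # state label -> KeyNode
    taxa: frozenset | None = None
    resolved: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.descriptor_id is None


@dataclass(frozen=True)
class KeyStats:
    """Per-taxon path statistics plus the global summary.

    ``per_taxon`` is a DataFrame with columns taxon, n_paths, min_len,
    max_len, mean_len; a step is one internal node traversed.  Global
    mean_steps averages the per-taxon mean lengths.
    """

    per_taxon: pd.DataFrame
    mean_steps: float
    steps_range: tuple
    mean_paths: float
    paths_range: tuple


def _disjoint_pairs(cells: list) -> int:
    n = 0
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if not cells[i] & cells[j]:
                n += 1
    return n


def _pick_descriptor(kb: KnowledgeBase, remaining: list, used: set):
    """Best usable descriptor at a node, or None if nothing separates."""
    best = None
    for d in kb.descriptors:
        if d.id in used:
            continue
        cells = []
        ok = True
        for tid in remaining:
            cell = kb.cell(tid, d.id)
            if cell is UNKNOWN or not is_applicable(kb, tid, d.id) \
                    or not isinstance(cell, frozenset):
                ok = False
                break
            cells.append(cell)
        if not ok:
            continue
        if all(c == cells[0] for c in cells):
            continue                       # separates nothing
        total = len(remaining) * (len(remaining) - 1) // 2
        score = _disjoint_pairs(cells) / total
        key = (-score, d.n_states, d.id)
        if best is None or key < best[0]:
            best = (key, d)
    return None if best is None else best[1]


def build_key(kb: KnowledgeBase, score: str = "xper") -> KeyNode:
    """Greedy polytomous key over all taxa of the base.

    Only the discriminatory-power ("xper") node score is implemented; the
    parameter is an extension point.  Descriptors never repeat along a path.
    Deterministic: identical bases give identical keys.
    """
    if score != "xper":
        raise ValueError(f"unknown score {score!r}")
    if not kb.taxa:
        raise ValueError("cannot build a key over an empty base")

    def grow(remaining: list, used: set) -> KeyNode:
        if len(remaining) == 1:
            return KeyNode(taxa=frozenset(remaining), resolved=True)
        d = _pick_descriptor(kb, remaining, used)
        if d is None:
            return KeyNode(taxa=frozenset(remaining), resolved=False)
        branches = {}
        for state in d.states:
            members = [tid for tid in remaining if state in kb.cell(tid, d.id)]
            if members:
                branches[state] = grow(members, used | {d.id})
        return KeyNode(descriptor_id=d.id, branches=branches)

    return grow(list(kb.taxon_ids), set())


def _walk_paths(node: KeyNode, depth: int, out: list) -> None:
    if node.is_leaf:
        out.append((depth, node))
        return
    for child in node.branches.values():
        _walk_paths(child, depth + 1, out)


def key_statistics(key: KeyNode, kb: KnowledgeBase) -> KeyStats:
    """Number and lengths of root-to-leaf paths per taxon, plus global means."""
    leaves: list = []
    _walk_paths(key, 0, leaves)
    lengths: dict = {tid: [] for tid in kb.taxon_ids}
    for depth, leaf in leaves:
        for tid in leaf.taxa:
            lengths[tid].append(depth)
    rows = []
    for tid in kb.taxon_ids:
        ls = lengths[tid]
        if not ls:
            raise RuntimeError(f"taxon {tid!r} unreachable in the key")
        rows.append({"taxon": tid, "n_paths": len(ls), "min_len": min(ls),
                     "max_len": max(ls), "mean_len": mean(ls)})
    per_taxon = pd.DataFrame(rows)
    return KeyStats(
        per_taxon=per_taxon,
        mean_steps=float(per_taxon["mean_len"].mean()),
        steps_range=(int(per_taxon["min_len"].min()),
                     int(per_taxon["max_len"].max())),
        mean_paths=float(per_taxon["n_paths"].mean()),
        paths_range=(int(per_taxon["n_paths"].min()),
                     int(per_taxon["n_paths"].max())),
    )


def export_key(key: KeyNode, kb: KnowledgeBase, format: str = "text") -> str:
    """Render a key as indented numbered couplets or as a DOT digraph."""
    if format == "text":
        return _export_text(key, kb)
    if format == "dot":
        return _export_dot(key, kb)
    raise ValueError(f"unknown format {format!r}")


def _leaf_label(kb: KnowledgeBase, leaf: KeyNode) -> str:
    names = []
    for tid in sorted(leaf.taxa):
        t = kb.taxon(tid)
        names.append(t.name if t.form is None else f"{t.name} f. {t.form}")
    label = "; ".join(names)
    if not leaf.resolved and len(leaf.taxa) > 1:
        label += " (unresolved)"
    return label


def _export_text(key: KeyNode, kb: KnowledgeBase) -> str:
    if key.is_leaf:
        return _leaf_label(kb, key) + "\n"
    numbers: dict = {}

    def number(node: KeyNode) -> None:
        if node.is_leaf:
            return
        numbers[id(node)] = len(numbers) + 1
        for child in node.branches.values():
            number(child)

    number(key)
    lines: list = []

    def emit(node: KeyNode) -> None:
        step = numbers[id(node)]
        name = kb.descriptor(node.descriptor_id).name
        lines.append(f"{step}. {name}")
        for state, child in node.branches.items():
            if child.is_leaf:
                lines.append(f"   = {state} → {_leaf_label(kb, child)}")
            else:
                lines.append(f"   = {state} → {numbers[id(child)]}")
        for child in node.branches.values():
            if not child.is_leaf:
                emit(child)

    emit(key)
    return "\n".join(lines) + "\n"


def _dot_quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _export_dot(key: KeyNode, kb: KnowledgeBase) -> str:
    lines = ["digraph identification_key {", "  node [shape=box];"]
    counter = [0]

    def emit(node: KeyNode) -> str:
        name = f"n{counter[0]}"
        counter[0] += 1
        if node.is_leaf:
            shape = "ellipse" if node.resolved else "octagon"
            lines.append(f"  {name} [shape={shape}, "
                         f"label={_dot_quote(_leaf_label(kb, node))}];")
            return name
        label = kb.descriptor(node.descriptor_id).name
        lines.append(f"  {name} [label={_dot_quote(label)}];")
        for state, child in node.branches.items():
            child_name = emit(child)
            lines.append(f"  {name} -> {child_name} "
                         f"[label={_dot_quote(state)}];")
        return name

    emit(key)
    lines.append("}")
    return "\n".join(lines) + "\n"
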