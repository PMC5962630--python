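"""Core knowledge-base model for descriptive taxonomy.

A knowledge base couples a *descriptive model* — a list of categorical
descriptors (characters), each with a finite vocabulary of states and an
optional dependency on a parent descriptor — with *descriptions*: for every
taxon and every descriptor either a non-empty set of states (possibly several,
recording intraspecific polymorphism), an explicit "inapplicable" marker, or
"unknown".

Dependencies encode conditional characters: "Shape of the scutellar spot" only
means something when "Scutellar spot" is Present.  The dependency links must
form a forest; applicability is evaluated recursively along it.

This module provides the data types, JSON and CSV-matrix input/output,
applicability evaluation, consistency checking (completeness, duplicate
descriptions, dependency violations) and summary statistics.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

__all__ = [
    "INAPPLICABLE",
    "UNKNOWN",
    "CellValue",
    "Dependency",
    "Descriptor",
    "TaxonConcept",
    "KnowledgeBase",
    "CheckReport",
    "BaseStatistics",
    "KBValidationError",
    "KBParseError",
    "is_applicable",
    "check_base",
    "base_statistics",
    "state_count_summary",
    "read_kb",
    "write_kb",
    "round_half_up",
]


class KBValidationError(ValueError):
    """A knowledge base violates a structural invariant."""


class KBParseError(ValueError):
    """A knowledge-base file could not be parsed."""


class _Marker:
    """Singleton cell marker (inapplicable / unknown)."""

    __slots__ = ("_label",)

    def __init__(self, label: str) -> None:
        self._label = label

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self._label


#: The descriptor does not apply to the taxon (e.g. spot shape of a spotless
#: species).  A recorded, expected absence: counts as *complete* in checks.
INAPPLICABLE = _Marker("INAPPLICABLE")

#: Nothing recorded.  Counts as incomplete; never asserts anything.
UNKNOWN = _Marker("UNKNOWN")

#: A cell is either a non-empty frozenset of state labels or one of the markers.
CellValue = Union[frozenset, _Marker]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention of printed tables.

    Python's builtin ``round`` uses banker's rounding (3.25 -> 3.2); printed
    taxonomic reports round 3.25 -> 3.3 and 76.19 -> 76.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Dependency:
    """Link making a descriptor conditional on a parent descriptor's states."""

    parent_id: int
    triggering_states: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "triggering_states", frozenset(self.triggering_states))


@dataclass(frozen=True)
class Descriptor:
    """A categorical character with a finite, ordered state vocabulary."""

    id: int
    name: str
    states: tuple
    category: str = "other"
    dependency: Dependency | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class TaxonConcept:
    """A unit to be identified: a species or an intraspecific colour form."""

    id: str
    name: str
    genus: str = ""
    tribe: str = ""
    form: str | None = None
    is_form: bool = False


def _as_cell(value) -> CellValue:
    if value is INAPPLICABLE or value is UNKNOWN:
        return value
    return frozenset(value)


class KnowledgeBase:
    """Descriptors + taxa + the full taxon-by-descriptor description matrix.

    Missing (taxon, descriptor) entries are filled with UNKNOWN at
    construction, so every pair always has a cell.  Instances are treated as
    immutable after construction.
    """

    def __init__(self, name, descriptors, taxa, descriptions, validate=True,
                 require_min_states=True):
        self.name = str(name)
        self.descriptors = [d if isinstance(d, Descriptor) else Descriptor(**d)
                            for d in descriptors]
        self.taxa = [t if isinstance(t, TaxonConcept) else TaxonConcept(**t)
                     for t in taxa]
        self._desc_by_id = {d.id: d for d in self.descriptors}
        self._taxon_by_id = {t.id: t for t in self.taxa}
        self.descriptions = {}
        for (tid, did), value in descriptions.items():
            self.descriptions[(tid, did)] = _as_cell(value)
        for t in self.taxa:
            for d in self.descriptors:
                self.descriptions.setdefault((t.id, d.id), UNKNOWN)
        if validate:
            self.validate(require_min_states=require_min_states)

    # -- access -----------------------------------------------------------

    @property
    def descriptor_ids(self) -> list:
        return [d.id for d in self.descriptors]

    @property
    def taxon_ids(self) -> list:
        return [t.id for t in self.taxa]

    def descriptor(self, descriptor_id: int) -> Descriptor:
        try:
            return self._desc_by_id[descriptor_id]
        except KeyError:
            raise KeyError(f"unknown descriptor id {descriptor_id!r}") from None

    def taxon(self, taxon_id: str) -> TaxonConcept:
        try:
            return self._taxon_by_id[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon id {taxon_id!r}") from None

    def cell(self, taxon_id: str, descriptor_id: int) -> CellValue:
        self.taxon(taxon_id)
        self.descriptor(descriptor_id)
        return self.descriptions[(taxon_id, descriptor_id)]

    def description_vector(self, taxon_id: str) -> tuple:
        """Canonical, hashable full description of one taxon (for equality)."""
        out = []
        for d in self.descriptors:
            cell = self.descriptions[(taxon_id, d.id)]
            if cell is INAPPLICABLE:
                out.append("NA")
            elif cell is UNKNOWN:
                out.append(None)
            else:
                out.append(tuple(sorted(cell)))
        return tuple(out)

    # -- validation -------------------------------------------------------

    def validate(self, require_min_states: bool = True) -> None:
        seen = set()
        for d in self.descriptors:
            if not isinstance(d.id, int) or d.id <= 0:
                raise KBValidationError(f"descriptor id must be a positive integer, got {d.id!r}")
            if d.id in seen:
                raise KBValidationError(f"duplicate descriptor id {d.id}")
            seen.add(d.id)
            if len(set(d.states)) != len(d.states):
                raise KBValidationError(f"descriptor {d.id}: repeated state labels")
            if require_min_states and len(d.states) < 2:
                raise KBValidationError(
                    f"descriptor {d.id} ({d.name!r}): needs at least 2 states")
            if d.dependency is not None:
                dep = d.dependency
                if dep.parent_id == d.id:
                    raise KBValidationError(f"descriptor {d.id}: depends on itself")
                if dep.parent_id not in self._desc_by_id:
                    raise KBValidationError(
                        f"descriptor {d.id}: unknown parent {dep.parent_id}")
                parent = self._desc_by_id[dep.parent_id]
                if not dep.triggering_states:
                    raise KBValidationError(f"descriptor {d.id}: empty triggering set")
                bad = dep.triggering_states - set(parent.states)
                if bad:
                    raise KBValidationError(
                        f"descriptor {d.id}: triggering states {sorted(bad)} "
                        f"not in parent {parent.id}'s vocabulary")

        graph = nx.DiGraph()
        graph.add_nodes_from(self._desc_by_id)
        for d in self.descriptors:
            if d.dependency is not None:
                graph.add_edge(d.dependency.parent_id, d.id)
        if not nx.is_directed_acyclic_graph(graph):
            raise KBValidationError("descriptor dependencies contain a cycle")

        seen_taxa = set()
        for t in self.taxa:
            if t.id in seen_taxa:
                raise KBValidationError(f"duplicate taxon id {t.id!r}")
            seen_taxa.add(t.id)

        for (tid, did), cell in self.descriptions.items():
            if tid not in self._taxon_by_id:
                raise KBValidationError(f"description for unknown taxon {tid!r}")
            if did not in self._desc_by_id:
                raise KBValidationError(f"description for unknown descriptor {did!r}")
            if isinstance(cell, frozenset):
                if not cell:
                    raise KBValidationError(f"empty state set at ({tid!r}, {did})")
                extra = cell - set(self._desc_by_id[did].states)
                if extra:
                    raise KBValidationError(
                        f"taxon {tid!r}, descriptor {did}: states {sorted(extra)} "
                        "not in the descriptor's vocabulary")

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (sorted(self.descriptors, key=lambda d: d.id)
                == sorted(other.descriptors, key=lambda d: d.id)
                and sorted(self.taxa, key=lambda t: t.id)
                == sorted(other.taxa, key=lambda t: t.id)
                and self.descriptions == other.descriptions)


# -- applicability ---------------------------------------------------------


def is_applicable(kb: KnowledgeBase, taxon_id: str, descriptor_id: int) -> bool:
    """Is a descriptor meaningful for a taxon under the dependency forest?

    A dependency-free descriptor applies to everything.  A dependent one
    applies iff its parent applies and the taxon's recorded parent cell is a
    state set intersecting the triggering states (a polymorphic parent cell
    triggers if *any* of its states does).  An INAPPLICABLE or UNKNOWN parent
    cell never triggers.
    """
    d = kb.descriptor(descriptor_id)
    kb.taxon(taxon_id)
    if d.dependency is None:
        return True
    dep = d.dependency
    if not is_applicable(kb, taxon_id, dep.parent_id):
        return False
    parent_cell = kb.cell(taxon_id, dep.parent_id)
    return isinstance(parent_cell, frozenset) and bool(
        parent_cell & dep.triggering_states)


# -- consistency checking ---------------------------------------------------


@dataclass(frozen=True)
class CheckReport:
    """Result of the base-consistency check.

    completeness counts a cell complete iff it is a state set or INAPPLICABLE
    (a recorded, expected absence); only UNKNOWN cells are incomplete.
    """

    completeness: float
    duplicate_pairs: tuple
    dependency_violations: tuple

    @property
    def is_clean(self) -> bool:
        return (self.completeness == 1.0 and not self.duplicate_pairs
                and not self.dependency_violations)


def check_base(kb: KnowledgeBase) -> CheckReport:
    """Completeness, duplicated descriptions, and dependency violations."""
    total = len(kb.taxa) * len(kb.descriptors)
    known = sum(1 for cell in kb.descriptions.values() if cell is not UNKNOWN)
    completeness = known / total if total else 1.0

    by_vector: dict = {}
    for tid in kb.taxon_ids:
        by_vector.setdefault(kb.description_vector(tid), []).append(tid)
    duplicates = []
    for ids in by_vector.values():
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                duplicates.append(tuple(sorted((ids[i], ids[j]))))

    violations = []
    for t in kb.taxa:
        for d in kb.descriptors:
            cell = kb.descriptions[(t.id, d.id)]
            applicable = is_applicable(kb, t.id, d.id)
            if applicable and cell is INAPPLICABLE:
                violations.append((t.id, d.id))
            elif not applicable and isinstance(cell, frozenset):
                violations.append((t.id, d.id))

    return CheckReport(completeness=completeness,
                       duplicate_pairs=tuple(sorted(duplicates)),
                       dependency_violations=tuple(violations))


# -- summary statistics ------------------------------------------------------


@dataclass(frozen=True)
class BaseStatistics:
    n_taxa: int
    n_species: int
    n_forms: int
    n_descriptors: int
    total_states: int
    min_states: int
    max_states: int
    mean_states: float
    n_independent: int
    n_parents: int
    n_children: int
    n_both: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def state_count_summary(counts: Iterable) -> tuple:
    """(total, min, max, mean) of a collection of per-descriptor state counts."""
    counts = [int(c) for c in counts]
    if not counts:
        raise ValueError("no state counts given")
    total = sum(counts)
    return total, min(counts), max(counts), total / len(counts)


def base_statistics(kb: KnowledgeBase) -> BaseStatistics:
    """Taxon, state and dependency-structure counts of a base.

    ``n_species`` counts taxa with ``is_form == False``; colour forms are the
    remainder.  A descriptor is a *parent* if some other descriptor depends on
    it, a *child* if it has a dependency, *independent* if neither.
    """
    if not kb.descriptors:
        raise KBValidationError("base has no descriptors")
    counts = [d.n_states for d in kb.descriptors]
    total, mn, mx, mean = state_count_summary(counts)

    children = {d.id for d in kb.descriptors if d.dependency is not None}
    parents = {d.dependency.parent_id for d in kb.descriptors
               if d.dependency is not None}
    both = children & parents
    independent = set(kb.descriptor_ids) - children - parents

    n_forms = sum(1 for t in kb.taxa if t.is_form)
    return BaseStatistics(
        n_taxa=len(kb.taxa),
        n_species=len(kb.taxa) - n_forms,
        n_forms=n_forms,
        n_descriptors=len(kb.descriptors),
        total_states=total,
        min_states=mn,
        max_states=mx,
        mean_states=mean,
        n_independent=len(independent),
        n_parents=len(parents),
        n_children=len(children),
        n_both=len(both),
    )


# -- file I/O ---------------------------------------------------------------

_NA_TOKEN = "not applicable"
_STATE_SEP = ";"


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("json", "csv-matrix"):
            raise ValueError(f"unknown format {format!r}")
        return format
    if path.suffix.lower() == ".json":
        return "json"
    return "csv-matrix"


def read_kb(path, format: str | None = None) -> KnowledgeBase:
    """Read a knowledge base from JSON (full fidelity) or a CSV matrix.

    The CSV-matrix dialect mirrors a printed comparison table: one row per
    descriptor labelled ``"<id>. <name>"``, one column per taxon; a cell is a
    ``";"``-separated state list, the literal ``"not applicable"``, or empty
    (unknown).  The dialect carries no vocabularies or dependencies, so state
    vocabularies are inferred from the observed cells and the minimum-two-states
    rule is not enforced on that path.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        return _read_json(path)
    return _read_csv_matrix(path)


def write_kb(kb: KnowledgeBase, path, format: str | None = None) -> None:
    """Write a base; ``read_kb`` on the result reproduces it (JSON exactly;
    CSV up to the metadata the matrix dialect cannot carry)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        _write_json(kb, path)
    else:
        _write_csv_matrix(kb, path)


def kb_to_dict(kb: KnowledgeBase) -> dict:
    descriptors = []
    for d in kb.descriptors:
        dep = None
        if d.dependency is not None:
            dep = {"parent": d.dependency.parent_id,
                   "states": sorted(d.dependency.triggering_states)}
        descriptors.append({"id": d.id, "name": d.name, "category": d.category,
                            "states": list(d.states), "depends_on": dep})
    taxa = [{"id": t.id, "name": t.name, "form": t.form, "genus": t.genus,
             "tribe": t.tribe, "is_form": t.is_form} for t in kb.taxa]
    descriptions: dict = {}
    for t in kb.taxa:
        row: dict = {}
        for d in kb.descriptors:
            cell = kb.descriptions[(t.id, d.id)]
            if cell is UNKNOWN:
                row[str(d.id)] = None
            elif cell is INAPPLICABLE:
                row[str(d.id)] = "NA"
            else:
                row[str(d.id)] = {"states": sorted(cell)}
        descriptions[t.id] = row
    return {"name": kb.name, "descriptors": descriptors, "taxa": taxa,
            "descriptions": descriptions}


def kb_from_dict(payload: dict, source: str = "<dict>") -> KnowledgeBase:
    try:
        descriptors = []
        for rec in payload["descriptors"]:
            dep = rec.get("depends_on")
            dependency = None
            if dep is not None:
                dependency = Dependency(parent_id=int(dep["parent"]),
                                        triggering_states=frozenset(dep["states"]))
            descriptors.append(Descriptor(
                id=int(rec["id"]), name=rec["name"],
                category=rec.get("category", "other"),
                states=tuple(rec["states"]), dependency=dependency))
        taxa = []
        for rec in payload["taxa"]:
            taxa.append(TaxonConcept(
                id=rec["id"], name=rec.get("name", rec["id"]),
                genus=rec.get("genus", ""), tribe=rec.get("tribe", ""),
                form=rec.get("form"), is_form=bool(rec.get("is_form", False))))
        descriptions = {}
        for tid, row in payload.get("descriptions", {}).items():
            for did, value in row.items():
                key = (tid, int(did))
                if value is None:
                    descriptions[key] = UNKNOWN
                elif value == "NA":
                    descriptions[key] = INAPPLICABLE
                else:
                    descriptions[key] = frozenset(value["states"])
    except (KeyError, TypeError, ValueError) as exc:
        raise KBParseError(f"{source}: malformed knowledge base: {exc}") from exc
    return KnowledgeBase(name=payload.get("name", "unnamed"),
                         descriptors=descriptors, taxa=taxa,
                         descriptions=descriptions)


def _read_json(path: Path) -> KnowledgeBase:
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise KBParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    return kb_from_dict(payload, source=str(path))


def _write_json(kb: KnowledgeBase, path: Path) -> None:
    path.write_text(json.dumps(kb_to_dict(kb), indent=1, ensure_ascii=False) + "\n",
                    encoding="utf-8")


_ROW_LABEL = re.compile(r"^\s*(\d+)\.\s*(.*\S)\s*$")


def _read_csv_matrix(path: Path) -> KnowledgeBase:
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise KBParseError(f"{path}: empty file")
    header = rows[0]
    taxon_ids = [c.strip() for c in header[1:]]
    if any(not tid for tid in taxon_ids):
        raise KBParseError(f"{path}: line 1: empty taxon column header")
    taxa = [TaxonConcept(id=tid, name=tid) for tid in taxon_ids]

    descriptors = []
    descriptions = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or not any(c.strip() for c in row):
            continue
        m = _ROW_LABEL.match(row[0])
        if not m:
            raise KBParseError(
                f"{path}: line {lineno}: row label {row[0]!r} is not '<id>. <name>'")
        did, name = int(m.group(1)), m.group(2)
        cells = row[1:]
        if len(cells) != len(taxon_ids):
            raise KBParseError(
                f"{path}: line {lineno}: expected {len(taxon_ids)} cells, "
                f"got {len(cells)}")
        observed: list = []
        for tid, raw in zip(taxon_ids, cells):
            raw = raw.strip()
            if not raw:
                descriptions[(tid, did)] = UNKNOWN
            elif raw.lower() == _NA_TOKEN:
                descriptions[(tid, did)] = INAPPLICABLE
            else:
                states = [s.strip() for s in raw.split(_STATE_SEP)]
                if any(not s for s in states):
                    raise KBParseError(
                        f"{path}: line {lineno}: empty state label in {raw!r}")
                descriptions[(tid, did)] = frozenset(states)
                for s in states:
                    if s not in observed:
                        observed.append(s)
        descriptors.append(Descriptor(id=did, name=name, states=tuple(observed)))
    return KnowledgeBase(name=path.stem, descriptors=descriptors, taxa=taxa,
                         descriptions=descriptions, require_min_states=False)


def _write_csv_matrix(kb: KnowledgeBase, path: Path) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + kb.taxon_ids)
        for d in kb.descriptors:
            row = [f"{d.id}. {d.name}"]
            for tid in kb.taxon_ids:
                cell = kb.descriptions[(tid, d.id)]
                if cell is UNKNOWN:
                    row.append("")
                elif cell is INAPPLICABLE:
                    row.append(_NA_TOKEN)
                else:
                    # vocabulary order keeps output deterministic
                    ordered = [s for s in d.states if s in cell]
                    ordered += sorted(cell - set(d.states))
                    row.append("; ".join(ordered))
            writer.writerow(row)
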