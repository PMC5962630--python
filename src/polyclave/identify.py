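"""Multi-access (free-access) identification sessions.

The user observes a specimen and enters character states in any order; the
session keeps the taxa whose recorded descriptions are compatible with every
observation.  A taxon *mismatches* one choice when its cell is a state set
disjoint from the observed states, or when applicability disagrees (a state
was observed but the taxon's cell is inapplicable, or the observer reports
the structure absent while the taxon has states recorded).  UNKNOWN cells
never mismatch — missing knowledge is not evidence.

A mismatch tolerance k > 0 keeps taxa with up to k mismatching choices, so a
single observation error cannot eliminate the true taxon when k >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

from .kb import INAPPLICABLE, UNKNOWN, KnowledgeBase, _Marker
from .discrimination import xper_index

__all__ = ["Session", "start_session", "apply_choice", "next_descriptors"]

Observation = Union[frozenset, _Marker]


@dataclass(frozen=True)
class Session:
    """Immutable snapshot of an identification session.

    ``choices`` maps descriptor id to the observed state set (or the
    INAPPLICABLE marker for an explicit "structure absent" answer);
    ``candidates`` lists (taxon_id, mismatch_count) for every taxon with at
    most ``tolerance`` mismatches, sorted by mismatches then taxon name.
    """

    kb: KnowledgeBase
    tolerance: int
    choices: dict = field(default_factory=dict)
    candidates: tuple = ()

    @property
    def candidate_ids(self) -> list:
        return [tid for tid, _ in self.candidates]


def _mismatches(kb: KnowledgeBase, taxon_id: str, choices: dict) -> int:
    count = 0
    for did, observed in choices.items():
        cell = kb.cell(taxon_id, did)
        if cell is UNKNOWN:
            continue
        if observed is INAPPLICABLE:
            if isinstance(cell, frozenset):
                count += 1
        else:
            if cell is INAPPLICABLE or not (cell & observed):
                count += 1
    return count


def _with_candidates(session: Session) -> Session:
    kb = session.kb
    rows = []
    for t in kb.taxa:
        m = _mismatches(kb, t.id, session.choices)
        if m <= session.tolerance:
            rows.append((m, t.name, t.id))
    rows.sort()
    return replace(session, candidates=tuple((tid, m) for m, _, tid in rows))


def start_session(kb: KnowledgeBase, tolerance: int = 0) -> Session:
    """Fresh session: no choices, every taxon a candidate with 0 mismatches."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return _with_candidates(Session(kb=kb, tolerance=tolerance))


def apply_choice(session: Session, descriptor_id: int,
                 observed) -> Session:
    """Record one observation and re-filter candidates (order-independent).

    ``observed`` is a set of state labels, or the INAPPLICABLE marker for an
    explicit absence answer.  Re-choosing a descriptor replaces the earlier
    answer.
    """
    d = session.kb.descriptor(descriptor_id)
    if observed is not INAPPLICABLE:
        observed = frozenset(observed)
        if not observed:
            raise ValueError("observed state set must be non-empty")
        bad = observed - set(d.states)
        if bad:
            raise ValueError(
                f"states {sorted(bad)!r} not in descriptor {d.id}'s vocabulary")
    choices = dict(session.choices)
    choices[descriptor_id] = observed
    return _with_candidates(replace(session, choices=choices))


def next_descriptors(session: Session) -> list:
    """Remaining descriptors ranked by power over the current candidates.

    Returns (descriptor_id, restricted index) pairs, best first, excluding
    descriptors already answered and descriptors that cannot separate any
    candidate pair (restricted index 0).  Empty when fewer than two
    candidates remain (nothing left to separate).
    """
    cand = session.candidate_ids
    if len(cand) < 2:
        return []
    ranked = []
    for d in session.kb.descriptors:
        if d.id in session.choices:
            continue
        idx = xper_index(session.kb, d.id, cand)
        if idx > 0:
            ranked.append((d.id, idx))
    ranked.sort(key=lambda pair: (-pair[1], pair[0]))
    return ranked
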