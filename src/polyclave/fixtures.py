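"""Packaged reference fixtures.

Three fixtures ship with the package:

``coccinella_table4``
    The published six-species *Coccinella* comparison matrix, transcribed
    verbatim in the printed row order (CSV matrix) with a sidecar mapping each
    matrix row to the canonical descriptor numbering 1–21 and supplying the
    descriptive model (vocabularies, categories, dependency forest) the matrix
    itself cannot carry.  Loaded as a fully validated KnowledgeBase under
    canonical ids.

``ladybird_taxa``
    The 66 items of the French ladybird key (47 species and 19 intraspecific
    colour forms) with genus and tribe, as a DataFrame.

``ladybird_descriptors``
    The 21 descriptors with category, published per-descriptor state count,
    full-base discriminatory-power index and membership in the published
    11-descriptor sufficient set, as a DataFrame.  The index and minimal-set
    columns are reference values from the complete (online-only) base; this
    package does not recompute them.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .kb import KnowledgeBase, kb_from_dict, read_kb

__all__ = ["FIXTURE_NAMES", "fixture_path", "load_fixture"]

FIXTURE_NAMES = ("coccinella_table4", "ladybird_taxa", "ladybird_descriptors")

_FILES = {
    "coccinella_table4": "coccinella_table4.csv",
    "coccinella_table4_meta": "coccinella_table4_meta.json",
    "coccinella_table4_json": "coccinella_table4.json",
    "ladybird_taxa": "ladybird_taxa.csv",
    "ladybird_descriptors": "ladybird_descriptors.csv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    try:
        fname = _FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FILES)}") from None
    return Path(str(resources.files("polyclave").joinpath("data", fname)))


def _load_coccinella() -> KnowledgeBase:
    # verbatim printed matrix + sidecar model, remapped to canonical numbering
    raw = read_kb(fixture_path("coccinella_table4"), format="csv-matrix")
    meta = json.loads(fixture_path("coccinella_table4_meta").read_text("utf-8"))
    row_map = {int(k): int(v) for k, v in meta["row_map"].items()}
    model = kb_from_dict({"name": meta["name"], "descriptors": meta["descriptors"],
                          "taxa": meta["taxa"], "descriptions": {}},
                         source="coccinella_table4_meta.json")
    descriptions = {(tid, row_map[row_id]): cell
                    for (tid, row_id), cell in raw.descriptions.items()}
    return KnowledgeBase(name=meta["name"], descriptors=model.descriptors,
                         taxa=model.taxa, descriptions=descriptions)


def load_fixture(name: str):
    """Load a packaged fixture: a KnowledgeBase or a metadata DataFrame."""
    if name == "coccinella_table4":
        return _load_coccinella()
    if name == "ladybird_taxa":
        df = pd.read_csv(fixture_path(name), dtype=str, keep_default_na=False)
        df["is_form"] = df["is_form"] == "True"
        df["form"] = df["form"].replace("", None)
        return df
    if name == "ladybird_descriptors":
        df = pd.read_csv(fixture_path(name))
        df["in_minimal_set"] = df["in_minimal_set"].astype(bool)
        return df
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
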