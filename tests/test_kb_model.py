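"""Knowledge-base model: I/O round trips, applicability, consistency checks."""

import pytest

from polyclave import (Dependency, Descriptor, KBParseError, KBValidationError,
                       KnowledgeBase, TaxonConcept, INAPPLICABLE, UNKNOWN,
                       base_statistics, check_base, fixture_path, is_applicable,
                       read_kb, state_count_summary, write_kb, generate_kb)


def tiny_kb(**overrides):
    kwargs = dict(
        name="tiny",
        descriptors=[Descriptor(id=1, name="colour", states=("Red", "Black"))],
        taxa=[TaxonConcept(id="a", name="Taxon a")],
        descriptions={("a", 1): frozenset(["Red"])},
    )
    kwargs.update(overrides)
    return KnowledgeBase(**kwargs)


class TestIO:
    def test_packaged_csv_matrix_reads(self):
        kb = read_kb(fixture_path("coccinella_table4"), format="csv-matrix")
        assert len(kb.taxa) == 6
        assert len(kb.descriptors) == 21

    def test_minimal_json_base(self, tmp_path):
        kb = tiny_kb()
        path = tmp_path / "tiny.json"
        write_kb(kb, path)
        assert read_kb(path) == kb

    def test_json_roundtrip_fixture(self, coccinella, tmp_path):
        path = tmp_path / "cocc.json"
        write_kb(coccinella, path)
        assert read_kb(path) == coccinella

    def test_packaged_json_equals_csv_transcription(self, coccinella):
        assert read_kb(fixture_path("coccinella_table4_json")) == coccinella

    def test_csv_roundtrip_preserves_cells(self, coccinella, tmp_path):
        path = tmp_path / "cocc.csv"
        write_kb(coccinella, path)
        back = read_kb(path)
        assert back.descriptions == coccinella.descriptions

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_generated_bases_both_formats(self, seed, tmp_path):
        kb = generate_kb(n_taxa=10, n_descriptors=6, seed=seed,
                         unknown_prob=0.1, dependency=(2, 1, 2, 0))
        for fmt, suffix in (("json", "json"), ("csv-matrix", "csv")):
            path = tmp_path / f"kb{seed}.{suffix}"
            write_kb(kb, path, format=fmt)
            assert read_kb(path, format=fmt).descriptions == kb.descriptions

    def test_unknown_cells_serialised_as_empty_fields(self, tmp_path):
        kb = tiny_kb(descriptions={("a", 1): UNKNOWN})
        path = tmp_path / "u.csv"
        write_kb(kb, path)
        row = path.read_text().splitlines()[1]
        assert row == "1. colour,"
        assert read_kb(path).descriptions[("a", 1)] is UNKNOWN

    def test_empty_taxa_base_writes_header_only(self, tmp_path):
        kb = KnowledgeBase(name="empty", descriptors=[
            Descriptor(id=1, name="colour", states=("Red", "Black"))],
            taxa=[], descriptions={})
        path = tmp_path / "e.csv"
        write_kb(kb, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2  # header row + the lone descriptor row
        assert lines[1].startswith("1. colour")
        assert read_kb(path).taxa == []

    def test_malformed_csv_row_label_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",a,b\nno-label-here,Red,Black\n")
        with pytest.raises(KBParseError, match="line 2"):
            read_kb(path)

    def test_invalid_json_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(KBParseError):
            read_kb(path)


class TestValidation:
    def test_state_outside_vocabulary_rejected(self):
        with pytest.raises(KBValidationError, match="vocabulary"):
            tiny_kb(descriptions={("a", 1): frozenset(["Chartreuse"])})

    def test_single_state_vocabulary_rejected(self):
        with pytest.raises(KBValidationError, match="at least 2"):
            tiny_kb(descriptors=[Descriptor(id=1, name="colour",
                                            states=("Red",))],
                    descriptions={("a", 1): frozenset(["Red"])})

    def test_dependency_cycle_rejected(self):
        descriptors = [
            Descriptor(id=1, name="x", states=("a", "b"),
                       dependency=Dependency(2, frozenset(["c"]))),
            Descriptor(id=2, name="y", states=("c", "d"),
                       dependency=Dependency(1, frozenset(["a"]))),
        ]
        with pytest.raises(KBValidationError, match="cycle"):
            KnowledgeBase(name="cyc", descriptors=descriptors, taxa=[],
                          descriptions={})

    def test_triggering_states_must_be_parental(self):
        descriptors = [
            Descriptor(id=1, name="x", states=("a", "b")),
            Descriptor(id=2, name="y", states=("c", "d"),
                       dependency=Dependency(1, frozenset(["zzz"]))),
        ]
        with pytest.raises(KBValidationError, match="triggering"):
            KnowledgeBase(name="t", descriptors=descriptors, taxa=[],
                          descriptions={})

    def test_missing_cells_filled_with_unknown(self):
        kb = tiny_kb(descriptions={})
        assert kb.cell("a", 1) is UNKNOWN


class TestApplicability:
    def test_recorded_inapplicable_iff_not_applicable(self, coccinella):
        # the fixture's dependency map explains every printed "not applicable"
        for t in coccinella.taxa:
            for d in coccinella.descriptors:
                recorded_na = coccinella.cell(t.id, d.id) is INAPPLICABLE
                assert recorded_na == (not is_applicable(coccinella, t.id, d.id))

    def test_venusta_scutellar_spot_shape_inapplicable(self, coccinella):
        assert coccinella.cell("coccinella_venusta", 16) == frozenset(["Absent"])
        assert not is_applicable(coccinella, "coccinella_venusta", 17)

    def test_dependency_free_descriptor_always_applicable(self, coccinella):
        for tid in coccinella.taxon_ids:
            assert is_applicable(coccinella, tid, 21)

    def test_polymorphic_parent_triggers_on_intersection(self, coccinella):
        # hieroglyphica's marking type is "Ovoid shape spot; Other": one of the
        # two states triggers the line-count descriptors, so they apply
        cell = coccinella.cell("coccinella_hieroglyphica", 9)
        assert cell == frozenset(["Ovoid shape spot", "Other"])
        assert is_applicable(coccinella, "coccinella_hieroglyphica", 10)
        assert is_applicable(coccinella, "coccinella_hieroglyphica", 11)


class TestCheckBase:
    def test_fixture_is_clean(self, coccinella):
        report = check_base(coccinella)
        assert report.completeness == 1.0
        assert report.duplicate_pairs == ()
        assert report.dependency_violations == ()
        assert report.is_clean

    def test_planted_duplicate_detected(self, coccinella):
        clone = KnowledgeBase(
            name="dup", descriptors=coccinella.descriptors,
            taxa=list(coccinella.taxa) + [TaxonConcept(id="copy", name="Copy")],
            descriptions={
                **coccinella.descriptions,
                **{("copy", d.id): coccinella.cell("coccinella_magnifica", d.id)
                   for d in coccinella.descriptors},
            })
        report = check_base(clone)
        assert ("coccinella_magnifica", "copy") in report.duplicate_pairs or \
               ("copy", "coccinella_magnifica") in report.duplicate_pairs

    def test_one_unknown_cell_of_126(self, coccinella):
        descriptions = dict(coccinella.descriptions)
        descriptions[("coccinella_venusta", 1)] = UNKNOWN
        kb = KnowledgeBase(name="hole", descriptors=coccinella.descriptors,
                           taxa=coccinella.taxa, descriptions=descriptions)
        assert check_base(kb).completeness == pytest.approx(125 / 126)

    def test_misrecorded_inapplicable_flagged(self, coccinella):
        descriptions = dict(coccinella.descriptions)
        descriptions[("coccinella_magnifica", 21)] = INAPPLICABLE
        kb = KnowledgeBase(name="viol", descriptors=coccinella.descriptors,
                           taxa=coccinella.taxa, descriptions=descriptions)
        assert ("coccinella_magnifica", 21) in check_base(kb).dependency_violations


class TestStatistics:
    def test_single_binary_descriptor(self):
        stats = base_statistics(tiny_kb())
        assert stats.total_states == 2
        assert stats.mean_states == 2.0
        assert stats.n_independent == 1

    def test_published_state_counts(self, ladybird_descriptors):
        total, mn, mx, mean = state_count_summary(ladybird_descriptors["n_states"])
        assert (total, mn, mx) == (98, 2, 12)
        assert mean == pytest.approx(4.67, abs=0.005)

    def test_taxon_fixture_counts(self, ladybird_taxa):
        assert len(ladybird_taxa) == 66
        assert (~ladybird_taxa["is_form"]).sum() == 47
        assert ladybird_taxa["is_form"].sum() == 19
        assert ladybird_taxa["genus"].nunique() == 24

    def test_mean_states_is_total_over_count(self, coccinella):
        stats = base_statistics(coccinella)
        assert stats.mean_states == stats.total_states / stats.n_descriptors

    def test_fixture_dependency_roles(self, coccinella):
        stats = base_statistics(coccinella)
        # reconstructed forest: 2, 6, 9, 16 are parents; 9 and 16 also children
        assert stats.n_parents == 4
        assert stats.n_both == 2
        assert stats.n_independent + stats.n_parents + stats.n_children \
            - stats.n_both == 21
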