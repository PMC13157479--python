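"""Catalog layer: code canonicalization, loaders, merging, export round-trip."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocuphen.catalog import (
    IGNORE_SENTINEL,
    CatalogError,
    CatalogParseError,
    CodeError,
    ConflictError,
    HpoTerm,
    SynonymCatalog,
    add_synonym,
    canonicalize_code,
    export_catalog,
    export_catalog_text,
    load_hpo_subset,
    load_local_catalog,
    merge,
    normalize_surface,
    to_curie,
)


class TestCodes:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("541", "0000541"),
            ("HP:0000541", "0000541"),
            ("11457", "0011457"),
            ("6000709", "6000709"),
            ("500081", "0500081"),
            (541, "0000541"),
            ("0", IGNORE_SENTINEL),
        ],
    )
    def test_canonical_form(self, raw, expected):
        assert canonicalize_code(raw) == expected

    def test_idempotent(self):
        for raw in ("541", "0", "6000709"):
            once = canonicalize_code(raw)
            assert canonicalize_code(once) == once

    @pytest.mark.parametrize("bad", ["", "abc", "12a4", "12345678", "HP:xyz"])
    def test_rejects_non_codes(self, bad):
        with pytest.raises(CodeError):
            canonicalize_code(bad)

    def test_curie_display(self):
        assert to_curie("541") == "HP:0000541"
        with pytest.raises(CodeError):
            to_curie("0")


class TestNormalization:
    @given(st.text(max_size=60))
    @settings(derandomize=True)
    def test_idempotent(self, s):
        assert normalize_surface(normalize_surface(s)) == normalize_surface(s)

    def test_folds_case_space_and_terminal_punctuation(self):
        assert normalize_surface("  Retinal\t Detachment. ") == "retinal detachment"


class TestOntologyLoading:
    def test_obo_labels_and_exact_synonyms(self, tiny_obo):
        cat = load_hpo_subset(tiny_obo)
        assert len(cat) == 3
        assert cat.lookup("retinal detachment").code == "0000541"
        assert cat.lookup("Amotio retinae").code == "0000541"
        assert cat.lookup("Eyelash loss").code == "0011457"
        # RELATED synonyms are not ingested
        assert cat.lookup("Madarosis of eyelashes") is None
        assert all(t.layer == "standard" and t.scope == "both" for t in cat.terms)

    def test_hpo_json_dialect(self, tiny_hpo_json):
        cat = load_hpo_subset(tiny_hpo_json)
        assert cat.lookup("amotio retinae").code == "0000541"
        assert cat.lookup("not an hp node") is None  # non-HP nodes skipped

    def test_empty_ontology_gives_empty_catalog(self, tmp_path):
        path = tmp_path / "empty.obo"
        path.write_text("format-version: 1.2\n", encoding="utf-8")
        assert len(load_hpo_subset(path)) == 0

    def test_duplicate_concept_id_is_load_error(self, tmp_path):
        path = tmp_path / "dup.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: HP:0000541\nname: A\n\n"
            "[Term]\nid: HP:0000541\nname: B\n",
            encoding="utf-8",
        )
        with pytest.raises(CatalogParseError, match="duplicate"):
            load_hpo_subset(path)

    def test_surface_count_matches_brute_force_enumeration(self, tiny_obo):
        # independent tally: labels + exact synonyms, none shared
        cat = load_hpo_subset(tiny_obo)
        expected = 3 + 2  # three labels, two EXACT synonyms
        assert len(cat.surface_index) == expected
        assert len(cat.entries()) == expected


class TestLocalCatalog:
    def test_rows_are_padded_local_scoped(self, tmp_path):
        path = tmp_path / "local.tsv"
        path.write_text("11457\tEyelash loss\n0\tMotility\n", encoding="utf-8")
        cat = load_local_catalog(path, scope="anterior")
        entry = cat.lookup("Eyelash loss")
        assert (entry.code, entry.layer, entry.scope) == ("0011457", "local", "anterior")
        assert cat.lookup("Motility").code == IGNORE_SENTINEL

    @pytest.mark.parametrize("row", ["xx\tEyelash loss", "11457\t  "])
    def test_bad_rows_name_the_row_number(self, tmp_path, row):
        path = tmp_path / "local.tsv"
        path.write_text("11457\tEyelash loss\n" + row + "\n", encoding="utf-8")
        with pytest.raises(CatalogParseError, match=":2"):
            load_local_catalog(path, scope="anterior")

    def test_export_load_round_trip(self, tmp_path, fixture_catalog):
        path = export_catalog(fixture_catalog, tmp_path / "cat.tsv")
        reloaded = load_local_catalog(path)
        assert reloaded == fixture_catalog
        assert export_catalog_text(reloaded) == export_catalog_text(fixture_catalog)

    def test_export_line_count_and_empty_export(self, tmp_path, fixture_catalog):
        text = export_catalog_text(fixture_catalog)
        assert len(text.splitlines()) == len(fixture_catalog.entries()) + 1
        assert export_catalog_text(SynonymCatalog()) == "hpo_id\tsurface\tscope\tlayer\tprovenance\n"


class TestMergeAndPrecedence:
    def test_merge_with_empty_is_identity(self, fixture_catalog):
        assert merge(fixture_catalog, SynonymCatalog()) == fixture_catalog

    def test_local_wins_surface_collision_against_standard(self):
        standard = SynonymCatalog([HpoTerm("541", "Retinal detachment")])
        local = SynonymCatalog(
            [HpoTerm("1177", "Retinal detachment", layer="local", scope="posterior",
                     provenance="fixture")]
        )
        merged = merge(standard, local)
        assert merged.lookup("retinal detachment").code == "0001177"

    def test_local_local_collision_is_error(self):
        t1 = HpoTerm("541", "Flap", layer="local", scope="posterior", provenance="fixture")
        t2 = HpoTerm("1177", "Flap", layer="local", scope="posterior", provenance="fixture")
        with pytest.raises(ConflictError, match="0000541|0001177"):
            SynonymCatalog([t1, t2])

    def test_merged_surface_set_equals_union_oracle(self, fixture_catalog, tiny_obo):
        other = load_hpo_subset(tiny_obo)
        merged = merge(other, fixture_catalog)
        expected = {normalize_surface(e.surface) for e in fixture_catalog.entries()} | {
            normalize_surface(e.surface) for e in other.entries()
        }
        assert set(merged.surface_index) == expected


class TestAddSynonym:
    def test_added_surface_resolves_exactly(self, fixture_catalog):
        cat = add_synonym(fixture_catalog, "Netzhaut abgehoben", "0000541")
        entry = cat.lookup("netzhaut abgehoben")
        assert entry.code == "0000541" and entry.provenance == "local-augmentation"

    def test_reading_existing_pair_is_noop(self, fixture_catalog):
        once = add_synonym(fixture_catalog, "Netzhaut abgehoben", "541")
        twice = add_synonym(once, "netzhaut  abgehoben", "HP:0000541")
        assert twice is once

    def test_conflicting_local_mapping_rejected(self, fixture_catalog):
        cat = add_synonym(fixture_catalog, "Netzhaut abgehoben", "541")
        with pytest.raises(ConflictError):
            add_synonym(cat, "Netzhaut abgehoben", "1177")

    def test_k_distinct_additions_grow_local_layer_by_k(self, fixture_catalog):
        before = fixture_catalog.local_synonym_count()
        cat = fixture_catalog
        surfaces = [f"invented finding {i}" for i in range(5)]
        for i, s in enumerate(surfaces):
            cat = add_synonym(cat, s, str(1000 + i))
        assert cat.local_synonym_count() == before + len(surfaces)


class TestTermInvariants:
    def test_standard_layer_rejects_sentinel(self):
        with pytest.raises(CatalogError):
            HpoTerm("0", "Motility", layer="standard")

    def test_synonyms_deduplicate_after_normalization(self):
        term = HpoTerm("541", "Retinal detachment", ("retinal  Detachment.", "Amotio retinae"))
        assert term.synonyms == ("Amotio retinae",)

    def test_empty_label_rejected(self):
        with pytest.raises(CatalogError):
            HpoTerm("541", "   ")
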