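from __future__ import annotations

import json

import pytest

from dmcompare import (
    CanonicalId,
    DiseaseMap,
    Element,
    EntityClass,
    Interaction,
    MapFormat,
    canonical_identifier,
    load_map,
    load_map_with_report,
    summarize,
    write_map,
)
from dmcompare.model import MapValidationError, map_from_dict, map_to_dict

from conftest import make_map, protein


class TestCanonicalIdentifier:
    def test_protein_hgnc_uppercased(self):
        e = Element("e1", "il13", EntityClass.PROTEIN, (("HGNC", "il13"),), "d1")
        assert canonical_identifier(e) == CanonicalId("HGNC", "IL13")

    @pytest.mark.parametrize("cls", [EntityClass.GENE, EntityClass.RNA])
    def test_gene_rna_use_hgnc(self, cls):
        e = Element("e1", "x", cls, (("HGNC", "Tbx21"),), "d1")
        assert canonical_identifier(e) == CanonicalId("HGNC", "TBX21")

    def test_simple_molecule_chebi_prefix_normalized(self):
        for raw in ("CHEBI:16412", "16412", "chebi:16412"):
            e = Element(
                "e1", "LPS", EntityClass.SIMPLE_MOLECULE, (("CHEBI", raw),), "d1"
            )
            assert canonical_identifier(e) == CanonicalId("CHEBI", "CHEBI:16412")

    def test_phenotype_name_collapsed_lowercased(self):
        e = Element("e1", "  Epithelial \t damage ", EntityClass.PHENOTYPE, (), "d1")
        assert canonical_identifier(e) == CanonicalId("NAME", "epithelial damage")

    def test_protein_without_hgnc_excluded(self):
        e = Element("e1", "X", EntityClass.PROTEIN, (("UNIPROT", "P05112"),), "d1")
        assert canonical_identifier(e) is None

    @pytest.mark.parametrize("cls", [EntityClass.COMPLEX, EntityClass.OTHER])
    def test_complex_and_other_excluded(self, cls):
        e = Element("e1", "X", cls, (("HGNC", "IL13"),), "d1")
        assert canonical_identifier(e) is None

    def test_duplicate_namespace_first_wins(self):
        e = Element(
            "e1", "X", EntityClass.PROTEIN, (("HGNC", "IL13"), ("HGNC", "IL4")), "d1"
        )
        assert canonical_identifier(e) == CanonicalId("HGNC", "IL13")

    def test_case_insensitive_deterministic(self):
        a = Element("e1", "x", EntityClass.PROTEIN, (("HGNC", "Jak1"),), "d1")
        b = Element("e2", "x", EntityClass.PROTEIN, (("HGNC", "JAK1"),), "d1")
        assert canonical_identifier(a) == canonical_identifier(b)


class TestValidation:
    def test_dangling_participant_is_fatal(self, tmp_path):
        m = make_map("M", [protein("e1", "A"), protein("e2", "B")])
        m.interactions = [
            Interaction("i1", "d1", sources=("e1",), targets=("missing",))
        ]
        with pytest.raises(MapValidationError, match="missing"):
            m.validate()

    def test_duplicate_element_id_is_fatal(self):
        with pytest.raises(MapValidationError, match="duplicate element_id"):
            make_map("M", [protein("e1", "A"), protein("e1", "B")])

    def test_empty_sources_is_fatal(self):
        m = make_map("M", [protein("e1", "A")])
        m.interactions = [Interaction("i1", "d1", sources=(), targets=("e1",))]
        with pytest.raises(MapValidationError, match="non-empty"):
            m.validate()

    def test_participants_deduplicated_on_load(self):
        doc = map_to_dict(make_map("M", [protein("e1", "A"), protein("e2", "B")]))
        doc["interactions"] = [
            {
                "interaction_id": "i1",
                "diagram_id": "d1",
                "sources": ["e1", "e1"],
                "targets": ["e2"],
                "modifiers": [],
                "sign": "UNKNOWN",
                "references": [],
            }
        ]
        m = map_from_dict(doc)
        assert m.interactions[0].sources == ("e1",)


class TestNativeRoundTrip:
    def test_minimal_map_round_trip(self, tmp_path):
        m = make_map(
            "M",
            [protein("e1", "IL13"), protein("e2", "IL4R")],
            [Interaction("i1", "d1", sources=("e1",), targets=("e2",))],
        )
        p = tmp_path / "m.json"
        write_map(m, p)
        loaded = load_map(p)
        assert loaded.map_id == m.map_id
        assert loaded.elements == m.elements
        assert loaded.interactions == m.interactions
        assert loaded.diagrams == m.diagrams

    def test_write_is_byte_stable(self, tmp_path, sim_pair):
        map_a, _, _ = sim_pair
        p1, p2 = tmp_path / "a1.json", tmp_path / "a2.json"
        write_map(map_a, p1)
        write_map(map_a, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_synthetic_50_element_round_trip(self, tmp_path, sim_pair):
        map_a, _, _ = sim_pair
        p = tmp_path / "a.json"
        write_map(map_a, p)
        loaded = load_map(p)
        assert loaded.elements == map_a.elements
        assert loaded.interactions == map_a.interactions

    def test_unicode_display_names_preserved(self, tmp_path):
        e = Element("e1", "NF-κB → ΙΚΚ", EntityClass.PHENOTYPE, (), "d1")
        m = make_map("M", [e])
        p = tmp_path / "m.json"
        write_map(m, p)
        assert load_map(p).elements[0].display_name == "NF-κB → ΙΚΚ"

    def test_wrong_format_tag_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"format": "something-else"}))
        with pytest.raises(MapValidationError, match="format"):
            load_map(p)


class TestMinervaAdapter:
    @pytest.fixture
    def export_doc(self):
        return {
            "project": {"projectId": "TESTproj", "name": "Test disease"},
            "models": [
                {
                    "idObject": 101,
                    "name": "Intercellular overview",
                    "elements": [
                        {
                            "id": 1, "name": "IL13", "type": "Protein",
                            "compartmentName": None,
                            "references": [
                                {"type": "HGNC_SYMBOL", "resource": "IL13"},
                                {"type": "UNIPROT", "resource": "P35225"},
                            ],
                        },
                        {
                            "id": 2, "name": "IL4R", "type": "Protein",
                            "compartmentName": None,
                            "references": [{"type": "HGNC_SYMBOL", "resource": "IL4R"}],
                        },
                        {"id": 3, "name": "LPS", "type": "Simple molecule",
                         "references": [{"type": "CHEBI", "resource": "CHEBI:16412"}]},
                    ],
                    "reactions": [
                        {
                            "id": 7, "type": "Positive influence",
                            "reactants": [{"element": 1}],
                            "products": [{"element": 2}],
                            "modifiers": [{"element": 3}],
                            "references": [{"type": "PUBMED", "resource": "12345"}],
                        }
                    ],
                },
                {
                    "idObject": 102,
                    "name": "Th2 cell",
                    "elements": [
                        {"id": 9, "name": "GATA3", "type": "Protein",
                         "compartmentName": "Th2 cell",
                         "references": [{"type": "HGNC_SYMBOL", "resource": "GATA3"}]},
                    ],
                    "reactions": [],
                },
            ],
        }

    def test_field_mapping(self, tmp_path, export_doc):
        p = tmp_path / "export.json"
        p.write_text(json.dumps(export_doc))
        m = load_map(p, MapFormat.MINERVA_EXPORT)
        assert m.map_id == "TESTproj"
        assert len(m.diagrams) == 2
        assert m.diagrams[0].kind.value == "INTERCELLULAR"
        assert m.diagrams[1].cell_type == "Th2 cell"
        assert len(m.elements) == 4
        assert len(m.interactions) == 1
        i = m.interactions[0]
        assert i.sign.value == "POSITIVE"
        assert i.modifiers == ("m101.e3",)
        assert i.references == ("12345",)
        ids = {canonical_identifier(e) for e in m.elements}
        assert CanonicalId("HGNC", "IL13") in ids
        assert CanonicalId("CHEBI", "CHEBI:16412") in ids

    def test_bad_reaction_dropped_and_counted(self, tmp_path, export_doc):
        export_doc["models"][0]["reactions"].append(
            {"id": 8, "type": "x", "reactants": [{"element": 999}],
             "products": [{"element": 1}]}
        )
        p = tmp_path / "export.json"
        p.write_text(json.dumps(export_doc))
        m, report = load_map_with_report(p, MapFormat.MINERVA_EXPORT)
        assert len(m.interactions) == 1
        assert report.n_interactions_dropped == 1
        assert report.warnings


class TestSummarize:
    def test_empty_map(self):
        m = DiseaseMap(map_id="E")
        s = summarize(m)
        assert (s.n_elements, s.n_interactions, s.n_unique_molecular_entities,
                s.n_diagrams, s.n_references) == (0, 0, 0, 0, 0)

    def test_same_protein_in_three_diagrams_dedups(self):
        elements = [
            protein("e1", "IL13", "d1"),
            protein("e2", "IL13", "d2"),
            protein("e3", "IL13", "d3"),
        ]
        m = make_map("M", elements)
        s = summarize(m)
        assert s.n_elements == 3
        assert s.n_unique_molecular_entities == 1

    def test_phenotypes_not_molecular(self):
        m = make_map(
            "M",
            [protein("e1", "IL13"),
             Element("e2", "damage", EntityClass.PHENOTYPE, (), "d1")],
        )
        assert summarize(m).n_unique_molecular_entities == 1

    def test_counts_bounded(self, sim_pair):
        map_a, _, _ = sim_pair
        s = summarize(map_a)
        assert 0 <= s.n_unique_molecular_entities <= s.n_elements
        assert s.n_elements == len(map_a.elements)
        assert s.n_interactions == len(map_a.interactions)
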