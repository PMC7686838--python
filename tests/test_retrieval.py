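"""Request construction, status classification, and payload parsing."""

import json
import math

import pytest
from hypothesis import given, settings, strategies as st

from scaffquery import retrieval
from scaffquery.retrieval import (
    ApiRequest,
    ParseError,
    NoStructureError,
    ValidationError,
    build_activity_request,
    build_association_request,
    build_iuphar_requests,
    classify_status,
    fixture_filename,
    map_pubchem_target,
    parse_activity_page,
    parse_association_payload,
    parse_best_structures,
    parse_bound_ligands,
    parse_chemcomp_smiles,
    parse_pdb_header,
    parse_uniprot_pdb_xrefs,
    plan_pagination,
    PubChemFixtures,
)
from scaffquery.synthetic import _activity_page_xml, _uniprot_entry_xml


class TestRequestBuilders:
    def test_association_request_matches_printed_form(self):
        req = build_association_request("EFO_0001360", 10_000, 0.99)
        assert req.url == (
            "https://platform-api.opentargets.io/v3/platform/public/association/filter"
            "?disease=EFO_0001360&size=10000&scorevalue_min=0.99"
        )

    @pytest.mark.parametrize(
        "disease,fragment",
        [("Orphanet_71277", "disease=Orphanet_71277"), ("MONDO_0100096", "disease=MONDO_0100096")],
    )
    def test_association_request_carries_disease_id(self, disease, fragment):
        assert fragment in build_association_request(disease, 10_000, 0.99).url

    def test_association_request_edge_parameters(self):
        req = build_association_request("MONDO_0100096", 1, 0.0)
        params = req.query_params
        assert params["size"] == "1"
        assert float(params["scorevalue_min"]) == 0.0

    def test_empty_disease_rejected(self):
        with pytest.raises(ValidationError):
            build_association_request("", 10, 0.5)

    @pytest.mark.parametrize("offset,suffix", [(0, "limit=1000&offset=0"), (2000, "offset=2000")])
    def test_activity_request_offsets(self, offset, suffix):
        req = build_activity_request("CHEMBL5118", 1000, offset)
        assert req.url.startswith(
            "https://www.ebi.ac.uk/chembl/api/data/activity?target_chembl_id=CHEMBL5118"
        )
        assert req.url.endswith(suffix)

    def test_activity_request_validates_id(self):
        with pytest.raises(ValidationError):
            build_activity_request("5118", 1000, 0)
        build_activity_request("CHEMBL1", 10, 0)  # minimal well-formed id

    def test_iuphar_request_pair(self):
        substrates, interactions = build_iuphar_requests(2421)
        assert substrates.url.endswith("/targets/2421/substrates")
        assert interactions.url.endswith("/targets/2421/interactions")
        with pytest.raises(ValidationError):
            build_iuphar_requests(0)

    @given(
        disease=st.from_regex(r"[A-Za-z]+_[0-9]{4,7}", fullmatch=True),
        size=st.integers(1, 100_000),
        score=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_association_round_trip(self, disease, size, score):
        """URL query strings parse back to the builder's inputs."""
        params = build_association_request(disease, size, score).query_params
        assert params["disease"] == disease
        assert int(params["size"]) == size
        assert math.isclose(float(params["scorevalue_min"]), score)

    @given(limit=st.integers(1, 5000), offset=st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_activity_round_trip(self, limit, offset):
        params = build_activity_request("CHEMBL5118", limit, offset).query_params
        assert (int(params["limit"]), int(params["offset"])) == (limit, offset)

    def test_timeout_must_exceed_two_seconds(self):
        with pytest.raises(ValidationError):
            ApiRequest(url="https://example.org/x", timeout=2.0)


class TestStatusClassification:
    @pytest.mark.parametrize(
        "code,expected",
        [(200, "success"), (404, "client_error"), (599, "server_error"),
         (100, "informational"), (301, "redirect"), (299, "success")],
    )
    def test_printed_ranges(self, code, expected):
        assert classify_status(code) == expected

    @given(st.integers(100, 599))
    @settings(max_examples=200, deadline=None)
    def test_partition_no_overlap(self, code):
        """Every code in 100-599 lands in exactly one class."""
        matches = [
            name for lo, hi, name in retrieval.STATUS_CLASSES if lo <= code <= hi
        ]
        assert len(matches) == 1
        assert classify_status(code) == matches[0]

    @pytest.mark.parametrize("code", [99, 600, -1])
    def test_out_of_range_rejected(self, code):
        with pytest.raises(ValidationError):
            classify_status(code)


class TestPagination:
    def test_worked_example_three_iterations(self):
        plan = plan_pagination(2410, 1000)
        assert plan.offsets == (0, 1000, 2000)

    @pytest.mark.parametrize(
        "total,page,expected",
        [(1000, 1000, (0,)), (0, 1000, ()), (1, 1000, (0,)), (1001, 1000, (0, 1000))],
    )
    def test_boundaries(self, total, page, expected):
        assert plan_pagination(total, page).offsets == expected

    def test_invalid_page_size(self):
        with pytest.raises(ValidationError):
            plan_pagination(10, 0)

    @given(total=st.integers(0, 50), page=st.integers(1, 7))
    @settings(max_examples=400, deadline=None)
    def test_exhaustive_coverage(self, total, page):
        """One request per offset retrieves every record exactly once."""
        plan = plan_pagination(total, page)
        assert len(plan.offsets) == math.ceil(total / page)
        fetched = []
        for offset in plan.offsets:
            fetched.extend(range(offset, min(offset + page, total)))
        assert fetched == list(range(total))
        assert (total == 0) == (plan.offsets == ())


class TestAssociationParsing:
    PAYLOAD = {
        "data": [
            {
                "target": {
                    "id": "ENSG00000100170",
                    "gene_info": {"name": "solute carrier family 2 member 1", "symbol": "SLC2A1"},
                },
                "association_score": {"overall": 1.0},
            },
            {
                "target": {"id": "ENSG00000130234", "gene_info": {"name": "ACE2"}},
                "association_score": {"overall": 0.99},
            },
        ]
    }

    def test_two_targets_parsed(self):
        records = parse_association_payload(self.PAYLOAD, disease_id="Orphanet_71277")
        assert len(records) == 2
        first = records[0]
        assert first.target_id == "ENSG00000100170"
        assert first.gene_symbol == "SLC2A1"
        assert first.association_score == 1.0
        assert first.disease_id == "Orphanet_71277"

    def test_missing_symbol_tolerated(self):
        records = parse_association_payload(self.PAYLOAD)
        assert records[1].gene_symbol is None

    def test_empty_data_array(self):
        assert parse_association_payload({"data": []}) == []

    def test_missing_data_key_names_path(self):
        with pytest.raises(ParseError, match="data"):
            parse_association_payload({"results": []})


class TestUniprotXrefs:
    DOC = """<uniprot xmlns="http://uniprot.org/uniprot"><entry>
        <dbReference type="PubMed" id="12730500"/>
        <dbReference type="PDB" id="6NUR"/>
        <dbReference type="Pfam" id="PF06478"/>
        <dbReference type="PDB" id="2VYI"/>
        <dbReference type="PDB" id="6NUR"/>
    </entry></uniprot>"""

    def test_pdb_type_only_in_document_order_deduplicated(self):
        assert parse_uniprot_pdb_xrefs(self.DOC) == ["6NUR", "2VYI"]

    def test_non_pdb_references_ignored(self):
        doc = """<uniprot xmlns="http://uniprot.org/uniprot"><entry>
            <dbReference type="Pfam" id="PF06478"/></entry></uniprot>"""
        assert parse_uniprot_pdb_xrefs(doc) == []

    def test_entry_without_references(self):
        doc = '<uniprot xmlns="http://uniprot.org/uniprot"><entry/></uniprot>'
        assert parse_uniprot_pdb_xrefs(doc) == []

    def test_non_xml_raises_parse_error(self):
        with pytest.raises(ParseError):
            parse_uniprot_pdb_xrefs("{not xml}")

    def test_generated_fixture_round_trip(self):
        doc = _uniprot_entry_xml("P10001", ["1SA0", "1SA1"])
        assert parse_uniprot_pdb_xrefs(doc) == ["1SA0", "1SA1"]


class TestBestStructures:
    def test_deduplication_and_upper_case(self):
        doc = {
            "Q9BYF1": [
                {"pdb_id": "6m17", "resolution": 2.9},
                {"pdb_id": "6M17", "resolution": 2.9},
                {"pdb_id": "1r42", "resolution": 2.2},
            ]
        }
        assert parse_best_structures(doc) == ["6M17", "1R42"]

    def test_empty_mapping(self):
        assert parse_best_structures({}) == []

    def test_absent_pdb_id_fields_yield_empty(self):
        assert parse_best_structures({"P12345": [{"resolution": 2.0}]}) == []


class TestBoundLigands:
    def test_printed_component_list(self):
        doc = {"rcsb_entry_info": {"nonpolymer_bound_components": ["BME", "NAG", "XU3"]}}
        assert parse_bound_ligands(doc) == ["BME", "NAG", "XU3"]

    def test_entry_without_ligands(self):
        assert parse_bound_ligands({"rcsb_entry_info": {}}) == []
        assert parse_bound_ligands({}) == []

    def test_blocklisted_agent_excluded(self):
        doc = {"rcsb_entry_info": {"nonpolymer_bound_components": ["INM", "XU3"]}}
        assert parse_bound_ligands(doc, blocklist={"INM"}) == ["XU3"]


class TestChemcompSmiles:
    def test_descriptor_returned(self):
        doc = {"rcsb_chem_comp_descriptor": {"smiles": "CCO"}}
        assert parse_chemcomp_smiles(doc) == "CCO"

    def test_missing_descriptor_is_typed_error(self):
        with pytest.raises(NoStructureError):
            parse_chemcomp_smiles({"rcsb_chem_comp_descriptor": {}})

    def test_sugar_fixture_parses_to_oxygen_heterocycle(self):
        # synthetic stand-in for a recorded N-acetylglucosamine payload
        from rdkit import Chem

        doc = {
            "rcsb_chem_comp_descriptor": {
                "smiles": "CC(=O)NC1C(O)OC(CO)C(O)C1O"
            }
        }
        mol = Chem.MolFromSmiles(parse_chemcomp_smiles(doc))
        ring_info = mol.GetRingInfo()
        assert any(
            any(mol.GetAtomWithIdx(i).GetAtomicNum() == 8 for i in ring)
            for ring in ring_info.AtomRings()
        )


class TestActivityPages:
    def _page(self, rows, total, offset=0):
        return _activity_page_xml(rows, total, 1000, offset)

    ROW = {
        "activity_comment": "active",
        "assay_description": "binding assay",
        "molecule_chembl_id": "CHEMBL25",
        "molecule_pref_name": "ASPIRIN",
        "standard_type": "IC50",
        "standard_units": "nM",
        "standard_value": "5",
        "standard_relation": "=",
        "parent_molecule_chembl_id": "CHEMBL25",
        "document_chembl_id": "CHEMBL1158643",
        "canonical_smiles": "CC(=O)Oc1ccccc1C(=O)O",
        "target_chembl_id": "CHEMBL5118",
    }

    def test_fields_and_total_count(self):
        records, total = parse_activity_page(self._page([self.ROW, self.ROW], 2410))
        assert total == 2410
        assert len(records) == 2
        record = records[0]
        assert record.molecule_id == "CHEMBL25"
        assert record.endpoint == "IC50"
        assert record.unit == "nM"
        assert record.value == 5.0
        assert record.document_ref == "CHEMBL1158643"
        assert record.parent_molecule_id == "CHEMBL25"

    def test_five_nanomolar_row_reaches_px_8_301(self):
        from scaffquery.bioactivity import label_record

        records, _ = parse_activity_page(self._page([self.ROW], 1))
        label_record(records[0], cutoff=9.0)
        assert records[0].px == pytest.approx(8.301, abs=5e-4)

    def test_empty_page_keeps_declared_count(self):
        records, total = parse_activity_page(self._page([], 2410, offset=3000))
        assert records == [] and total == 2410

    def test_missing_value_kept_and_flagged(self):
        row = {k: v for k, v in self.ROW.items() if k != "standard_value"}
        records, _ = parse_activity_page(self._page([row], 1))
        assert records[0].value is None
        assert "missing_standard_value" in records[0].flags

    def test_missing_total_count_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_activity_page(b"<response><activities/></response>")

    @pytest.mark.parametrize("total,page", [(t, p) for t in (0, 1, 7, 23, 50) for p in (1, 3, 7)])
    def test_paginated_pages_concatenate_exactly(self, total, page):
        """Concatenating the pages of a pagination plan yields every record
        exactly once (ids distinct, count equals total_count)."""
        plan = plan_pagination(total, page)
        seen = []
        for offset in plan.offsets:
            n = min(page, total - offset)
            rows = [
                dict(self.ROW, molecule_chembl_id=f"CHEMBL{offset + i}")
                for i in range(n)
            ]
            records, declared = parse_activity_page(self._page(rows, total, offset))
            assert declared == total
            seen.extend(r.molecule_id for r in records)
        assert len(seen) == total
        assert len(set(seen)) == total


class TestPubChemChain:
    def fixtures(self):
        return PubChemFixtures(
            uniprot_to_aids={"P09958": [1000], "P62937": [2000]},
            aid_to_cids={1000: [11, 12], 2000: []},
            cid_info={
                11: {"name": "CHEMBL25", "endpoint": "Ki", "value": 5.0, "unit": "nM"},
                12: {"name": "compound-12", "endpoint": "IC50", "value": 50.0, "unit": "nM"},
            },
            chembl_names={"CHEMBL25": "aspirin"},
        )

    def test_one_aid_two_cids(self):
        records = map_pubchem_target("P09958", self.fixtures())
        assert len(records) == 2
        assert {r.molecule_id for r in records} == {"11", "12"}

    def test_chembl_named_compound_resolved(self):
        records = map_pubchem_target("P09958", self.fixtures())
        assert records[0].molecule_name == "aspirin"

    def test_dangling_aid_skipped(self):
        assert map_pubchem_target("P62937", self.fixtures()) == []

    def test_unknown_target_empty(self):
        assert map_pubchem_target("P00000", self.fixtures()) == []

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "pubchem.json"
        self.fixtures().to_json(path)
        loaded = PubChemFixtures.from_json(path)
        assert loaded.aid_to_cids == {1000: [11, 12], 2000: []}
        assert map_pubchem_target("P09958", loaded)[0].molecule_name == "aspirin"


class TestMappingsAndHeaders:
    def test_uniprot_mapping_prefers_reviewed(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "Entry\tCross-reference (OpenTargets)\tStatus\n"
            "A0A024\tENSG00000100170;\tunreviewed\n"
            "P11166\tENSG00000100170;\treviewed\n"
            "Q9BYF1\tENSG00000130234;\treviewed\n"
        )
        mapping = retrieval.read_uniprot_mapping(path)
        assert mapping == {"ENSG00000100170": "P11166", "ENSG00000130234": "Q9BYF1"}

    def test_pdb_header_fields(self):
        from scaffquery.synthetic import _pdb_text

        props = parse_pdb_header(_pdb_text("2VYI", 1.75))
        assert props["experimental_method"] == "X-RAY DIFFRACTION"
        assert props["resolution"] == pytest.approx(1.75)
        assert props["r_factor"] == pytest.approx(0.18)
        assert props["space_group"] == "P 21 21 21"

    def test_unparseable_header_keeps_nulls(self):
        props = parse_pdb_header("garbage\nlines\n")
        assert props["experimental_method"] is None
        assert props["resolution"] is None


class TestFixtureTransport:
    def test_round_trip_by_url(self, tmp_path):
        request = build_association_request("SYN_0001", 10, 0.5)
        (tmp_path / fixture_filename(request.url)).write_text(json.dumps({"data": []}))
        transport = retrieval.FixtureTransport(tmp_path)
        assert transport.get_json(request) == {"data": []}

    def test_missing_fixture_is_error(self, tmp_path):
        transport = retrieval.FixtureTransport(tmp_path)
        with pytest.raises(retrieval.RetrievalError):
            transport.get(build_association_request("SYN_MISSING", 10, 0.5))
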