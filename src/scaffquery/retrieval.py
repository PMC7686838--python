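"""API request construction and payload parsing for target/ligand evidence.

Five public-resource payload dialects feed the repurposing pipeline:

* Open Targets association JSON (disease -> target records),
* UniProt entry XML (protein -> PDB cross-references),
* PDBe best-structures JSON (protein -> ranked PDB entries),
* RCSB entry / chemcomp JSON (PDB entry -> bound ligands -> SMILES),
* ChEMBL activity XML (target -> paginated bioactivity rows),

plus the Guide-to-Pharmacology (IUPHAR) interaction JSON and a
fixture-backed PubChem AID/CID chain.  Every parser is a pure function of
the payload so the whole module is testable on canned files with no
network; live HTTP sits behind the small :class:`Transport` contract.
"""

from __future__ import annotations

import json
import logging
import math
import re
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .bioactivity import BioactivityRecord

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Endpoint templates (the payload dialects these parsers target)
# ---------------------------------------------------------------------------

OPENTARGETS_ASSOCIATION_URL = (
    "https://platform-api.opentargets.io/v3/platform/public/association/filter"
    "?disease={disease}&size={size}&scorevalue_min={min_score}"
)
UNIPROT_ENTRY_URL = "https://www.uniprot.org/uniprot/{acc}.xml"
UNIPROT_COVID_ENTRY_URL = (
    "https://www.ebi.ac.uk/uniprot/api/covid-19/uniprotkb/accession/{acc}.xml"
)
PDBE_BEST_STRUCTURES_URL = (
    "https://www.ebi.ac.uk/pdbe/graph-api/mappings/best_structures/{acc}"
)
RCSB_ENTRY_URL = "https://data.rcsb.org/rest/v1/core/entry/{pdb_id}"
RCSB_CHEMCOMP_URL = "https://data.rcsb.org/rest/v1/core/chemcomp/{comp_id}"
PDB_FILE_URL = "https://files.rcsb.org/view/{pdb_id}.pdb"
CHEMBL_ACTIVITY_URL = (
    "https://www.ebi.ac.uk/chembl/api/data/activity"
    "?target_chembl_id={target_id}&limit={limit}&offset={offset}"
)
IUPHAR_SUBSTRATES_URL = (
    "http://www.guidetopharmacology.org/services/targets/{target_id}/substrates"
)
IUPHAR_INTERACTIONS_URL = (
    "http://www.guidetopharmacology.org/services/targets/{target_id}/interactions"
)
IUPHAR_LIGAND_STRUCTURE_URL = (
    "http://www.guidetopharmacology.org/services/ligands/{ligand_id}/structure"
)

UNIPROT_NS = "http://uniprot.org/uniprot"

#: The vendor's 2 s request timeout is usually insufficient for the larger
#: payloads; 60 s is ample for every endpoint used here.
DEFAULT_TIMEOUT = 60.0

UNIPROT_ACCESSION_RE = re.compile(
    r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}$"
)
CHEMBL_ID_RE = re.compile(r"^CHEMBL\d+$")
PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


class RetrievalError(Exception):
    """Base class for request/parse failures in this module."""


class ValidationError(RetrievalError):
    """Malformed input to a request builder."""


class ParseError(RetrievalError):
    """A payload does not match the expected dialect."""


class NoStructureError(RetrievalError):
    """A chemical component payload carries no structure descriptor."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TargetRecord:
    """A disease-associated protein with its cross-reference identifiers."""

    disease_id: str
    target_id: str
    gene_name: str | None = None
    gene_symbol: str | None = None
    association_score: float | None = None
    uniprot_id: str | None = None
    chembl_target_id: str | None = None
    iuphar_target_id: int | None = None
    pubchem_aids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.association_score is not None and not (
            0.0 <= self.association_score <= 1.0
        ):
            raise ValidationError(
                f"association_score {self.association_score!r} outside [0, 1]"
            )
        if self.uniprot_id is not None and not UNIPROT_ACCESSION_RE.match(
            self.uniprot_id
        ):
            raise ValidationError(f"not a UniProt accession: {self.uniprot_id!r}")


@dataclass(frozen=True)
class ApiRequest:
    """One GET request: URL, timeout, and the content type we expect back."""

    url: str
    timeout: float = DEFAULT_TIMEOUT
    expected_content: str = "json"  # json | xml | tsv | pdb

    def __post_init__(self) -> None:
        parsed = urllib.parse.urlparse(self.url)
        if not parsed.scheme or not parsed.netloc:
            raise ValidationError(f"not an absolute URL: {self.url!r}")
        if self.timeout <= 2:
            raise ValidationError("timeout must exceed the insufficient 2 s default")
        if self.expected_content not in {"json", "xml", "tsv", "pdb"}:
            raise ValidationError(f"unknown content type {self.expected_content!r}")

    @property
    def query_params(self) -> dict[str, str]:
        return {
            k: v[0]
            for k, v in urllib.parse.parse_qs(
                urllib.parse.urlparse(self.url).query
            ).items()
        }


@dataclass(frozen=True)
class PaginationPlan:
    """Offsets needed to page through ``total_count`` records."""

    total_count: int
    page_size: int
    offsets: tuple[int, ...]


@dataclass
class StructureEntry:
    """One protein/PDB pair with experimental metadata and bound ligands."""

    uniprot_id: str
    pdb_id: str
    title: str | None = None
    experimental_method: str | None = None
    resolution: float | None = None
    r_factor: float | None = None
    space_group: str | None = None
    model_count: int | None = None
    bound_ligands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not PDB_ID_RE.match(self.pdb_id):
            raise ValidationError(f"not a PDB id: {self.pdb_id!r}")
        for code in self.bound_ligands:
            if not re.match(r"^[A-Za-z0-9]{1,5}$", code):
                raise ValidationError(f"not a chemical-component code: {code!r}")


# ---------------------------------------------------------------------------
# Request builders
# ---------------------------------------------------------------------------


def build_association_request(
    disease_id: str, size: int = 10_000, min_score: float = 0.99
) -> ApiRequest:
    """Disease -> target association request.

    ``size`` caps the number of associated targets returned and
    ``min_score`` prioritizes targets by their evidence-based association
    score (a fraction in [0, 1]).
    """
    if not disease_id:
        raise ValidationError("disease_id must be non-empty")
    if size < 1:
        raise ValidationError("size must be positive")
    if not 0.0 <= min_score <= 1.0:
        raise ValidationError("min_score must lie in [0, 1]")
    url = OPENTARGETS_ASSOCIATION_URL.format(
        disease=disease_id, size=size, min_score=_format_number(min_score)
    )
    return ApiRequest(url=url, expected_content="json")


def _format_number(x: float) -> str:
    # 0.99 -> "0.99", 0.0 -> "0.0": repr of a float is already minimal
    return repr(float(x))


def build_uniprot_entry_request(accession: str, covid_prerelease: bool = False) -> ApiRequest:
    """Entry-XML request; the COVID-19 pre-release accessions live under an
    alternate URL form selected by ``covid_prerelease``."""
    if not accession:
        raise ValidationError("accession must be non-empty")
    template = UNIPROT_COVID_ENTRY_URL if covid_prerelease else UNIPROT_ENTRY_URL
    return ApiRequest(url=template.format(acc=accession), expected_content="xml")


def build_best_structures_request(accession: str) -> ApiRequest:
    if not accession:
        raise ValidationError("accession must be non-empty")
    return ApiRequest(
        url=PDBE_BEST_STRUCTURES_URL.format(acc=accession), expected_content="json"
    )


def build_rcsb_entry_request(pdb_id: str) -> ApiRequest:
    if not PDB_ID_RE.match(pdb_id):
        raise ValidationError(f"not a PDB id: {pdb_id!r}")
    return ApiRequest(url=RCSB_ENTRY_URL.format(pdb_id=pdb_id), expected_content="json")


def build_chemcomp_request(comp_id: str) -> ApiRequest:
    if not re.match(r"^[A-Za-z0-9]{1,5}$", comp_id):
        raise ValidationError(f"not a chemical-component code: {comp_id!r}")
    return ApiRequest(
        url=RCSB_CHEMCOMP_URL.format(comp_id=comp_id), expected_content="json"
    )


def build_pdb_file_request(pdb_id: str) -> ApiRequest:
    if not PDB_ID_RE.match(pdb_id):
        raise ValidationError(f"not a PDB id: {pdb_id!r}")
    return ApiRequest(url=PDB_FILE_URL.format(pdb_id=pdb_id), expected_content="pdb")


def build_activity_request(
    target_chembl_id: str, limit: int = 1000, offset: int = 0
) -> ApiRequest:
    """Bioactivity page request; ``offset`` records are skipped before the
    page of at most ``limit`` rows is returned."""
    if not CHEMBL_ID_RE.match(target_chembl_id):
        raise ValidationError(f"not a ChEMBL target id: {target_chembl_id!r}")
    if limit < 1:
        raise ValidationError("limit must be positive")
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    url = CHEMBL_ACTIVITY_URL.format(
        target_id=target_chembl_id, limit=limit, offset=offset
    )
    return ApiRequest(url=url, expected_content="xml")


def build_iuphar_requests(iuphar_target_id: int) -> tuple[ApiRequest, ApiRequest]:
    """(substrates, interactions) request pair for one IUPHAR target id."""
    if iuphar_target_id <= 0:
        raise ValidationError("IUPHAR target id must be positive")
    substrates = ApiRequest(
        url=IUPHAR_SUBSTRATES_URL.format(target_id=iuphar_target_id),
        expected_content="json",
    )
    interactions = ApiRequest(
        url=IUPHAR_INTERACTIONS_URL.format(target_id=iuphar_target_id),
        expected_content="json",
    )
    return substrates, interactions


def build_iuphar_ligand_request(ligand_id: int) -> ApiRequest:
    if ligand_id <= 0:
        raise ValidationError("IUPHAR ligand id must be positive")
    return ApiRequest(
        url=IUPHAR_LIGAND_STRUCTURE_URL.format(ligand_id=ligand_id),
        expected_content="json",
    )


# ---------------------------------------------------------------------------
# HTTP status classification
# ---------------------------------------------------------------------------

STATUS_CLASSES = (
    (100, 199, "informational"),
    (200, 299, "success"),
    (300, 399, "redirect"),
    (400, 499, "client_error"),
    (500, 599, "server_error"),
)


def classify_status(code: int) -> str:
    """Map an HTTP status code onto its class.

    Only ``success`` responses proceed downstream; everything else is
    filtered out as useless data.
    """
    for lo, hi, name in STATUS_CLASSES:
        if lo <= code <= hi:
            return name
    raise ValidationError(f"HTTP status code {code!r} outside 100-599")


# ---------------------------------------------------------------------------
# Pagination
# ---------------------------------------------------------------------------


def plan_pagination(total_count: int, page_size: int = 1000) -> PaginationPlan:
    """Offsets required to fetch ``total_count`` records ``page_size`` at a
    time: ceil(total/page_size) iterations at offsets 0, page_size, ...

    2410 records at page size 1000 therefore need three iterations, at
    offsets 0, 1000, and 2000.
    """
    if page_size < 1:
        raise ValidationError("page_size must be positive")
    if total_count < 0:
        raise ValidationError("total_count must be non-negative")
    n_pages = math.ceil(total_count / page_size)
    offsets = tuple(i * page_size for i in range(n_pages))
    return PaginationPlan(total_count=total_count, page_size=page_size, offsets=offsets)


# ---------------------------------------------------------------------------
# Payload parsers
# ---------------------------------------------------------------------------


def parse_association_payload(doc: Mapping, disease_id: str = "") -> list[TargetRecord]:
    """Parse an association payload into one record per target.

    Extracted fields follow the payload's bracket paths
    ``$['data'][*]['target']['id']``, ``...['gene_info']['name']`` and
    ``...['gene_info']['symbol']``; list-valued cells are flattened to one
    row per target.
    """
    if "data" not in doc:
        raise ParseError("association payload lacks the $['data'] array")
    records: list[TargetRecord] = []
    for element in doc["data"]:
        target = element.get("target", {})
        gene_info = target.get("gene_info", {})
        score = element.get("association_score")
        if isinstance(score, Mapping):
            score = score.get("overall")
        records.append(
            TargetRecord(
                disease_id=disease_id or element.get("disease", {}).get("id", ""),
                target_id=target.get("id", ""),
                gene_name=gene_info.get("name"),
                gene_symbol=gene_info.get("symbol"),
                association_score=score,
            )
        )
    return records


def _as_xml_root(doc: bytes | str | etree._Element) -> etree._Element:
    if isinstance(doc, etree._Element):
        return doc
    if isinstance(doc, str):
        doc = doc.encode()
    try:
        return etree.fromstring(doc)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed XML: {exc}") from exc


def parse_uniprot_pdb_xrefs(doc: bytes | str | etree._Element) -> list[str]:
    """PDB ids cross-referenced by a UniProt entry.

    Follows ``/uniprot/entry/dbReference[@type='PDB']/@id`` in the
    ``http://uniprot.org/uniprot`` namespace: only ``dbReference`` elements
    whose ``type`` is exactly ``PDB`` contribute, in document order and with
    duplicates removed.
    """
    root = _as_xml_root(doc)
    ids = root.xpath(
        "/u:uniprot/u:entry/u:dbReference[@type='PDB']/@id",
        namespaces={"u": UNIPROT_NS},
    )
    seen: dict[str, None] = {}
    for pdb_id in ids:
        seen.setdefault(pdb_id, None)
    return list(seen)


def _collect_key(node, key: str, out: list) -> None:
    if isinstance(node, Mapping):
        for k, v in node.items():
            if k == key and isinstance(v, (str, int)):
                out.append(v)
            else:
                _collect_key(v, key, out)
    elif isinstance(node, list):
        for item in node:
            _collect_key(item, key, out)


def parse_best_structures(doc: Mapping) -> list[str]:
    """All ``pdb_id`` values from a best-structures payload (keyed by
    accession), deduplicated and normalized to upper case."""
    found: list = []
    _collect_key(doc, "pdb_id", found)
    if not found and doc:
        logger.warning("best-structures payload contains no pdb_id fields")
    seen: dict[str, None] = {}
    for pdb_id in found:
        seen.setdefault(str(pdb_id).upper(), None)
    return list(seen)


def parse_bound_ligands(
    doc: Mapping, blocklist: Iterable[str] = ()
) -> list[str]:
    """Non-polymer bound-component codes of one PDB entry.

    An absent key is legal (entries without a co-resolved ligand are
    dropped downstream).  ``blocklist`` removes retained co-crystallization
    agents (buffers, cryoprotectants, isonicotinamide and friends); see
    :data:`scaffquery.chemstruct.DEFAULT_COCRYSTAL_BLOCKLIST`.
    """
    components = doc.get("rcsb_entry_info", {}).get("nonpolymer_bound_components")
    if not components:
        return []
    blocked = {c.upper() for c in blocklist}
    return [c for c in components if c.upper() not in blocked]


def parse_chemcomp_smiles(doc: Mapping) -> str:
    """The descriptor SMILES of one chemical component."""
    smiles = doc.get("rcsb_chem_comp_descriptor", {}).get("smiles")
    if not smiles:
        raise NoStructureError("chemcomp payload carries no SMILES descriptor")
    return smiles


_ACTIVITY_FIELDS = {
    "activity_comment": "activity_comment",
    "assay_description": "assay_description",
    "molecule_chembl_id": "molecule_id",
    "molecule_pref_name": "molecule_name",
    "standard_type": "endpoint",
    "standard_units": "unit",
    "standard_relation": "relation",
    "parent_molecule_chembl_id": "parent_molecule_id",
    "document_chembl_id": "document_ref",
    "canonical_smiles": "smiles",
    "target_chembl_id": "target_chembl_id",
}


def parse_activity_page(
    doc: bytes | str | etree._Element,
) -> tuple[list[BioactivityRecord], int]:
    """One page of activity XML -> (records, declared total_count).

    ``total_count`` is constant across the pages of one target and drives
    :func:`plan_pagination`.  Rows without a ``standard_value`` are kept
    with pX unset and flagged rather than dropped.
    """
    root = _as_xml_root(doc)
    total_node = root.find(".//total_count")
    if total_node is None or total_node.text is None:
        raise ParseError("activity page lacks the <total_count> element")
    total_count = int(total_node.text)

    records: list[BioactivityRecord] = []
    for node in root.iter("activity"):
        kwargs: dict = {"source": "chembl"}
        for tag, attr in _ACTIVITY_FIELDS.items():
            child = node.find(tag)
            if child is not None and child.text:
                kwargs[attr] = child.text
        value_node = node.find("standard_value")
        record = BioactivityRecord(**kwargs)
        if value_node is not None and value_node.text:
            record.value = float(value_node.text)
        else:
            record.flags.append("missing_standard_value")
        records.append(record)
    return records, total_count


def parse_iuphar_interactions(
    doc: Sequence[Mapping], uniprot_id: str | None = None
) -> list[BioactivityRecord]:
    """Interaction/substrate JSON -> bioactivity records.

    Affinity values arrive already on the negative-log scale, with the
    affinity type naming the endpoint and the action annotating the
    interaction mode.
    """
    records: list[BioactivityRecord] = []
    for row in doc:
        record = BioactivityRecord(
            source="iuphar",
            uniprot_id=uniprot_id,
            molecule_id=str(row.get("ligandId", "")),
            molecule_name=row.get("ligandName") or None,
            endpoint=row.get("affinityType", ""),
            relation="=",
            document_ref=str(row["refs"][0].get("pmid"))
            if row.get("refs")
            else None,
            smiles=row.get("smiles"),
        )
        affinity = row.get("affinity")
        try:
            record.px = float(affinity)
        except (TypeError, ValueError):
            record.flags.append("missing_affinity")
        if row.get("action"):
            record.flags.append(f"action:{row['action']}")
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# PubChem fixture chain
# ---------------------------------------------------------------------------


@dataclass
class PubChemFixtures:
    """The AID -> CID -> (value, name) chains a PubChem crawl would yield.

    ``chembl_names`` backs the secondary lookup for compounds whose PubChem
    name is itself a molecule ChEMBL identifier.
    """

    uniprot_to_aids: dict[str, list[int]] = field(default_factory=dict)
    aid_to_cids: dict[int, list[int]] = field(default_factory=dict)
    cid_info: dict[int, dict] = field(default_factory=dict)
    chembl_names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "PubChemFixtures":
        raw = json.loads(Path(path).read_text())
        return cls(
            uniprot_to_aids={k: list(v) for k, v in raw.get("uniprot_to_aids", {}).items()},
            aid_to_cids={int(k): list(v) for k, v in raw.get("aid_to_cids", {}).items()},
            cid_info={int(k): dict(v) for k, v in raw.get("cid_info", {}).items()},
            chembl_names=dict(raw.get("chembl_names", {})),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "uniprot_to_aids": self.uniprot_to_aids,
                    "aid_to_cids": self.aid_to_cids,
                    "cid_info": self.cid_info,
                    "chembl_names": self.chembl_names,
                },
                indent=1,
                sort_keys=True,
            )
        )


def map_pubchem_target(
    uniprot_id: str, fixtures: PubChemFixtures
) -> list[BioactivityRecord]:
    """Resolve a UniProt accession through the AID -> CID chain into
    bioactivity records; ChEMBL-identifier compound names are resolved via
    the secondary name lookup."""
    records: list[BioactivityRecord] = []
    for aid in fixtures.uniprot_to_aids.get(uniprot_id, []):
        cids = fixtures.aid_to_cids.get(aid)
        if not cids:
            logger.warning("AID %s has no compounds; skipped", aid)
            continue
        for cid in cids:
            info = fixtures.cid_info.get(cid, {})
            name = info.get("name")
            if name and CHEMBL_ID_RE.match(name):
                name = fixtures.chembl_names.get(name, name)
            records.append(
                BioactivityRecord(
                    source="pubchem",
                    uniprot_id=uniprot_id,
                    molecule_id=str(cid),
                    molecule_name=name,
                    endpoint=info.get("endpoint", ""),
                    value=info.get("value"),
                    unit=info.get("unit", ""),
                    relation=info.get("relation", "="),
                    document_ref=str(info["pmid"]) if info.get("pmid") else None,
                    smiles=info.get("smiles"),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Cross-reference mapping readers
# ---------------------------------------------------------------------------


def read_uniprot_mapping(path: str | Path) -> dict[str, str]:
    """Bulk UniProt <-> Open Targets mapping from an exported TSV.

    Columns: accession, Open Targets (Ensembl gene) id, reviewed status.
    One gene may map to several accessions; reviewed entries win, then the
    first listed, so the mapping is deterministic in file order.
    """
    mapping: dict[str, tuple[str, bool]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row = dict(zip(header, parts))
            acc = row.get("Entry") or parts[0]
            ot_ids = (row.get("Cross-reference (OpenTargets)") or parts[1]).strip(";")
            reviewed = (row.get("Status") or (parts[2] if len(parts) > 2 else "")) == "reviewed"
            for ot_id in filter(None, ot_ids.split(";")):
                current = mapping.get(ot_id)
                if current is None or (reviewed and not current[1]):
                    mapping[ot_id] = (acc, reviewed)
    return {k: v[0] for k, v in mapping.items()}


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV (with header) -> dict; used for the UniProt->ChEMBL
    and UniProt->IUPHAR target id maps."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                mapping.setdefault(parts[0], parts[1])
    return mapping


# ---------------------------------------------------------------------------
# PDB header properties
# ---------------------------------------------------------------------------


def parse_pdb_header(text: str) -> dict:
    """Experimental properties from the header records of PDB-format text.

    Unparseable headers simply yield null fields; the entry itself is kept.
    """
    props: dict = {
        "title": None,
        "experimental_method": None,
        "resolution": None,
        "r_factor": None,
        "space_group": None,
        "model_count": None,
    }
    title_parts: list[str] = []
    for line in text.splitlines():
        rec = line[:6].strip()
        try:
            if rec == "TITLE":
                title_parts.append(line[10:80].strip())
            elif rec == "EXPDTA":
                props["experimental_method"] = line[10:79].strip()
            elif rec == "NUMMDL":
                props["model_count"] = int(line[10:14])
            elif rec == "CRYST1":
                sg = line[55:66].strip()
                props["space_group"] = sg or None
            elif rec == "REMARK" and line[7:10].strip() == "2":
                m = re.search(r"RESOLUTION\.\s+([0-9.]+)\s+ANGSTROM", line)
                if m:
                    props["resolution"] = float(m.group(1))
            elif rec == "REMARK" and line[7:10].strip() == "3":
                m = re.search(r"R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)", line)
                if m:
                    props["r_factor"] = float(m.group(1))
        except (ValueError, IndexError):
            continue
    if title_parts:
        props["title"] = " ".join(title_parts)
    return props


# ---------------------------------------------------------------------------
# Transport: fixtures by default, live HTTP only on request
# ---------------------------------------------------------------------------


def fixture_filename(url: str) -> str:
    """Deterministic flat filename for a URL, shared by the fixture writer
    and the fixture transport."""
    trimmed = re.sub(r"^https?://", "", url)
    return re.sub(r"[^A-Za-z0-9._-]", "_", trimmed)


class FixtureTransport:
    """Serves canned payloads from a directory keyed by request URL."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def get(self, request: ApiRequest) -> bytes:
        path = self.directory / fixture_filename(request.url)
        if not path.exists():
            raise RetrievalError(f"no fixture for {request.url} (expected {path.name})")
        return path.read_bytes()

    def get_json(self, request: ApiRequest):
        return json.loads(self.get(request))

    def get_text(self, request: ApiRequest) -> str:
        return self.get(request).decode()


class LiveTransport:
    """Thin urllib-based GET client with retries and exponential backoff.

    Non-success status classes drop the request (returning ``None`` from
    :meth:`try_get`) after logging, so useless rows never enter the tables.
    """

    def __init__(self, retries: int = 3, backoff: float = 1.0):
        self.retries = retries
        self.backoff = backoff

    def get(self, request: ApiRequest) -> bytes:
        last_error: Exception | None = None
        for attempt in range(self.retries):
            try:
                with urllib.request.urlopen(
                    request.url, timeout=request.timeout
                ) as response:
                    if classify_status(response.status) != "success":
                        raise RetrievalError(
                            f"{request.url}: status {response.status}"
                        )
                    return response.read()
            except (urllib.error.URLError, RetrievalError) as exc:
                last_error = exc
                logger.warning(
                    "GET %s failed (attempt %d/%d): %s",
                    request.url, attempt + 1, self.retries, exc,
                )
                time.sleep(self.backoff * 2**attempt)
        raise RetrievalError(f"GET {request.url} failed after retries: {last_error}")

    def try_get(self, request: ApiRequest) -> bytes | None:
        try:
            return self.get(request)
        except RetrievalError:
            return None

    def get_json(self, request: ApiRequest):
        return json.loads(self.get(request))

    def get_text(self, request: ApiRequest) -> str:
        return self.get(request).decode()
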