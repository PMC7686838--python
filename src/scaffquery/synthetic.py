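"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here with a known
answer key: compound libraries built from seed scaffold families plus
scaffold-free decoys, bioactivity tables with controlled pX
distributions, and canned API payload directories in the exact shapes the
retrieval parsers target.  All generators are pure functions of their
spec and RNG seed, so identical seeds give byte-identical files.

The generators emulate the *structure* of real inputs (payload shapes,
pagination, salts/stereo/charges to exercise standardization), not the
property distributions of real drug libraries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from lxml import etree
from rdkit import Chem

from . import retrieval
from .bioactivity import BioactivityRecord
from .chemstruct import CompoundRecord
from .retrieval import PubChemFixtures, fixture_filename

logger = logging.getLogger(__name__)

#: Default seed scaffolds: five multi-ring frameworks whose pairwise MCS
#: distance exceeds the 0.5 clustering threshold, so each family maps to
#: its own cluster and query.  (Single-ring frameworks would be removed by
#: the genericity filter and must not be used as seeds.)
DEFAULT_SEED_SCAFFOLDS: tuple[str, ...] = (
    "C1C2CC3CC1CC(C2)C3",          # adamantane
    "c1ccc2ncncc2c1",              # quinazoline
    "c1ccc2c(c1)OCO2",             # 1,3-benzodioxole
    "c1ccc(cc1)N1CCNCC1",          # phenylpiperazine
    "C1CC(OC1)n1cnc2ncncc21",      # purine nucleoside core
)

#: Substituents (attachment point = first atom), all inside the organic
#: element whitelist.
DEFAULT_SUBSTITUENT_POOL: tuple[str, ...] = (
    "C", "CC", "O", "N", "F", "OC", "C(=O)O",
)

_STEREO_SUBSTITUENT = "[C@@H](C)CC"   # sec-butyl: a genuine stereocenter
_CHARGED_SUBSTITUENT = "C(=O)[O-]"    # carboxylate: neutralizable charge

_DECOY_TOKENS = ("C", "C", "C", "O", "N", "C(C)", "C(=O)", "CC")


class SyntheticError(Exception):
    pass


@dataclass(frozen=True)
class ChemotypeLibrarySpec:
    """Recipe for a compound library with planted scaffold families."""

    seed_scaffolds: tuple[str, ...] = DEFAULT_SEED_SCAFFOLDS
    analogs_per_family: int = 8
    decoys: int = 50
    substituent_pool: tuple[str, ...] = DEFAULT_SUBSTITUENT_POOL
    salt_rate: float = 0.15
    stereo_rate: float = 0.2
    charge_rate: float = 0.15
    rng_seed: int = 2020
    id_prefix: str = "SYN"

    def __post_init__(self) -> None:
        for rate in (self.salt_rate, self.stereo_rate, self.charge_rate):
            if not 0.0 <= rate <= 1.0:
                raise SyntheticError(f"rate {rate} outside [0, 1]")
        mols = [Chem.MolFromSmiles(s) for s in self.seed_scaffolds]
        if any(m is None for m in mols):
            raise SyntheticError("seed scaffolds must be valid SMILES")
        for i, a in enumerate(mols):
            for j, b in enumerate(mols):
                if i != j and a.HasSubstructMatch(b):
                    raise SyntheticError(
                        f"seed scaffolds must be mutually non-matching: "
                        f"{self.seed_scaffolds[j]} matches within {self.seed_scaffolds[i]}"
                    )


def family_label(index: int) -> str:
    return f"family{index + 1}"


def family_seeds(spec: ChemotypeLibrarySpec) -> dict[str, str]:
    """family label -> canonical seed scaffold SMILES."""
    return {
        family_label(i): Chem.MolToSmiles(Chem.MolFromSmiles(s))
        for i, s in enumerate(spec.seed_scaffolds)
    }


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------


def _attach(mol: Chem.Mol, fragment_smiles: str, atom_idx: int) -> Chem.Mol | None:
    fragment = Chem.MolFromSmiles(fragment_smiles)
    if fragment is None:
        return None
    combined = Chem.RWMol(Chem.CombineMols(mol, fragment))
    combined.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _attachment_points(mol: Chem.Mol) -> list[int]:
    # carbon atoms with a hydrogen to give up
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]


def _make_analog(
    seed: Chem.Mol, spec: ChemotypeLibrarySpec, rng: np.random.Generator
) -> tuple[str, bool]:
    """One decorated analog of a seed scaffold.

    Substituents are plain side chains, so the analog's ring-plus-linker
    framework stays exactly the seed scaffold.  Returns (SMILES with any
    salt appended, carries_negative_charge).
    """
    n_subs = int(rng.integers(1, 4))
    mol = Chem.Mol(seed)
    charged = False
    want_stereo = rng.random() < spec.stereo_rate
    want_charge = rng.random() < spec.charge_rate
    for k in range(n_subs):
        points = _attachment_points(mol)
        if not points:
            break
        if want_stereo and k == 0:
            sub = _STEREO_SUBSTITUENT
        elif want_charge and k == n_subs - 1:
            sub = _CHARGED_SUBSTITUENT
            charged = True
        else:
            sub = spec.substituent_pool[int(rng.integers(len(spec.substituent_pool)))]
        attached = _attach(mol, sub, points[int(rng.integers(len(points)))])
        if attached is not None:
            mol = attached
    smiles = Chem.MolToSmiles(mol)
    if rng.random() < spec.salt_rate:
        smiles += ".[Na+]" if charged else ".Cl"
    return smiles, charged


def _make_decoy(spec: ChemotypeLibrarySpec, rng: np.random.Generator) -> str:
    """A ring-free (hence scaffold-free) chain molecule."""
    for _ in range(50):
        length = int(rng.integers(3, 9))
        tokens = ["C"] + [
            _DECOY_TOKENS[int(rng.integers(len(_DECOY_TOKENS)))] for _ in range(length)
        ]
        if rng.random() < spec.stereo_rate:
            tokens.insert(1 + int(rng.integers(len(tokens) - 1)), "[C@@H](O)")
        smiles = "".join(tokens)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetRingInfo().NumRings() > 0:
            continue
        smiles = Chem.MolToSmiles(mol)
        if rng.random() < spec.salt_rate:
            smiles += ".Cl"
        return smiles
    raise SyntheticError("could not generate a valid decoy")


def generate_chemotype_library(
    spec: ChemotypeLibrarySpec,
) -> tuple[list[CompoundRecord], dict[str, str]]:
    """Generate the library and its answer key.

    Returns (records, truth) where truth maps each compound id to its
    family label or ``"decoy"``.  Invariants enforced at generation time:
    every family member contains its seed scaffold as a substructure, and
    no decoy contains any seed scaffold.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seeds = [Chem.MolFromSmiles(s) for s in spec.seed_scaffolds]
    for seed_smiles, seed in zip(spec.seed_scaffolds, seeds):
        if _attach(seed, spec.substituent_pool[0], _attachment_points(seed)[0]) is None:
            raise SyntheticError(f"substituent pool incompatible with seed {seed_smiles}")
    records: list[CompoundRecord] = []
    truth: dict[str, str] = {}
    for fi, seed in enumerate(seeds):
        for j in range(spec.analogs_per_family):
            smiles, _ = _make_analog(seed, spec, rng)
            parent = Chem.MolFromSmiles(smiles.split(".")[0])
            if not parent.HasSubstructMatch(seed):
                raise SyntheticError(
                    f"analog {smiles} lost its seed scaffold {spec.seed_scaffolds[fi]}"
                )
            cid = f"{spec.id_prefix}_F{fi + 1}_{j:03d}"
            records.append(
                CompoundRecord(
                    source="synthetic", source_id=cid, name=cid, raw_structure=smiles
                )
            )
            truth[cid] = family_label(fi)
    for j in range(spec.decoys):
        smiles = _make_decoy(spec, rng)
        mol = Chem.MolFromSmiles(smiles.split(".")[0])
        if any(mol.HasSubstructMatch(seed) for seed in seeds):
            raise SyntheticError(f"decoy {smiles} matches a seed scaffold")
        cid = f"{spec.id_prefix}_DEC_{j:03d}"
        records.append(
            CompoundRecord(
                source="synthetic", source_id=cid, name=cid, raw_structure=smiles
            )
        )
        truth[cid] = "decoy"
    return records, truth


# ---------------------------------------------------------------------------
# Bioactivity generation
# ---------------------------------------------------------------------------


def generate_bioactivity_table(
    library: list[CompoundRecord],
    truth: dict[str, str],
    active_families: set[str] | None = None,
    px_active: tuple[float, float] = (9.5, 0.1),
    px_inactive: tuple[float, float] = (5.0, 0.5),
    replicates: int = 3,
    rng_seed: int = 2021,
    uniprot_id: str = "P99999",
) -> list[BioactivityRecord]:
    """Measurements for every library compound.

    Members of active families draw pX from the active normal
    distribution, everything else from the inactive one; ``replicates``
    measurements per compound exercise median aggregation.  Values are
    reported as IC50 in nM (value = 10**(9 - pX)) from rotating sources.
    """
    if active_families is None:
        active_families = {t for t in truth.values() if t != "decoy"}
    rng = np.random.default_rng(rng_seed)
    sources = ("chembl", "pubchem", "iuphar")
    records: list[BioactivityRecord] = []
    for record in library:
        family = truth.get(record.source_id, "decoy")
        mean, sd = px_active if family in active_families else px_inactive
        for r in range(replicates):
            px = float(rng.normal(mean, sd))
            records.append(
                BioactivityRecord(
                    uniprot_id=uniprot_id,
                    endpoint="IC50",
                    value=10.0 ** (9.0 - px),
                    unit="nM",
                    relation="=",
                    source=sources[r % len(sources)],
                    molecule_id=record.source_id,
                    molecule_name=record.name,
                    smiles=record.raw_structure,
                    document_ref=f"DOC{r}",
                )
            )
    return records


# ---------------------------------------------------------------------------
# API payload fixtures
# ---------------------------------------------------------------------------


def _write(directory: Path, url: str, payload: bytes | str) -> None:
    if isinstance(payload, str):
        payload = payload.encode()
    (directory / fixture_filename(url)).write_bytes(payload)


def _uniprot_entry_xml(accession: str, pdb_ids: list[str]) -> bytes:
    ns = retrieval.UNIPROT_NS
    root = etree.Element(f"{{{ns}}}uniprot", nsmap={None: ns})
    entry = etree.SubElement(root, f"{{{ns}}}entry")
    etree.SubElement(entry, f"{{{ns}}}accession").text = accession
    for pdb_id in pdb_ids:
        etree.SubElement(entry, f"{{{ns}}}dbReference", type="PDB", id=pdb_id)
    etree.SubElement(entry, f"{{{ns}}}dbReference", type="Pfam", id="PF00001")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _activity_page_xml(
    rows: list[dict], total_count: int, limit: int, offset: int
) -> bytes:
    root = etree.Element("response")
    activities = etree.SubElement(root, "activities")
    for row in rows:
        node = etree.SubElement(activities, "activity")
        for tag, value in row.items():
            etree.SubElement(node, tag).text = str(value)
    meta = etree.SubElement(root, "page_meta")
    etree.SubElement(meta, "limit").text = str(limit)
    etree.SubElement(meta, "offset").text = str(offset)
    etree.SubElement(meta, "total_count").text = str(total_count)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _pdb_text(pdb_id: str, resolution: float) -> str:
    return "\n".join(
        [
            f"HEADER    SYNTHETIC PROTEIN                       01-JAN-20   {pdb_id.upper()}",
            f"TITLE     SYNTHETIC STRUCTURE {pdb_id.upper()} FOR PARSER TESTS",
            "EXPDTA    X-RAY DIFFRACTION",
            f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.",
            "REMARK   3   R VALUE            (WORKING SET) : 0.180",
            "CRYST1   50.000   60.000   70.000  90.00  90.00  90.00 P 21 21 21    4",
            "END",
        ]
    ) + "\n"


@dataclass
class FixtureManifest:
    """What generate_api_fixtures wrote, for driving a pipeline run."""

    directory: Path
    disease_id: str
    size: int
    min_score: float
    targets: list[dict] = field(default_factory=list)


def generate_api_fixtures(
    out_dir: str | Path,
    n_targets: int = 2,
    records_per_target: int = 2410,
    page_size: int = 1000,
    rng_seed: int = 2022,
    disease_id: str = "SYN_0001",
    size: int = 10_000,
    min_score: float = 0.99,
) -> FixtureManifest:
    """Write a complete canned-payload directory for an offline run.

    Per target: an association entry, the UniProt<->cross-reference
    mapping rows, a UniProt entry XML with PDB cross-references, a
    best-structures payload, RCSB entry/chemcomp payloads for the bound
    ligands, PDB-format header text, and ceil(records/page_size) activity
    XML pages whose ``total_count`` equals ``records_per_target`` on every
    page (the last page ragged).  Plus one PubChem chain file and IUPHAR
    interaction payloads.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)

    # molecule pool: analogs of the default seeds, so downstream scaffold
    # mining on these fixtures finds real families
    pool_spec = ChemotypeLibrarySpec(
        analogs_per_family=6, decoys=10, rng_seed=int(rng.integers(2**31)),
        id_prefix="POOL",
    )
    pool, _ = generate_chemotype_library(pool_spec)

    targets = []
    association_data = []
    mapping_lines = ["Entry\tCross-reference (OpenTargets)\tStatus"]
    chembl_lines = ["uniprot_id\ttarget_chembl_id"]
    iuphar_lines = ["uniprot_id\tiuphar_target_id"]
    pubchem = PubChemFixtures()

    for i in range(n_targets):
        accession = f"P{10001 + i}"
        ensembl = f"ENSG{i:011d}"
        symbol = f"SYNG{i + 1}"
        chembl_id = "CHEMBL5118" if i == 0 else f"CHEMBL{5000 + i}"
        iuphar_id = 2421 + i
        pdb_ids = [f"{1 + i}SA{j}" for j in range(2)]
        targets.append(
            {
                "uniprot_id": accession, "ensembl_id": ensembl, "symbol": symbol,
                "chembl_id": chembl_id, "iuphar_id": iuphar_id, "pdb_ids": pdb_ids,
            }
        )
        association_data.append(
            {
                "target": {
                    "id": ensembl,
                    "gene_info": {"name": f"synthetic gene {i + 1}", "symbol": symbol},
                },
                "association_score": {"overall": round(0.99 + 0.01 * (i == 0), 2)},
            }
        )
        mapping_lines.append(f"{accession}\t{ensembl};\treviewed")
        chembl_lines.append(f"{accession}\t{chembl_id}")
        iuphar_lines.append(f"{accession}\t{iuphar_id}")

        # UniProt entry XML and best-structures JSON
        _write(
            out_dir,
            retrieval.build_uniprot_entry_request(accession).url,
            _uniprot_entry_xml(accession, pdb_ids),
        )
        best = {
            accession: [
                {"pdb_id": p.lower(), "resolution": round(1.5 + 0.1 * j, 2)}
                for j, p in enumerate(pdb_ids)
            ]
        }
        _write(
            out_dir,
            retrieval.build_best_structures_request(accession).url,
            json.dumps(best, indent=1),
        )

        # RCSB entry + chemcomp + PDB text per structure
        for j, pdb_id in enumerate(pdb_ids):
            comp_code = f"SY{i}{j}"
            ligand = pool[(i * len(pdb_ids) + j) % len(pool)]
            entry_payload = {
                "rcsb_entry_info": {
                    "nonpolymer_bound_components": [comp_code, "GOL"],
                }
            }
            _write(
                out_dir,
                retrieval.build_rcsb_entry_request(pdb_id).url,
                json.dumps(entry_payload, indent=1),
            )
            chemcomp_payload = {
                "rcsb_chem_comp_descriptor": {
                    "smiles": ligand.raw_structure.split(".")[0]
                }
            }
            _write(
                out_dir,
                retrieval.build_chemcomp_request(comp_code).url,
                json.dumps(chemcomp_payload, indent=1),
            )
            _write(
                out_dir,
                retrieval.build_pdb_file_request(pdb_id).url,
                _pdb_text(pdb_id, 1.5 + 0.25 * j),
            )
            # the blocklisted co-crystallization agent still needs a payload
            _write(
                out_dir,
                retrieval.build_chemcomp_request("GOL").url,
                json.dumps(
                    {"rcsb_chem_comp_descriptor": {"smiles": "OCC(O)CO"}}, indent=1
                ),
            )

        # paginated activity XML
        plan = retrieval.plan_pagination(records_per_target, page_size)
        row_index = 0
        for offset in plan.offsets or (0,):
            n_rows = min(page_size, records_per_target - offset)
            rows = []
            for _ in range(max(n_rows, 0)):
                compound = pool[row_index % len(pool)]
                px = float(rng.normal(9.5, 0.4))
                rows.append(
                    {
                        "activity_comment": "active",
                        "assay_description": f"synthetic binding assay {symbol}",
                        "molecule_chembl_id": f"CHEMBL{700000 + row_index % len(pool)}",
                        "molecule_pref_name": compound.source_id,
                        "standard_type": "IC50",
                        "standard_units": "nM",
                        "standard_value": f"{10 ** (9 - px):.4g}",
                        "standard_relation": "=",
                        "parent_molecule_chembl_id": f"CHEMBL{700000 + row_index % len(pool)}",
                        "document_chembl_id": f"CHEMBL{800000 + row_index % 7}",
                        "canonical_smiles": compound.raw_structure,
                        "target_chembl_id": chembl_id,
                    }
                )
                row_index += 1
            _write(
                out_dir,
                retrieval.build_activity_request(chembl_id, page_size, offset).url,
                _activity_page_xml(rows, records_per_target, page_size, offset),
            )

        # IUPHAR payloads (pX-scale affinities, one substrate + interactions)
        interactions = [
            {
                "ligandId": 9000 + i * 10 + k,
                "ligandName": pool[k].source_id,
                "affinity": round(float(rng.normal(9.4, 0.3)), 2),
                "affinityType": "pKi",
                "action": "Inhibition",
                "smiles": pool[k].raw_structure,
                "refs": [{"pmid": 30000000 + k}],
            }
            for k in range(2)
        ]
        substrates, interactions_req = retrieval.build_iuphar_requests(iuphar_id)
        _write(out_dir, substrates.url, json.dumps([], indent=1))
        _write(out_dir, interactions_req.url, json.dumps(interactions, indent=1))

        # PubChem chain: one AID, two CIDs, one ChEMBL-named compound
        aid = 1000 + i
        cids = [500000 + i * 10, 500001 + i * 10]
        pubchem.uniprot_to_aids[accession] = [aid]
        pubchem.aid_to_cids[aid] = cids
        for k, cid in enumerate(cids):
            compound = pool[(5 + k + i) % len(pool)]
            name = "CHEMBL99999" if k == 0 else compound.source_id
            pubchem.cid_info[cid] = {
                "name": name,
                "endpoint": "Ki",
                "value": round(10 ** (9 - float(rng.normal(9.5, 0.3))), 4),
                "unit": "nM",
                "relation": "=",
                "pmid": 20000000 + cid,
                "smiles": compound.raw_structure,
            }
        pubchem.chembl_names["CHEMBL99999"] = "synthetic reference inhibitor"

    association = {"data": association_data, "total": len(association_data)}
    _write(
        out_dir,
        retrieval.build_association_request(disease_id, size, min_score).url,
        json.dumps(association, indent=1),
    )
    (out_dir / "uniprot_mapping.tsv").write_text("\n".join(mapping_lines) + "\n")
    (out_dir / "chembl_targets.tsv").write_text("\n".join(chembl_lines) + "\n")
    (out_dir / "iuphar_targets.tsv").write_text("\n".join(iuphar_lines) + "\n")
    pubchem.to_json(out_dir / "pubchem.json")

    return FixtureManifest(
        directory=out_dir, disease_id=disease_id, size=size,
        min_score=min_score, targets=targets,
    )


# ---------------------------------------------------------------------------
# Library file output (the formats the screen stage reads)
# ---------------------------------------------------------------------------


def write_library_csv(records: list[CompoundRecord], path: str | Path) -> None:
    lines = ["compound_id,name,smiles"]
    for record in records:
        lines.append(f"{record.source_id},{record.name or ''},{record.raw_structure}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_library_sdf(records: list[CompoundRecord], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for record in records:
            mol = Chem.MolFromSmiles(record.raw_structure)
            if mol is None:
                continue
            mol.SetProp("_Name", record.source_id)
            if record.name:
                mol.SetProp("name", record.name)
            writer.write(mol)
    finally:
        writer.close()
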