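"""Chemical structure standardization and compound identity.

Every compound entering the pipeline — PDB-bound ligands, bioactivity
ligands, and screening-library molecules alike — passes the same six-step
curation before identities are compared:

1. stereochemistry removal (substructure logic downstream is 2D),
2. salt stripping, 3. listing of the stripped fragments,
4. charge neutralization (with a valence sanity check),
5. an organic element filter (H, C, N, O, F, Br, I, Cl, P, S only),
6. InChI / InChIKey / canonical SMILES generation.

Failures never drop a record silently: the record comes back with a
rejection reason and is written to a quarantine table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.inchi import MolToInchi, MolToInchiKey
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # rdkit is chatty about valence retries

#: Allowed atomic numbers: H, C, N, O, F, P, S, Cl, Br, I.
ELEMENT_WHITELIST = frozenset({1, 6, 7, 8, 9, 15, 16, 17, 35, 53})

# Fragments treated as salts/solvents when they arrive as extra pieces of a
# multi-fragment structure (canonical SMILES, computed below): halide and
# alkali/alkaline-earth counter-ions, sulfate/nitrate/phosphate, and common
# crystallization solvents.
_SALT_SMILES = [
    "Cl", "[Cl-]", "Br", "[Br-]", "I", "[I-]", "F", "[F-]",
    "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]", "[Zn+2]", "[NH4+]",
    "O=S(=O)(O)O", "O=S(=O)([O-])[O-]", "O=S(=O)([O-])O",
    "O=[N+]([O-])O", "O=[N+]([O-])[O-]",
    "O=P(O)(O)O", "O=P([O-])(O)O", "O=P([O-])([O-])O", "O=P([O-])([O-])[O-]",
    "O", "CO", "CCO", "CC(C)O", "CS(C)=O", "CC(C)=O", "O=CO", "CC(=O)O",
]

#: Chemical-component codes of co-crystallization agents retained as "bound
#: ligands" in PDB entries: buffers, cryoprotectants, reductants, lone ions,
#: and isonicotinamide.  Applied to PDB-derived ligand lists.
DEFAULT_COCRYSTAL_BLOCKLIST = frozenset({
    "HOH", "EDO", "GOL", "PEG", "PG4", "PGE", "MPD", "DMS", "BME", "MBO",
    "ACT", "ACY", "FMT", "SO4", "PO4", "NO3", "CIT", "TRS", "EPE", "MES",
    "IMD", "INM", "CL", "BR", "IOD", "NA", "K", "MG", "CA", "ZN", "NH4",
})


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol)


SALT_FRAGMENTS = frozenset(_canonical(s) for s in _SALT_SMILES)


class StandardizationError(Exception):
    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


REJECTION_REASONS = ("unparseable", "element_filter", "normalization_failure")


@dataclass
class CompoundRecord:
    """One small molecule carried through curation.

    ``raw_structure`` is what arrived (SMILES or a V2000 molblock);
    ``std_structure`` is the standardized molecular graph.  A rejected
    record keeps its raw form plus the reason it was quarantined.
    """

    source: str  # pdb | chembl | pubchem | iuphar | library | synthetic
    source_id: str
    raw_structure: str
    name: str | None = None
    uniprot_id: str | None = None
    std_structure: Chem.Mol | None = None
    canonical_smiles: str | None = None
    salt_fragments: list[str] = field(default_factory=list)
    inchi: str | None = None
    inchikey: str | None = None
    permanently_charged: bool = False
    rejected: str | None = None


# ---------------------------------------------------------------------------
# Individual curation steps
# ---------------------------------------------------------------------------


def parse_structure(raw: str) -> Chem.Mol:
    """Parse a SMILES string or a V2000 molblock."""
    if raw is None:
        raise StandardizationError("unparseable", "no structure")
    raw = str(raw)
    if "M  END" in raw or "\n" in raw:
        mol = Chem.MolFromMolBlock(raw)
    else:
        mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise StandardizationError("unparseable", f"cannot parse {raw!r}")
    return mol


def remove_stereochemistry(mol: Chem.Mol) -> Chem.Mol:
    """Drop tetrahedral and double-bond stereo flags.

    Operates on the molecular graph (clear flags, re-canonicalize) rather
    than deleting marker characters from the SMILES text, which is not
    robust to directional bonds inside aromatic rings.  Constitution —
    atoms, bonds, bond orders — is unchanged.
    """
    out = Chem.Mol(mol)
    Chem.RemoveStereochemistry(out)
    return out


def strip_salts(
    mol: Chem.Mol, salt_set: frozenset[str] = SALT_FRAGMENTS
) -> tuple[Chem.Mol, list[str]]:
    """Split off salt/solvent fragments, keeping the organic parent.

    Single-fragment input is returned unchanged.  When several non-salt
    fragments remain, the one with the most heavy atoms wins (ties broken
    by molecular weight, then canonical SMILES order).  Every removed
    fragment is reported so it can be listed alongside the parent.
    """
    fragments = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(fragments) <= 1:
        return mol, []
    annotated = [(f, Chem.MolToSmiles(f)) for f in fragments]
    keepers = [(f, s) for f, s in annotated if s not in salt_set]
    if not keepers:
        raise StandardizationError(
            "normalization_failure", "all fragments are salts/solvents"
        )
    keepers.sort(
        key=lambda fs: (-fs[0].GetNumHeavyAtoms(), -Descriptors.MolWt(fs[0]), fs[1])
    )
    parent, parent_smiles = keepers[0]
    stripped = [s for f, s in annotated if f is not parent]
    return parent, stripped


_UNCHARGER = rdMolStandardize.Uncharger()


def neutralize_charges(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Zero out protonation-adjustable formal charges.

    Charges that cannot be removed by adding/removing hydrogens (e.g. a
    quaternary nitrogen) are left intact, and the second return value
    flags the molecule as permanently charged.  A valence error after
    adjustment is a normalization failure.
    """
    try:
        neutral = _UNCHARGER.uncharge(Chem.Mol(mol))
        Chem.SanitizeMol(neutral)
    except Exception as exc:  # rdkit raises several sanitization types
        raise StandardizationError("normalization_failure", str(exc)) from exc
    net_charge = sum(a.GetFormalCharge() for a in neutral.GetAtoms())
    return neutral, net_charge != 0


def passes_element_filter(
    mol: Chem.Mol, whitelist: frozenset[int] = ELEMENT_WHITELIST
) -> bool:
    """True iff every atom's element is on the organic whitelist."""
    return all(a.GetAtomicNum() in whitelist for a in mol.GetAtoms())


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def standardize_mol(mol: Chem.Mol) -> tuple[Chem.Mol, list[str], bool]:
    """Steps 1-5 on an already parsed molecule.

    Returns (standardized mol, stripped fragments, permanently-charged
    flag); raises :class:`StandardizationError` with the rejection reason
    on failure.
    """
    mol = remove_stereochemistry(mol)
    mol, stripped = strip_salts(mol)
    mol, charged = neutralize_charges(mol)
    if not passes_element_filter(mol):
        offending = sorted(
            {a.GetSymbol() for a in mol.GetAtoms() if a.GetAtomicNum() not in ELEMENT_WHITELIST}
        )
        raise StandardizationError("element_filter", f"disallowed elements: {offending}")
    # one fixed aromaticity perception for every downstream comparison
    smiles = Chem.MolToSmiles(mol)
    out = Chem.MolFromSmiles(smiles)
    if out is None:
        raise StandardizationError("normalization_failure", f"re-parse failed: {smiles}")
    return out, stripped, charged


def standardize_compound(record: CompoundRecord) -> CompoundRecord:
    """Run the full six-step curation on one record.

    On success the standardized graph, canonical SMILES, InChI and
    InChIKey are populated; on failure the record is returned with its
    rejection reason set — never dropped.  The operation is idempotent:
    standardizing an already standardized record reproduces it.
    """
    out = replace(record, salt_fragments=list(record.salt_fragments))
    try:
        mol = parse_structure(record.raw_structure)
        mol, stripped, charged = standardize_mol(mol)
    except StandardizationError as exc:
        out.rejected = exc.reason
        logger.debug("compound %s rejected (%s): %s", record.source_id, exc.reason, exc)
        return out
    out.std_structure = mol
    out.salt_fragments = stripped
    out.permanently_charged = charged
    out.canonical_smiles = Chem.MolToSmiles(mol)
    out.inchi = MolToInchi(mol)
    out.inchikey = MolToInchiKey(mol)
    out.rejected = None
    if not out.inchikey:
        out.rejected = "normalization_failure"
    return out


def standardize_all(
    records: Iterable[CompoundRecord],
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Standardize a batch; returns (accepted, quarantined)."""
    accepted, quarantined = [], []
    for record in records:
        out = standardize_compound(record)
        (quarantined if out.rejected else accepted).append(out)
    return accepted, quarantined


# ---------------------------------------------------------------------------
# Readers and writers
# ---------------------------------------------------------------------------


def read_sdf(path: str | Path, source: str = "library") -> list[CompoundRecord]:
    """Read a V2000 multi-record SDF into raw compound records.

    The molecule title is used as the id; a ``name`` property tag, when
    present, supplies the human-readable name.  Unparseable entries become
    records that will be quarantined by standardization.
    """
    records: list[CompoundRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            records.append(
                CompoundRecord(source=source, source_id=f"{Path(path).stem}_{i}",
                               raw_structure="", name=None)
            )
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"{Path(path).stem}_{i}"
        name = mol.GetProp("name") if mol.HasProp("name") else None
        records.append(
            CompoundRecord(
                source=source,
                source_id=mol_id or f"{Path(path).stem}_{i}",
                name=name,
                raw_structure=Chem.MolToMolBlock(mol, kekulize=False),
            )
        )
    return records


def read_smiles_table(
    path: str | Path,
    smiles_column: str = "smiles",
    id_column: str = "compound_id",
    name_column: str | None = "name",
    sep: str | None = None,
    source: str = "library",
) -> list[CompoundRecord]:
    """Read a SMILES CSV/TSV (delimiter sniffed from the extension unless
    given) into raw compound records."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".smi", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    if smiles_column not in frame.columns:
        raise ValueError(f"{path}: no {smiles_column!r} column")
    records = []
    for i, row in enumerate(frame.to_dict("records")):
        records.append(
            CompoundRecord(
                source=source,
                source_id=str(row.get(id_column, i)),
                name=str(row[name_column]) if name_column in frame.columns and pd.notna(row.get(name_column)) else None,
                raw_structure=str(row[smiles_column]),
            )
        )
    return records


def write_sdf(records: Sequence[CompoundRecord], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for record in records:
            if record.std_structure is None:
                continue
            mol = Chem.Mol(record.std_structure)
            mol.SetProp("_Name", record.source_id)
            if record.name:
                mol.SetProp("name", record.name)
            if record.inchikey:
                mol.SetProp("inchikey", record.inchikey)
            writer.write(mol)
    finally:
        writer.close()


IDENTITY_COLUMNS = [
    "source", "source_id", "name", "uniprot_id", "canonical_smiles",
    "inchi", "inchikey", "salt_fragments", "permanently_charged", "rejected",
]


def identity_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    rows = [
        {
            "source": r.source,
            "source_id": r.source_id,
            "name": r.name,
            "uniprot_id": r.uniprot_id,
            "canonical_smiles": r.canonical_smiles,
            "inchi": r.inchi,
            "inchikey": r.inchikey,
            "salt_fragments": ";".join(r.salt_fragments),
            "permanently_charged": r.permanently_charged,
            "rejected": r.rejected,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=IDENTITY_COLUMNS)


def write_identity_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    identity_frame(records).to_csv(path, sep="\t", index=False)
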