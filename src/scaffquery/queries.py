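"""SMARTS structural-query generation from scaffold clusters.

Each scaffold cluster of a target is collapsed into one substructure
query: the scaffold itself for a singleton cluster, otherwise the maximum
common substructure of all members.  Queries are rendered in the
element-number / explicit-bond SMARTS dialect ([#6], [#7], ':' aromatic
bonds, ring-closure digits) and are guaranteed — by an explicit
verification pass — to match every member scaffold of their cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .scaffolds import ScaffoldCluster, find_mcs

logger = logging.getLogger(__name__)

#: Queries smaller than this many heavy atoms are vacuous and suppressed.
DEFAULT_MIN_QUERY_SIZE = 3


class QueryError(Exception):
    pass


@dataclass
class StructuralQuery:
    """One SMARTS pattern generated from one scaffold cluster."""

    uniprot_id: str | None
    cluster_id: int
    smarts: str
    heavy_atoms: int
    n_members: int
    approximate: bool = False

    @property
    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise QueryError(f"invalid SMARTS {self.smarts!r}")
        return patt


@dataclass(frozen=True)
class ReferenceQuery:
    """One published reference pattern with its cluster annotation."""

    smarts: str
    cluster: int
    cluster_name: str
    hits: int
    targets: tuple[str, ...]


def render_scaffold_smarts(mol: Chem.Mol) -> str:
    """Render a molecule as an element-number/explicit-bond SMARTS.

    Bond aromaticity is written as perceived (':' only for aromatic
    bonds); no hybrid ",:"-style bond expressions are emitted.
    """
    return Chem.MolToSmarts(mol)


def cluster_mcs_query(
    cluster: ScaffoldCluster,
    min_query_size: int = DEFAULT_MIN_QUERY_SIZE,
    timeout: int = 5,
) -> StructuralQuery | None:
    """Collapse one cluster into a query, or ``None`` when the common
    substructure is below ``min_query_size`` heavy atoms.

    The emitted pattern is verified to match every member scaffold; a
    multi-molecule MCS truncated by the timeout is flagged approximate.
    """
    if not cluster.members:
        raise QueryError("empty cluster")
    members = sorted(cluster.members, key=lambda s: s.smiles)
    mols = [m.mol for m in members]
    approximate = False
    if len(mols) == 1:
        smarts = render_scaffold_smarts(mols[0])
        heavy = mols[0].GetNumHeavyAtoms()
    else:
        result = find_mcs(mols, timeout=timeout)
        if result.numAtoms < 1 or not result.smartsString:
            return None
        smarts = result.smartsString
        heavy = result.numAtoms
        approximate = bool(result.canceled)
    if heavy < min_query_size:
        return None
    pattern = Chem.MolFromSmarts(smarts)
    if pattern is None:
        raise QueryError(f"generated SMARTS does not parse: {smarts!r}")
    for mol, member in zip(mols, members):
        if not mol.HasSubstructMatch(pattern):
            raise QueryError(
                f"query {smarts!r} fails to match member scaffold {member.smiles!r}"
            )
    return StructuralQuery(
        uniprot_id=cluster.uniprot_id,
        cluster_id=cluster.cluster_id,
        smarts=smarts,
        heavy_atoms=heavy,
        n_members=len(members),
        approximate=approximate,
    )


def generate_queries(
    clusters: Iterable[ScaffoldCluster],
    min_query_size: int = DEFAULT_MIN_QUERY_SIZE,
    timeout: int = 5,
) -> list[StructuralQuery]:
    """At most one query per cluster, deduplicated by pattern string
    within each target (member counts summed on collision)."""
    by_key: dict[tuple[str | None, str], StructuralQuery] = {}
    for cluster in clusters:
        query = cluster_mcs_query(cluster, min_query_size=min_query_size, timeout=timeout)
        if query is None:
            continue
        key = (query.uniprot_id, query.smarts)
        existing = by_key.get(key)
        if existing is None:
            by_key[key] = query
        else:
            existing.n_members += query.n_members
            existing.approximate = existing.approximate or query.approximate
    return [by_key[k] for k in sorted(by_key, key=lambda k: (str(k[0]), k[1]))]


# ---------------------------------------------------------------------------
# Exchange format (consumed by the screen stage) and the packaged
# reference queries
# ---------------------------------------------------------------------------

QUERY_COLUMNS = ["smarts", "uniprot_id", "cluster_id", "heavy_atoms", "n_members", "approximate"]


def queries_to_frame(queries: Iterable[StructuralQuery]) -> pd.DataFrame:
    rows = [
        {
            "smarts": q.smarts,
            "uniprot_id": q.uniprot_id,
            "cluster_id": q.cluster_id,
            "heavy_atoms": q.heavy_atoms,
            "n_members": q.n_members,
            "approximate": q.approximate,
        }
        for q in queries
    ]
    return pd.DataFrame(rows, columns=QUERY_COLUMNS)


def write_queries(queries: Iterable[StructuralQuery], path: str | Path) -> None:
    """One query per line: the SMARTS first, tab-separated metadata after."""
    queries_to_frame(queries).to_csv(path, sep="\t", index=False)


def read_queries(path: str | Path) -> list[StructuralQuery]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.to_dict("records"):
        out.append(
            StructuralQuery(
                uniprot_id=None if pd.isna(row.get("uniprot_id")) else str(row["uniprot_id"]),
                cluster_id=int(row.get("cluster_id", 0)),
                smarts=str(row["smarts"]),
                heavy_atoms=int(row.get("heavy_atoms", 0)),
                n_members=int(row.get("n_members", 1)),
                approximate=bool(row.get("approximate", False)),
            )
        )
    return out


def load_reference_queries() -> list[ReferenceQuery]:
    """The 18 published reference MCS patterns shipped with the package,
    annotated with their five named clusters and per-pattern hit counts."""
    text = (
        resources.files("scaffquery").joinpath("data/table2.smarts").read_text()
    )
    out: list[ReferenceQuery] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smarts, cluster, cluster_name, hits, targets = line.split("\t")
        out.append(
            ReferenceQuery(
                smarts=smarts,
                cluster=int(cluster),
                cluster_name=cluster_name,
                hits=int(hits),
                targets=tuple(targets.split(";")),
            )
        )
    return out
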