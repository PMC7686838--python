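"""Bemis-Murcko scaffolds, MCS distances, and hierarchical clustering.

The Bemis-Murcko scaffold of a molecule is what remains after removing all
side chains: the ring systems plus the linkers connecting them.  Per
target, the scaffolds of the active ligands are compared by the size of
their Maximum Common Substructure (MCS), turned into a distance matrix,
and grouped by agglomerative hierarchical clustering cut at a distance
threshold (0.5 by default).  Scaffolds consisting of a single ring are
considered too generic to carry query value and are filtered out first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_THRESHOLD = 0.5
DEFAULT_LINKAGE = "average"
DEFAULT_MCS_TIMEOUT = 5  # seconds per pair
MIN_RINGS_NON_GENERIC = 2  # "too generic" = fewer rings than this


class ScaffoldError(Exception):
    pass


@dataclass
class Scaffold:
    """One ring-plus-linker framework with the compounds that produced it."""

    smiles: str
    heavy_atoms: int
    ring_count: int
    uniprot_id: str | None = None
    parent_keys: list[str] = field(default_factory=list)

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


class MCSResult(NamedTuple):
    size: int  # heavy atoms of the maximum common connected substructure
    smarts: str | None
    approximate: bool  # True when the per-pair timeout truncated the search


@dataclass
class DistanceMatrix:
    labels: list[str]  # canonical scaffold SMILES, sorted
    entries: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.entries.shape != (n, n):
            raise ScaffoldError("distance matrix shape does not match labels")
        if not np.allclose(self.entries, self.entries.T):
            raise ScaffoldError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.entries), 0.0):
            raise ScaffoldError("distance matrix must have a zero diagonal")
        if (self.entries < -1e-9).any() or (self.entries > 1 + 1e-9).any():
            raise ScaffoldError("distances must lie in [0, 1]")


@dataclass
class ScaffoldCluster:
    uniprot_id: str | None
    cluster_id: int
    members: list[Scaffold]
    threshold_used: float


# ---------------------------------------------------------------------------
# Scaffold extraction
# ---------------------------------------------------------------------------


def murcko_scaffold(
    structure: Chem.Mol | str,
    uniprot_id: str | None = None,
    parent_key: str | None = None,
) -> Scaffold | None:
    """Extract the Bemis-Murcko framework; ``None`` for ring-free input."""
    mol = Chem.MolFromSmiles(structure) if isinstance(structure, str) else structure
    if mol is None:
        raise ScaffoldError(f"unparseable structure {structure!r}")
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumHeavyAtoms() == 0:
        return None
    smiles = Chem.MolToSmiles(core)
    core = Chem.MolFromSmiles(smiles)  # re-perceive aromaticity canonically
    return Scaffold(
        smiles=smiles,
        heavy_atoms=core.GetNumHeavyAtoms(),
        ring_count=len(Chem.GetSSSR(core)),
        uniprot_id=uniprot_id,
        parent_keys=[parent_key] if parent_key else [],
    )


def scaffolds_for_target(
    compounds: Iterable[tuple[str, str]], uniprot_id: str | None = None
) -> list[Scaffold]:
    """Unique scaffolds for one target from (inchikey, smiles) pairs,
    sorted by canonical SMILES for deterministic downstream ordering."""
    by_smiles: dict[str, Scaffold] = {}
    for inchikey, smiles in compounds:
        if not smiles:
            continue
        scaffold = murcko_scaffold(smiles, uniprot_id=uniprot_id, parent_key=inchikey)
        if scaffold is None:
            continue
        existing = by_smiles.get(scaffold.smiles)
        if existing is None:
            by_smiles[scaffold.smiles] = scaffold
        elif inchikey and inchikey not in existing.parent_keys:
            existing.parent_keys.append(inchikey)
    return [by_smiles[s] for s in sorted(by_smiles)]


def is_too_generic(scaffold: Scaffold, min_rings: int = MIN_RINGS_NON_GENERIC) -> bool:
    """True iff the framework has too few rings to discriminate — by
    default exactly one ring (a lone aromatic ring being the canonical
    example)."""
    return scaffold.ring_count < min_rings


def filter_generic(
    scaffolds: Iterable[Scaffold], min_rings: int = MIN_RINGS_NON_GENERIC
) -> list[Scaffold]:
    return [s for s in scaffolds if not is_too_generic(s, min_rings)]


# ---------------------------------------------------------------------------
# MCS and distances
# ---------------------------------------------------------------------------

def _mcs_params() -> dict:
    # Matching semantics: elements must match, aromatic bonds match only
    # aromatic bonds, the common substructure is connected, rings need not
    # be complete.
    return dict(
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        ringMatchesRingOnly=False,
        completeRingsOnly=False,
        matchValences=False,
    )


def find_mcs(mols: Sequence[Chem.Mol], timeout: int = DEFAULT_MCS_TIMEOUT):
    """RDKit MCS over two or more molecules under the fixed matching
    semantics of this package."""
    return rdFMCS.FindMCS(list(mols), timeout=timeout, **_mcs_params())


def _common_single_atom(a: Chem.Mol, b: Chem.Mol) -> MCSResult:
    elements_a = {atom.GetAtomicNum() for atom in a.GetAtoms()}
    elements_b = {atom.GetAtomicNum() for atom in b.GetAtoms()}
    shared = sorted(elements_a & elements_b)
    if not shared:
        return MCSResult(0, None, False)
    return MCSResult(1, f"[#{shared[0]}]", False)


def mcs_common_atoms(
    a: Scaffold | Chem.Mol | str,
    b: Scaffold | Chem.Mol | str,
    timeout: int = DEFAULT_MCS_TIMEOUT,
) -> MCSResult:
    """Heavy-atom count and SMARTS of the maximum common connected
    substructure of two scaffolds.

    A timeout yields the best pattern found so far, flagged approximate.
    Pairs sharing no bond but at least one element fall back to the
    single-atom common substructure.
    """
    mol_a = _as_mol(a)
    mol_b = _as_mol(b)
    result = find_mcs([mol_a, mol_b], timeout=timeout)
    if result.numAtoms < 1:
        return _common_single_atom(mol_a, mol_b)
    return MCSResult(result.numAtoms, result.smartsString, bool(result.canceled))


def _as_mol(x: Scaffold | Chem.Mol | str) -> Chem.Mol:
    if isinstance(x, Scaffold):
        return x.mol
    if isinstance(x, str):
        mol = Chem.MolFromSmiles(x)
        if mol is None:
            raise ScaffoldError(f"unparseable SMILES {x!r}")
        return mol
    return x


def scaffold_distance(
    a: Scaffold | Chem.Mol | str,
    b: Scaffold | Chem.Mol | str,
    metric: Literal["tanimoto", "max"] = "tanimoto",
    timeout: int = DEFAULT_MCS_TIMEOUT,
) -> float:
    """MCS-based distance in [0, 1].

    ``tanimoto`` (default): d = 1 - m / (|a| + |b| - m) with m the MCS
    heavy-atom count — 0 for identical scaffolds, 1 for scaffolds sharing
    no atom.  ``max``: d = 1 - m / max(|a|, |b|).
    """
    mol_a, mol_b = _as_mol(a), _as_mol(b)
    m = mcs_common_atoms(mol_a, mol_b, timeout=timeout).size
    na, nb = mol_a.GetNumHeavyAtoms(), mol_b.GetNumHeavyAtoms()
    if metric == "tanimoto":
        denom = na + nb - m
    elif metric == "max":
        denom = max(na, nb)
    else:
        raise ScaffoldError(f"unknown metric {metric!r}")
    if denom == 0:
        return 0.0
    return 1.0 - m / denom


def distance_matrix(
    scaffolds: Sequence[Scaffold],
    metric: Literal["tanimoto", "max"] = "tanimoto",
    timeout: int = DEFAULT_MCS_TIMEOUT,
) -> DistanceMatrix:
    """Pairwise scaffold distances; rows/columns sorted by canonical
    SMILES so the matrix (and everything downstream) is independent of
    input order."""
    ordered = sorted(scaffolds, key=lambda s: s.smiles)
    mols = [s.mol for s in ordered]
    n = len(ordered)
    entries = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = scaffold_distance(mols[i], mols[j], metric=metric, timeout=timeout)
            entries[i, j] = entries[j, i] = d
    return DistanceMatrix(labels=[s.smiles for s in ordered], entries=entries)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_scaffolds(
    matrix: DistanceMatrix,
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    linkage: Literal["single", "complete", "average"] = DEFAULT_LINKAGE,
) -> list[int]:
    """Agglomerative clustering cut at ``threshold``; returns one cluster
    id per matrix label, ids numbered in order of first appearance."""
    if not 0 < threshold <= 1:
        raise ScaffoldError("threshold must lie in (0, 1]")
    n = len(matrix.labels)
    if n == 0:
        return []
    if n == 1:
        return [1]
    condensed = squareform(matrix.entries, checks=False)
    tree = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(tree, t=threshold, criterion="distance")
    remap: dict[int, int] = {}
    out = []
    for label in raw:
        if label not in remap:
            remap[label] = len(remap) + 1
        out.append(remap[label])
    return out


def cluster_target_scaffolds(
    scaffolds: Sequence[Scaffold],
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    linkage: Literal["single", "complete", "average"] = DEFAULT_LINKAGE,
    metric: Literal["tanimoto", "max"] = "tanimoto",
    timeout: int = DEFAULT_MCS_TIMEOUT,
) -> list[ScaffoldCluster]:
    """Cluster the scaffolds of one target; a single scaffold short-cuts
    to one singleton cluster with no matrix computation."""
    if not scaffolds:
        return []
    uniprot_ids = {s.uniprot_id for s in scaffolds}
    uniprot_id = next(iter(uniprot_ids)) if len(uniprot_ids) == 1 else None
    if len(scaffolds) == 1:
        return [
            ScaffoldCluster(
                uniprot_id=uniprot_id, cluster_id=1,
                members=list(scaffolds), threshold_used=threshold,
            )
        ]
    matrix = distance_matrix(scaffolds, metric=metric, timeout=timeout)
    by_smiles = {s.smiles: s for s in scaffolds}
    assignment = cluster_scaffolds(matrix, threshold=threshold, linkage=linkage)
    clusters: dict[int, ScaffoldCluster] = {}
    for label, cluster_id in zip(matrix.labels, assignment):
        cluster = clusters.setdefault(
            cluster_id,
            ScaffoldCluster(
                uniprot_id=uniprot_id, cluster_id=cluster_id,
                members=[], threshold_used=threshold,
            ),
        )
        cluster.members.append(by_smiles[label])
    return [clusters[k] for k in sorted(clusters)]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def clusters_to_frame(clusters: Iterable[ScaffoldCluster]) -> pd.DataFrame:
    rows = [
        {
            "uniprot_id": c.uniprot_id,
            "scaffold_smiles": s.smiles,
            "heavy_atoms": s.heavy_atoms,
            "cluster_id": c.cluster_id,
            "n_parents": len(s.parent_keys),
        }
        for c in clusters
        for s in c.members
    ]
    return pd.DataFrame(
        rows,
        columns=["uniprot_id", "scaffold_smiles", "heavy_atoms", "cluster_id", "n_parents"],
    )


def write_clusters(clusters: Iterable[ScaffoldCluster], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(matrix.entries, index=matrix.labels, columns=matrix.labels)
    frame.to_csv(path, sep="\t")
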