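"""Substructure screening of drug libraries with generated SMARTS queries.

Standardized library compounds are filtered against each structural query;
every (compound, query) match becomes a hit row carrying the matched atom
indices, so hits can be depicted with the substructure highlighted.
Cross-library overlap and rediscovery accounting (hits that were already
in the active input set) summarize a screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from .chemstruct import CompoundRecord
from .queries import StructuralQuery

logger = logging.getLogger(__name__)


class ScreenError(Exception):
    pass


class InvalidQueryError(ScreenError):
    """Raised before any screening happens when a query does not parse."""


@dataclass
class ScreenHit:
    """One library compound matched by one query."""

    library: str
    compound_id: str
    compound_name: str | None
    inchikey: str | None
    uniprot_id: str | None
    cluster_id: int
    smarts: str
    matched_atoms: tuple[int, ...]
    rediscovered: bool = False
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def query_ref(self) -> tuple[str | None, int, str]:
        return (self.uniprot_id, self.cluster_id, self.smarts)


def substructure_screen(
    library: Sequence[CompoundRecord],
    queries: Sequence[StructuralQuery],
    library_name: str = "library",
) -> list[ScreenHit]:
    """Match every query against every standardized library compound.

    A compound matched by k queries yields k hit rows.  Matching uses the
    same aromaticity perception as standardization (compounds are matched
    on their standardized graphs).  Any query that fails to parse aborts
    the whole run, naming the offending pattern.
    """
    patterns = []
    for query in queries:
        patt = Chem.MolFromSmarts(query.smarts)
        if patt is None:
            raise InvalidQueryError(f"query does not parse: {query.smarts!r}")
        patterns.append((query, patt))
    hits: list[ScreenHit] = []
    for record in library:
        mol = record.std_structure
        if mol is None or record.rejected:
            continue
        for query, patt in patterns:
            match = mol.GetSubstructMatch(patt)
            if not match:
                continue
            hits.append(
                ScreenHit(
                    library=library_name,
                    compound_id=record.source_id,
                    compound_name=record.name,
                    inchikey=record.inchikey,
                    uniprot_id=query.uniprot_id,
                    cluster_id=query.cluster_id,
                    smarts=query.smarts,
                    matched_atoms=tuple(match),
                    mol=mol,
                )
            )
    return hits


def cross_library_overlap(
    hits_by_library: Mapping[str, Sequence[ScreenHit]],
) -> list[tuple[str, tuple[str, ...], tuple[str, ...]]]:
    """Compounds (by InChIKey) hit in *every* screened library.

    Returns (inchikey, libraries, matching query SMARTS) tuples; the query
    list is the union across libraries.  With fewer than two libraries
    there is nothing to intersect.
    """
    if len(hits_by_library) < 2:
        logger.warning("cross-library overlap needs at least two libraries")
        return []
    keys_per_library = [
        {h.inchikey for h in hits if h.inchikey} for hits in hits_by_library.values()
    ]
    shared = set.intersection(*keys_per_library)
    out = []
    for key in sorted(shared):
        queries = sorted(
            {
                h.smarts
                for hits in hits_by_library.values()
                for h in hits
                if h.inchikey == key
            }
        )
        out.append((key, tuple(sorted(hits_by_library)), tuple(queries)))
    return out


def flag_rediscoveries(
    hits: Iterable[ScreenHit], active_keys: Iterable[str]
) -> tuple[list[ScreenHit], float | None]:
    """Mark hits whose compound was already in the active input set.

    The rediscovery fraction is rediscovered unique compounds over unique
    hit compounds; ``None`` (reported as n/a) when there are no hits.
    """
    active = set(active_keys)
    hits = list(hits)
    for hit in hits:
        hit.rediscovered = hit.inchikey in active if hit.inchikey else False
    unique = {h.inchikey for h in hits if h.inchikey}
    if not unique:
        return hits, None
    fraction = len(unique & active) / len(unique)
    return hits, fraction


def render_highlight(
    hit: ScreenHit, out_dir: str | Path | None = None, size: tuple[int, int] = (350, 300)
) -> str:
    """2D depiction of a hit with the matched atoms and bonds highlighted.

    Returns the SVG document; when ``out_dir`` is given the drawing is
    also written to ``<compound_id>__<uniprot>_c<cluster>.svg``.  Invalid
    atom indices raise before any file is produced.
    """
    if hit.mol is None:
        raise ScreenError(f"hit {hit.compound_id} carries no structure to draw")
    n_atoms = hit.mol.GetNumAtoms()
    if any(i < 0 or i >= n_atoms for i in hit.matched_atoms):
        raise ScreenError(
            f"matched atom indices {hit.matched_atoms} out of range for "
            f"{hit.compound_id} ({n_atoms} atoms)"
        )
    matched = set(hit.matched_atoms)
    bonds = [
        b.GetIdx()
        for b in hit.mol.GetBonds()
        if b.GetBeginAtomIdx() in matched and b.GetEndAtomIdx() in matched
    ]
    drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, hit.mol, highlightAtoms=list(hit.matched_atoms), highlightBonds=bonds
    )
    drawer.FinishDrawing()
    svg = drawer.GetDrawingText()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        name = f"{hit.compound_id}__{hit.uniprot_id or 'NA'}_c{hit.cluster_id}.svg"
        (out_dir / name).write_text(svg)
    return svg


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "library", "compound_id", "name", "inchikey",
    "uniprot_id", "cluster_id", "smarts", "rediscovered",
]


def hits_to_frame(hits: Iterable[ScreenHit]) -> pd.DataFrame:
    rows = [
        {
            "library": h.library,
            "compound_id": h.compound_id,
            "name": h.compound_name,
            "inchikey": h.inchikey,
            "uniprot_id": h.uniprot_id,
            "cluster_id": h.cluster_id,
            "smarts": h.smarts,
            "rediscovered": h.rediscovered,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits(hits: Iterable[ScreenHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_overlap(
    overlap: Sequence[tuple[str, tuple[str, ...], tuple[str, ...]]], path: str | Path
) -> None:
    frame = pd.DataFrame(
        [
            {"inchikey": key, "libraries": ";".join(libs), "queries": ";".join(qs)}
            for key, libs, qs in overlap
        ],
        columns=["inchikey", "libraries", "queries"],
    )
    frame.to_csv(path, sep="\t", index=False)


def hit_counts(hits: Sequence[ScreenHit]) -> dict[str, int]:
    """Both hit-count conventions: (compound, query) pair rows and unique
    compounds."""
    return {
        "pair_rows": len(hits),
        "unique_compounds": len({h.inchikey for h in hits if h.inchikey}),
    }
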