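"""Bioactivity transformation, labeling, and merging.

Measurements of heterogeneous endpoints (Ki, IC50, Km, EC50, ...) are put
on the common pX scale (negative base-10 log of the molar value, so
1 nM <-> pX 9), labeled active/inactive at a configurable cutoff, reduced
to one median label per (target, ligand) pair, and merged across sources
into a unique-actives-per-target table.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Supported concentration units and their value in molar.
UNIT_FACTORS: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # micro sign
    "nM": 1e-9,
    "pM": 1e-12,
}

#: pX cutoff for the high-potency case: active means < 1 nM, i.e. pX > 9.
DEFAULT_CUTOFF = 9.0
#: Cutoff used for transporter targets, whose characteristic activity range
#: is weaker: active means < 1 uM, i.e. pX > 6.
TRANSPORTER_CUTOFF = 6.0

RELATIONS = {"=", "<", ">", "<=", ">="}


class BioactivityError(Exception):
    pass


@dataclass
class BioactivityRecord:
    """One measurement linking a ligand to a target."""

    uniprot_id: str | None = None
    ligand_key: str | None = None  # InChIKey once standardized
    endpoint: str = ""
    value: float | None = None
    unit: str = ""
    relation: str = "="
    px: float | None = None
    label: int | None = None
    document_ref: str | None = None
    source: str = ""
    molecule_id: str | None = None
    molecule_name: str | None = None
    smiles: str | None = None
    parent_molecule_id: str | None = None
    target_chembl_id: str | None = None
    assay_description: str | None = None
    activity_comment: str | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class ActivityLabel:
    """Median binary label for one (target, ligand) pair."""

    uniprot_id: str | None
    ligand_key: str
    median_label: float
    active: bool
    cutoff_used: float
    n_measurements: int = 0
    sources: tuple[str, ...] = ()


def to_pscale(value: float, unit: str) -> float:
    """Negative log10 of a concentration expressed in molar.

    >>> to_pscale(1, "nM")
    9.0
    """
    if unit not in UNIT_FACTORS:
        raise BioactivityError(f"unsupported concentration unit {unit!r}")
    if value is None or value <= 0:
        raise BioactivityError(f"non-positive value {value!r}")
    return -math.log10(value * UNIT_FACTORS[unit])


def assign_label(px: float, cutoff: float = DEFAULT_CUTOFF) -> int:
    """1 iff pX strictly exceeds the cutoff, else 0.

    The comparison is strict: a compound at exactly the cutoff is inactive.
    """
    if px is None or not math.isfinite(px):
        raise BioactivityError(f"pX must be finite, got {px!r}")
    return 1 if px > cutoff else 0


def label_record(record: BioactivityRecord, cutoff: float = DEFAULT_CUTOFF) -> BioactivityRecord:
    """Compute pX and the binary label for one record, in place.

    Relation handling (bounds are on the concentration, so they invert on
    the pX scale):

    * ``=``: labeled directly from pX;
    * ``<`` / ``<=``: true pX exceeds the bound's pX, so the record is kept
      (label 1) only when the bound already forces activity;
    * ``>`` / ``>=``: symmetric, kept (label 0) only when inactivity is
      forced;
    * a bound that forces nothing leaves the record flagged and unlabeled.

    Records with missing value/unit, an unknown unit, or a non-positive
    value get a flag and no pX; they are excluded from aggregation.
    """
    if record.px is None:
        try:
            record.px = to_pscale(record.value, record.unit)
        except BioactivityError as exc:
            if "unlabelable" not in record.flags:
                record.flags.append(f"px_unset:{exc}")
            return record
    relation = record.relation or "="
    if relation not in RELATIONS:
        record.flags.append(f"unknown_relation:{relation}")
        return record
    bound_label = assign_label(record.px, cutoff)
    if relation == "=":
        record.label = bound_label
    elif relation in {"<", "<="}:
        # concentration below the bound => pX above the bound's pX
        forced_active = record.px > cutoff or (relation == "<" and record.px >= cutoff)
        if forced_active:
            record.label = 1
        else:
            record.flags.append("censored_uninformative")
    else:  # ">", ">="
        forced_inactive = record.px <= cutoff
        if forced_inactive:
            record.label = 0
        else:
            record.flags.append("censored_uninformative")
    return record


def label_records(
    records: Iterable[BioactivityRecord], cutoff: float = DEFAULT_CUTOFF
) -> list[BioactivityRecord]:
    return [label_record(r, cutoff) for r in records]


def aggregate_labels(
    records: Sequence[BioactivityRecord], cutoff: float = DEFAULT_CUTOFF
) -> ActivityLabel | None:
    """Median binary label over the labeled records of one (target,
    ligand_key) group; active iff the median is exactly 1 (an even split,
    median 0.5, is not active)."""
    labeled = [r for r in records if r.label is not None]
    if not labeled:
        return None
    keys = {r.ligand_key for r in labeled}
    targets = {r.uniprot_id for r in labeled}
    if len(keys) != 1 or len(targets) != 1:
        raise BioactivityError(
            f"aggregate_labels expects one (target, ligand) group, got {targets} x {keys}"
        )
    median = float(statistics.median(r.label for r in labeled))
    return ActivityLabel(
        uniprot_id=labeled[0].uniprot_id,
        ligand_key=labeled[0].ligand_key,
        median_label=median,
        active=median == 1.0,
        cutoff_used=cutoff,
        n_measurements=len(labeled),
        sources=tuple(sorted({r.source for r in labeled if r.source})),
    )


def aggregate_by_ligand(
    records: Iterable[BioactivityRecord], cutoff: float = DEFAULT_CUTOFF
) -> list[ActivityLabel]:
    """Group records by (target, ligand_key) and aggregate each group."""
    groups: dict[tuple, list[BioactivityRecord]] = {}
    for record in records:
        if record.ligand_key is None:
            continue
        groups.setdefault((record.uniprot_id, record.ligand_key), []).append(record)
    out = []
    for key in sorted(groups, key=lambda k: (str(k[0]), k[1])):
        label = aggregate_labels(groups[key], cutoff)
        if label is not None:
            out.append(label)
    return out


def merge_active_set(
    label_tables: Sequence[Sequence[ActivityLabel]],
    pdb_ligands: Sequence[tuple[str, str]] = (),
    structures: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Merge per-source label tables into one unique-actives-per-target
    table.

    Only active ligands (median label 1) are kept; the result is then
    concatenated with the PDB-derived ligands, which carry no bioactivity
    label and are included unconditionally.  ``pdb_ligands`` are
    (uniprot_id, inchikey) pairs; ``structures`` maps InChIKey to a
    canonical SMILES for downstream scaffold extraction.  One row per
    (uniprot_id, InChIKey); provenance lists every contributing source.
    Deterministic (sorted) regardless of input order.
    """
    rows: dict[tuple[str, str], set[str]] = {}
    for table in label_tables:
        for label in table:
            if not label.active:
                continue
            key = (str(label.uniprot_id), label.ligand_key)
            rows.setdefault(key, set()).update(label.sources or ("bioactivity",))
    for uniprot_id, inchikey in pdb_ligands:
        if not inchikey:
            logger.warning("PDB ligand for %s lacks an InChIKey; quarantined", uniprot_id)
            continue
        rows.setdefault((str(uniprot_id), inchikey), set()).add("pdb")
    structures = structures or {}
    data = [
        {
            "uniprot_id": uniprot,
            "inchikey": key,
            "smiles": structures.get(key),
            "provenance": ";".join(sorted(sources)),
        }
        for (uniprot, key), sources in sorted(rows.items())
    ]
    return pd.DataFrame(
        data, columns=["uniprot_id", "inchikey", "smiles", "provenance"]
    )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

ACTIVITY_COLUMNS = [
    "uniprot_id", "inchikey", "endpoint", "value", "unit", "relation",
    "px", "label", "source", "document_ref",
]


def records_to_frame(records: Iterable[BioactivityRecord]) -> pd.DataFrame:
    rows = [
        {
            "uniprot_id": r.uniprot_id,
            "inchikey": r.ligand_key,
            "endpoint": r.endpoint,
            "value": r.value,
            "unit": r.unit,
            "relation": r.relation,
            "px": r.px,
            "label": r.label,
            "source": r.source,
            "document_ref": r.document_ref,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ACTIVITY_COLUMNS)


def write_activity_table(records: Iterable[BioactivityRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_activity_table(path: str | Path) -> list[BioactivityRecord]:
    frame = pd.read_csv(path, sep="\t")
    records = []
    for row in frame.to_dict("records"):
        records.append(
            BioactivityRecord(
                uniprot_id=_opt(row.get("uniprot_id")),
                ligand_key=_opt(row.get("inchikey")),
                endpoint=_opt(row.get("endpoint")) or "",
                value=row.get("value") if pd.notna(row.get("value")) else None,
                unit=_opt(row.get("unit")) or "",
                relation=_opt(row.get("relation")) or "=",
                px=row.get("px") if pd.notna(row.get("px")) else None,
                label=int(row["label"]) if pd.notna(row.get("label")) else None,
                source=_opt(row.get("source")) or "",
                document_ref=_opt(row.get("document_ref")),
            )
        )
    return records


def _opt(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return value if not isinstance(value, str) or value else None
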