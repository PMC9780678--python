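"""Compound-library ingestion and the three-stage curation cascade.

A food-constituent export (FooDB-style) arrives as a CSV, SDF, or plain
SMILES file.  Each entry becomes a :class:`CompoundRecord`; entries whose
structure string does not parse are *kept* with ``parse_ok=False`` so the
per-stage accounting stays auditable — nothing is dropped silently.

The curation cascade mirrors the usual pre-screening of a natural-product
library:

1. :func:`filter_by_class` — delete whole ontology classes that are not
   drug-like candidates (glycerolipids such as triacylglycerols,
   diacylglycerols, phosphatidylethanolamines);
2. :func:`filter_inorganic` — delete water and inorganic salts, detected
   either by an explicit class tag or by the absence of any carbon atom;
3. :func:`filter_by_molecular_weight` — delete very small molecules
   (default MW < 100 Da), which tend to bind without specificity.

Every stage returns a :class:`FilterStageReport` so the counts can be
chained and checked (``n_out`` of one stage equals ``n_in`` of the next).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

#: Controlled vocabulary of compound-class tags.
CLASS_VOCAB = frozenset(
    {
        "triacylglycerol",
        "diacylglycerol",
        "phosphatidylethanolamine",
        "inorganic",
        "flavonoid",
        "anthocyanin",
        "other",
    }
)

#: Glycerolipid classes excluded by default in the first cascade stage.
DEFAULT_EXCLUDED_CLASSES = frozenset(
    {"triacylglycerol", "diacylglycerol", "phosphatidylethanolamine"}
)


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry.

    ``parse_ok`` records whether ``smiles`` parsed; failed records are
    excluded from descriptor-dependent stages but carried through reports.
    """

    compound_id: str
    name: str
    smiles: str
    compound_class: str = "other"
    source: str = ""
    parse_ok: bool = True


@dataclass
class FilterStageReport:
    """Per-stage audit record: who came in, who left, who was removed."""

    stage_name: str
    n_in: int
    n_out: int
    removed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - len(self.removed_ids):
            raise ValueError(
                f"inconsistent stage report {self.stage_name!r}: "
                f"n_out={self.n_out} != n_in={self.n_in} - {len(self.removed_ids)} removed"
            )

    def to_dict(self) -> dict:
        return {
            "stage_name": self.stage_name,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "removed_ids": list(self.removed_ids),
        }


def _check_unique_ids(records: Sequence[CompoundRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.compound_id in seen:
            raise DataError(f"duplicate compound_id {rec.compound_id!r} in library")
        seen.add(rec.compound_id)


def _smiles_parses(smiles: str) -> bool:
    return bool(smiles) and Chem.MolFromSmiles(smiles) is not None


def read_compound_table(path: str | Path, format: str | None = None) -> list[CompoundRecord]:
    """Read a compound library from ``path``.

    Parameters
    ----------
    path:
        Input file.  Format is inferred from the suffix when ``format`` is
        None (``.csv``, ``.sdf``, ``.smi``/``.smiles``).
    format:
        One of ``{"csv", "sdf", "smiles"}``.

    Returns one record per row / molecule block, in input order.
    Unparsable structures yield ``parse_ok=False`` records, never drops.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"library file not found: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {".csv": "csv", ".sdf": "sdf", ".smi": "smiles", ".smiles": "smiles"}.get(
            suffix
        )
        if format is None:
            raise ConfigurationError(f"cannot infer library format from suffix {suffix!r}")
    if format == "csv":
        records = _read_csv(path)
    elif format == "sdf":
        records = _read_sdf(path)
    elif format == "smiles":
        records = _read_smiles(path)
    else:
        raise ConfigurationError(f"unknown library format {format!r}")
    if not records:
        raise DataError(f"library file {path} contains no compounds")
    _check_unique_ids(records)
    return records


def _read_csv(path: Path) -> list[CompoundRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataError(f"library file {path} is empty")
        for col in ("compound_id", "name", "smiles"):
            if col not in reader.fieldnames:
                raise ConfigurationError(
                    f"library CSV {path} is missing required column {col!r}"
                )
        records = []
        for row in reader:
            smiles = (row["smiles"] or "").strip()
            records.append(
                CompoundRecord(
                    compound_id=row["compound_id"].strip(),
                    name=(row["name"] or "").strip(),
                    smiles=smiles,
                    compound_class=(row.get("compound_class") or "other").strip() or "other",
                    source=(row.get("source") or "").strip(),
                    parse_ok=_smiles_parses(smiles),
                )
            )
    return records


def _read_sdf(path: Path) -> list[CompoundRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records = []
    for i, mol in enumerate(supplier):
        if mol is None:
            records.append(
                CompoundRecord(
                    compound_id=f"M_{i + 1:04d}", name="", smiles="", parse_ok=False
                )
            )
            continue
        if mol.HasProp("compound_id"):
            cid = mol.GetProp("compound_id")
        elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            cid = mol.GetProp("_Name").strip()
        else:
            cid = f"M_{i + 1:04d}"
        name = mol.GetProp("name") if mol.HasProp("name") else cid
        records.append(
            CompoundRecord(
                compound_id=cid, name=name, smiles=Chem.MolToSmiles(mol), parse_ok=True
            )
        )
    return records


def _read_smiles(path: Path) -> list[CompoundRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"M_{i + 1:04d}"
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    name=cid,
                    smiles=smiles,
                    parse_ok=_smiles_parses(smiles),
                )
            )
    return records


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records to CSV in the same dialect :func:`read_compound_table` reads."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "name", "smiles", "compound_class", "source"])
        for rec in records:
            writer.writerow(
                [rec.compound_id, rec.name, rec.smiles, rec.compound_class, rec.source]
            )


def filter_by_class(
    records: Sequence[CompoundRecord], excluded_tags: Iterable[str]
) -> tuple[list[CompoundRecord], FilterStageReport]:
    """Remove records whose ``compound_class`` is in ``excluded_tags``.

    Unknown tags (outside :data:`CLASS_VOCAB`) are ignored with a warning.
    """
    excluded = set(excluded_tags)
    unknown = excluded - CLASS_VOCAB
    if unknown:
        logger.warning("ignoring unknown class tags in exclusion set: %s", sorted(unknown))
        excluded -= unknown
    kept, removed = [], []
    for rec in records:
        if rec.compound_class in excluded:
            removed.append(rec.compound_id)
        else:
            kept.append(rec)
    report = FilterStageReport("class_filter", len(records), len(kept), removed)
    logger.info("class_filter: %d -> %d (removed %d)", len(records), len(kept), len(removed))
    return kept, report


def filter_inorganic(
    records: Sequence[CompoundRecord],
) -> tuple[list[CompoundRecord], FilterStageReport]:
    """Remove water and inorganic entries.

    A record is removed when it is tagged ``inorganic`` or when its parsed
    structure contains no carbon atom.  Parse failures pass through
    untouched (they stay flagged and are handled downstream).
    """
    kept, removed = [], []
    for rec in records:
        drop = rec.compound_class == "inorganic"
        if not drop and rec.parse_ok:
            mol = Chem.MolFromSmiles(rec.smiles)
            if mol is not None:
                drop = not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())
        if drop:
            removed.append(rec.compound_id)
        else:
            kept.append(rec)
    report = FilterStageReport("inorganic_filter", len(records), len(kept), removed)
    logger.info(
        "inorganic_filter: %d -> %d (removed %d)", len(records), len(kept), len(removed)
    )
    return kept, report


def filter_by_molecular_weight(
    records: Sequence[CompoundRecord],
    descriptors: Mapping[str, "DescriptorVector"],  # noqa: F821 - forward ref
    min_mw: float = 100.0,
) -> tuple[list[CompoundRecord], FilterStageReport]:
    """Remove records with MW strictly below ``min_mw`` Da (MW == min_mw is kept).

    ``descriptors`` maps compound_id to its descriptor vector; a parsed
    record without an entry is an error.  Records with ``parse_ok=False``
    pass through untouched (descriptor-dependent stages skip them).
    """
    kept, removed = [], []
    for rec in records:
        if not rec.parse_ok:
            kept.append(rec)
            continue
        vec = descriptors.get(rec.compound_id)
        if vec is None:
            raise DataError(
                f"no descriptor entry for compound {rec.compound_id!r} in MW filter"
            )
        if vec.mw < min_mw:
            removed.append(rec.compound_id)
        else:
            kept.append(rec)
    report = FilterStageReport("molecular_weight_filter", len(records), len(kept), removed)
    logger.info(
        "molecular_weight_filter (min_mw=%g): %d -> %d (removed %d)",
        min_mw,
        len(records),
        len(kept),
        len(removed),
    )
    return kept, report


def mark_parse_status(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Recompute ``parse_ok`` for every record (after external edits)."""
    return [replace(rec, parse_ok=_smiles_parses(rec.smiles)) for rec in records]
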