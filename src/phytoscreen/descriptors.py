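"""The seven physicochemical descriptors used by the screening rules.

MW, hydrogen-bond acceptor/donor counts, rotatable bonds, ring count,
net formal charge, and an atom-contribution (Crippen) logP — the minimal
property set needed for drug-likeness windows on a natural-product
library.  Salts are reduced to their parent fragment first
(:func:`strip_counterions`), so e.g. an anthocyanin chloride is scored as
the flavylium cation it delivers.

Two acceptor/donor conventions are available:

``lipinski`` (default)
    acceptors = number of N and O atoms; donors = number of N and O
    atoms carrying at least one hydrogen.
``pharmacophore``
    RDKit's stricter definitions (``CalcNumHBA``/``CalcNumHBD``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .errors import DataError, StructureParseError
from .library_io import CompoundRecord

#: Canonical ordering of descriptor names, used in rules and CSV columns.
DESCRIPTOR_NAMES = ("mw", "n_ha", "n_hd", "n_rot", "n_ring", "f_char", "logp")

HBOND_CONVENTIONS = ("lipinski", "pharmacophore")


@dataclass(frozen=True)
class DescriptorVector:
    """The seven properties, in the units stated.

    mw: Da (average atomic masses); n_ha/n_hd: counts; n_rot: rotatable
    bonds (non-ring single bonds between non-terminal heavy atoms, amide
    C-N excluded); n_ring: SSSR ring count; f_char: net formal charge in
    elementary-charge units; logp: unitless Crippen estimate.
    """

    mw: float
    n_ha: int
    n_hd: int
    n_rot: int
    n_ring: int
    f_char: int
    logp: float

    def as_dict(self) -> dict[str, float | int]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    return mol


def strip_counterions(smiles: str) -> str:
    """Return the parent fragment of a (possibly multi-fragment) structure.

    The fragment with the most heavy atoms wins; ties go to the larger
    molecular weight, then to the lexicographically smaller canonical
    SMILES.  Single-fragment input is returned canonicalized.
    """
    mol = _mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return Chem.MolToSmiles(frags[0])
    # sort key: most heavy atoms, heaviest, then smallest canonical SMILES
    keyed = [
        (-f.GetNumHeavyAtoms(), -Descriptors.MolWt(f), Chem.MolToSmiles(f)) for f in frags
    ]
    keyed.sort()
    return keyed[0][2]


def compute_descriptors(
    smiles: str, hbond_convention: str = "lipinski"
) -> DescriptorVector:
    """Compute the seven descriptors for a single-fragment structure.

    Multi-fragment input (salts) must be stripped first; passing one
    raises :class:`DataError` rather than silently picking a fragment.
    """
    if hbond_convention not in HBOND_CONVENTIONS:
        raise DataError(f"unknown hbond convention {hbond_convention!r}")
    mol = _mol_from_smiles(smiles)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise DataError(
            f"multi-fragment structure {smiles!r}: call strip_counterions first"
        )
    # recanonicalize so atom order (and hence float summation order in the
    # logp estimate) is identical for any spelling of the same molecule
    mol = _mol_from_smiles(Chem.MolToSmiles(mol))
    if hbond_convention == "lipinski":
        n_ha = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))
        n_hd = sum(
            1
            for a in mol.GetAtoms()
            if a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs() > 0
        )
    else:
        n_ha = rdMolDescriptors.CalcNumHBA(mol)
        n_hd = rdMolDescriptors.CalcNumHBD(mol)
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        n_ha=n_ha,
        n_hd=n_hd,
        n_rot=rdMolDescriptors.CalcNumRotatableBonds(mol),
        n_ring=rdMolDescriptors.CalcNumRings(mol),
        f_char=Chem.GetFormalCharge(mol),
        logp=Crippen.MolLogP(mol),
    )


def compute_descriptor_table(
    records: Iterable[CompoundRecord], hbond_convention: str = "lipinski"
) -> dict[str, DescriptorVector]:
    """Descriptors for every parseable record, after counter-ion stripping.

    Records with ``parse_ok=False`` are skipped (they have no entry).
    """
    table: dict[str, DescriptorVector] = {}
    for rec in records:
        if not rec.parse_ok:
            continue
        parent = strip_counterions(rec.smiles)
        table[rec.compound_id] = compute_descriptors(parent, hbond_convention)
    return table


def write_descriptor_csv(
    descriptors: Mapping[str, DescriptorVector], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", *DESCRIPTOR_NAMES])
        for cid in descriptors:
            vec = descriptors[cid]
            writer.writerow([cid, *[vec.as_dict()[n] for n in DESCRIPTOR_NAMES]])


def read_descriptor_csv(path: str | Path) -> dict[str, DescriptorVector]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"descriptor file not found: {path}")
    table: dict[str, DescriptorVector] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ("compound_id", *DESCRIPTOR_NAMES) if c not in (reader.fieldnames or [])]
        if missing:
            raise DataError(f"descriptor CSV {path} missing columns {missing}")
        for row in reader:
            cid = row["compound_id"]
            if cid in table:
                raise DataError(f"duplicate compound_id {cid!r} in descriptor CSV")
            table[cid] = DescriptorVector(
                mw=float(row["mw"]),
                n_ha=int(row["n_ha"]),
                n_hd=int(row["n_hd"]),
                n_rot=int(row["n_rot"]),
                n_ring=int(row["n_ring"]),
                f_char=int(row["f_char"]),
                logp=float(row["logp"]),
            )
    return table


def append_descriptor_columns(
    in_csv: str | Path, out_csv: str | Path, hbond_convention: str = "lipinski"
) -> None:
    """Batch mode: library CSV in, same CSV with seven descriptor columns out.

    Unparsable rows get empty descriptor cells.
    """
    from .library_io import read_compound_table

    records = read_compound_table(in_csv, format="csv")
    table = compute_descriptor_table(records, hbond_convention)
    with open(out_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["compound_id", "name", "smiles", "compound_class", "source", *DESCRIPTOR_NAMES]
        )
        for rec in records:
            vec = table.get(rec.compound_id)
            cells = [vec.as_dict()[n] for n in DESCRIPTOR_NAMES] if vec else [""] * 7
            writer.writerow(
                [rec.compound_id, rec.name, rec.smiles, rec.compound_class, rec.source, *cells]
            )
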