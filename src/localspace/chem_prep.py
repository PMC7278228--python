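"""Molecule standardization, randomized-SMILES augmentation and prefilters.

Every molecule entering the pipeline passes through :func:`standardize`,
which sanitizes the structure, keeps the largest fragment of multi-fragment
(salt) inputs, strips all stereochemistry (tetrahedral centers and
double-bond geometry) and emits the canonical achiral SMILES that serves as
the molecule's identity key everywhere downstream.  Stereo must go because
the generator's token alphabet contains no stereo symbols, and fragments
must go because it contains no "." separator.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Lipinski

# RDKit prints a parse error for every invalid SMILES; sampled token runs
# contain thousands, so route rejection reporting through our own logging.
RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "SmilesCorpus",
    "StandardizationError",
    "standardize",
    "standardize_all",
    "deduplicate",
    "randomize_smiles",
    "druglike_filter",
    "read_smiles_file",
    "write_smiles_file",
    "read_csv",
    "write_csv",
]


class StandardizationError(ValueError):
    """Raised for unparsable or valence-violating SMILES input."""

    def __init__(self, smiles: str, reason: str = "unparsable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule identified by its canonical achiral SMILES.

    ``smiles_canonical`` is stereo-free and re-canonicalizes to itself;
    ``source_tag`` records provenance (e.g. "training", "generated",
    "cluster_center").
    """

    smiles_canonical: str
    source_tag: str = ""
    id: str = ""

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles_canonical)


@dataclass
class SmilesCorpus:
    """Deduplicated records plus their (possibly augmented) sequences."""

    records: list[MoleculeRecord]
    sequences: list[str] = field(default_factory=list)
    shuffle_seed: int = 0


def standardize(smiles: str, source_tag: str = "", id: str = "") -> MoleculeRecord:
    """Sanitize, keep the largest fragment, remove stereo, canonicalize.

    Raises :class:`StandardizationError` for input RDKit cannot sanitize.
    Two SMILES describing the same achiral molecular graph map to the same
    ``smiles_canonical``.
    """
    if not smiles or not smiles.strip():
        raise StandardizationError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol, isomericSmiles=False)
    if not canonical or Chem.MolFromSmiles(canonical) is None:
        raise StandardizationError(smiles, "canonicalization failed")
    return MoleculeRecord(canonical, source_tag=source_tag, id=id)


def standardize_all(
    smiles_list: Iterable[str],
    source_tag: str = "",
    strict: bool = False,
) -> tuple[list[MoleculeRecord], list[str]]:
    """Standardize a batch; drop-and-log failures unless ``strict``.

    Returns (records, rejected_inputs).  Record ids default to the input
    position when the caller supplies bare strings.
    """
    records: list[MoleculeRecord] = []
    rejected: list[str] = []
    for i, smi in enumerate(smiles_list):
        try:
            records.append(standardize(smi, source_tag=source_tag, id=str(i)))
        except StandardizationError:
            if strict:
                raise
            rejected.append(smi)
    if rejected:
        logger.warning("dropped %d unparsable SMILES during loading", len(rejected))
    return records, rejected


def deduplicate(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Remove replicate molecules, keeping first occurrences in order."""
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if rec.smiles_canonical not in seen:
            seen.add(rec.smiles_canonical)
            out.append(rec)
    return out


def randomize_smiles(record: MoleculeRecord, n_variants: int, seed: int) -> list[str]:
    """Write ``n_variants`` random-atom-order SMILES for one molecule.

    Every variant canonicalizes back to ``record.smiles_canonical``.
    Variants may collide for small molecules; no uniqueness is promised.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    mol = record.mol()
    return list(Chem.MolToRandomSmilesVect(mol, n_variants, randomSeed=int(seed)))


def augment_corpus(
    records: Sequence[MoleculeRecord], n_variants: int, seed: int
) -> SmilesCorpus:
    """Randomized-SMILES augmentation for a whole deduplicated record set."""
    records = deduplicate(records)
    sequences: list[str] = []
    for j, rec in enumerate(records):
        sequences.extend(randomize_smiles(rec, n_variants, seed=seed + j))
    return SmilesCorpus(records=list(records), sequences=sequences, shuffle_seed=seed)


#: Lipinski/Veber bounds; molecules must satisfy all of them with zero
#: violations, plus MW strictly above the ``mw_min`` floor.
_LIPINSKI_VEBER = {
    "mw_max": 500.0,
    "logp_max": 5.0,
    "hbd_max": 5,
    "hba_max": 10,
    "rotb_max": 10,
    "tpsa_max": 140.0,
}


def druglike_filter(
    records: Sequence[MoleculeRecord], mw_min: float = 300.0
) -> list[MoleculeRecord]:
    """Keep molecules passing Lipinski + Veber with MW > ``mw_min``.

    Lipinski: MW <= 500, logP <= 5, H-bond donors <= 5, acceptors <= 10.
    Veber: rotatable bonds <= 10, TPSA <= 140 A^2.  Order is preserved.
    """
    kept: list[MoleculeRecord] = []
    b = _LIPINSKI_VEBER
    for rec in records:
        mol = rec.mol()
        mw = Descriptors.MolWt(mol)
        if not (mw_min < mw <= b["mw_max"]):
            continue
        if Descriptors.MolLogP(mol) > b["logp_max"]:
            continue
        if Lipinski.NumHDonors(mol) > b["hbd_max"]:
            continue
        if Lipinski.NumHAcceptors(mol) > b["hba_max"]:
            continue
        if Descriptors.NumRotatableBonds(mol) > b["rotb_max"]:
            continue
        if Descriptors.TPSA(mol) > b["tpsa_max"]:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# SMILES I/O: one-per-line text (optional second ID column) and CSV.


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read (smiles, id) pairs from a one-SMILES-per-line file."""
    pairs: list[tuple[str, str]] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        pairs.append((parts[0], parts[1] if len(parts) > 1 else str(i)))
    return pairs


def write_smiles_file(path: str | Path, records: Sequence[MoleculeRecord]) -> None:
    lines = [
        f"{rec.smiles_canonical}\t{rec.id}" if rec.id else rec.smiles_canonical
        for rec in records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_csv(
    path: str | Path, smiles_column: str = "smiles", id_column: str = "id"
) -> list[tuple[str, str]]:
    """Read (smiles, id) pairs from a CSV with configurable column names."""
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            smi = row[smiles_column]
            pairs.append((smi, row.get(id_column) or str(i)))
    return pairs


def write_csv(path: str | Path, records: Sequence[MoleculeRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles", "id", "source_tag"])
        for rec in records:
            w.writerow([rec.smiles_canonical, rec.id, rec.source_tag])


def load_records(
    path: str | Path,
    source_tag: str = "training",
    smiles_column: str = "smiles",
    id_column: str = "id",
    strict: bool = False,
) -> list[MoleculeRecord]:
    """Load, standardize and deduplicate molecules from .smi/.txt or .csv."""
    p = Path(path)
    if p.suffix.lower() == ".csv":
        pairs = read_csv(p, smiles_column=smiles_column, id_column=id_column)
    else:
        pairs = read_smiles_file(p)
    records: list[MoleculeRecord] = []
    n_bad = 0
    for smi, mol_id in pairs:
        try:
            rec = standardize(smi, source_tag=source_tag, id=mol_id)
        except StandardizationError:
            if strict:
                raise
            n_bad += 1
            continue
        records.append(rec)
    if n_bad:
        logger.warning("%s: dropped %d unparsable entries", path, n_bad)
    return deduplicate(records)
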