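"""Molecule and activity IO, affinity conversion, activity classes, splits.

Affinities are stored internally in molar units; files carry nanomolar
values (``Ki_nM`` SDF property or ``ki_nM`` CSV column), matching how hERG
binding data is reported in the literature this package serves.

Activity classes follow the displacement-assay convention used for hERG
blockers: potent Ki <= 50 nM, moderate 50 nM < Ki < 5 uM, inactive
Ki >= 5 uM.  The 50 nM boundary is inclusive to potent; the 5 uM boundary
goes to the safer, inactive-flagging class.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

__all__ = [
    "AtomSet",
    "MoleculeRecord",
    "ChemIOError",
    "ki_to_pki",
    "pki_to_ki",
    "classify_activity",
    "read_molecules",
    "write_molecules",
    "split_train_test",
    "write_predictions",
    "standardize_protonation",
]

POTENT_MAX_KI = 5e-8  # molar; Ki <= 50 nM
INACTIVE_MIN_KI = 5e-6  # molar; Ki >= 5 uM

ACTIVITY_CLASSES = ("potent", "moderate", "inactive", "unknown")
SET_LABELS = ("train", "test", "external", "active", "decoy", "unlabeled")


class ChemIOError(RuntimeError):
    """Fatal molecule IO problem (unreadable file, empty set, duplicate ids)."""


@dataclass
class AtomSet:
    """Classed point-set representation of a molecule's heavy atoms.

    Used both for real molecules (classes from :mod:`phore3d.qsar3d` rules)
    and for synthetic benchmark molecules, which are rigid point-sets with
    classes assigned at generation time.
    """

    classes: list[str]
    coords: np.ndarray  # (n, 3) Angstrom
    radii: np.ndarray  # (n,) van der Waals radii, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if not (len(self.classes) == len(self.coords) == len(self.radii)):
            raise ValueError("AtomSet fields must have equal length")
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be positive")


@dataclass
class MoleculeRecord:
    """One compound: structure, affinity, class and provenance.

    Either ``mol`` (an RDKit molecule) or ``atoms`` (a classed point-set,
    for synthetic benchmark compounds) carries the structure; ``sites``
    optionally carries precomputed pharmacophore feature sites.
    """

    id: str
    name: str = ""
    mol: Chem.Mol | None = None
    atoms: AtomSet | None = None
    sites: list | None = None  # list[FeatureSite]; typed loosely to avoid a cycle
    ki: float | None = None  # molar
    set_label: str = "unlabeled"
    source_ref: str = ""
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.ki is not None and self.ki <= 0:
            raise ValueError(f"record {self.id}: Ki must be positive, got {self.ki}")
        if self.set_label not in SET_LABELS:
            raise ValueError(f"record {self.id}: unknown set label {self.set_label!r}")

    @property
    def pki(self) -> float | None:
        return None if self.ki is None else ki_to_pki(self.ki)

    @property
    def activity_class(self) -> str:
        return "unknown" if self.ki is None else classify_activity(self.ki)


def ki_to_pki(ki: float) -> float:
    """pKi = -log10(Ki in molar). Domain error for non-positive Ki."""
    if ki <= 0:
        raise ValueError(f"Ki must be positive, got {ki}")
    return -math.log10(ki)


def pki_to_ki(pki: float) -> float:
    """Inverse of :func:`ki_to_pki`."""
    return 10.0 ** (-pki)


def classify_activity(ki: float) -> str:
    """Activity class from a molar Ki: potent / moderate / inactive."""
    if ki <= 0:
        raise ValueError(f"Ki must be positive, got {ki}")
    if ki <= POTENT_MAX_KI:
        return "potent"
    if ki < INACTIVE_MIN_KI:
        return "moderate"
    return "inactive"


# ---------------------------------------------------------------------------
# Reading


def _parse_ki_nM(raw: str | float | None, mol_id: str) -> float | None:
    if raw is None or raw == "":
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValueError(f"unparsable Ki_nM {raw!r} for molecule {mol_id}")
    if value <= 0:
        raise ValueError(f"non-positive Ki_nM {value} for molecule {mol_id}")
    return value * 1e-9


def _record_from_rdkit(mol: Chem.Mol, ki_field: str, index: int) -> MoleculeRecord:
    mol_id = (
        mol.GetProp("_Name").strip()
        if mol.HasProp("_Name") and mol.GetProp("_Name").strip()
        else f"mol{index}"
    )
    ki = None
    if mol.HasProp(ki_field):
        ki = _parse_ki_nM(mol.GetProp(ki_field), mol_id)
    set_label = mol.GetProp("set").strip() if mol.HasProp("set") else "unlabeled"
    atoms = None
    sites = None
    if mol.HasProp("atom_classes"):
        from .pharmacophore import FeatureSite  # deferred: avoids import cycle

        classes = mol.GetProp("atom_classes").split()
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        radii = np.full(len(classes), 1.7)
        if mol.HasProp("atom_radii"):
            radii = np.array([float(x) for x in mol.GetProp("atom_radii").split()])
        atoms = AtomSet(classes=classes, coords=coords, radii=radii)
        if mol.HasProp("feature_sites"):
            sites = [FeatureSite.from_dict(d) for d in json.loads(mol.GetProp("feature_sites"))]
    return MoleculeRecord(
        id=mol_id,
        name=mol_id,
        mol=mol,
        atoms=atoms,
        sites=sites,
        ki=ki,
        set_label=set_label,
    )


def read_molecules(
    path: str | Path, format: str | None = None, ki_field: str = "Ki_nM"
) -> list[MoleculeRecord]:
    """Read molecules with affinities from an SDF or a SMILES CSV.

    Unparsable entries are skipped with a logged warning; an unreadable file,
    zero valid molecules, or duplicate ids are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    if format is None:
        format = "smiles_csv" if path.suffix.lower() == ".csv" else "sdf"
    if format == "sdf":
        records = _read_sdf(path, ki_field)
    elif format == "smiles_csv":
        records = _read_smiles_csv(path)
    else:
        raise ChemIOError(f"unknown format {format!r}")
    if not records:
        raise ChemIOError(f"no valid molecules in {path}")
    seen: dict[str, int] = {}
    for r in records:
        seen[r.id] = seen.get(r.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ChemIOError(f"duplicate molecule ids in {path}: {', '.join(dups)}")
    _flag_duplicate_structures(records)
    return records


def _read_sdf(path: Path, ki_field: str) -> list[MoleculeRecord]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records: list[MoleculeRecord] = []
    skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            logger.warning("%s: skipping unreadable SDF record %d", path, i)
            continue
        try:
            records.append(_record_from_rdkit(mol, ki_field, i))
        except ValueError as exc:
            skipped += 1
            logger.warning("%s: skipping record %d (%s)", path, i, exc)
    if skipped:
        logger.warning("%s: skipped %d of %d records", path, skipped, skipped + len(records))
    return records


def _read_smiles_csv(path: Path) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    skipped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
            raise ChemIOError(f"{path}: CSV must have 'id' and 'smiles' columns")
        for i, row in enumerate(reader):
            mol_id = (row.get("id") or "").strip()
            smiles = (row.get("smiles") or "").strip()
            mol = Chem.MolFromSmiles(smiles) if smiles else None
            if not mol_id or mol is None:
                skipped += 1
                logger.warning("%s: skipping row %d (bad id or SMILES)", path, i)
                continue
            try:
                ki = _parse_ki_nM(row.get("ki_nM"), mol_id)
            except ValueError as exc:
                skipped += 1
                logger.warning("%s: skipping row %d (%s)", path, i, exc)
                continue
            set_label = (row.get("set") or "unlabeled").strip() or "unlabeled"
            records.append(
                MoleculeRecord(id=mol_id, name=mol_id, mol=mol, ki=ki, set_label=set_label)
            )
    if skipped:
        logger.warning("%s: skipped %d rows", path, skipped)
    return records


def _flag_duplicate_structures(records: Sequence[MoleculeRecord]) -> None:
    """Flag (not drop) records whose canonical SMILES repeats an earlier one."""
    first_by_smiles: dict[str, str] = {}
    for r in records:
        if r.mol is None or r.atoms is not None:
            # point-set records all share a bond-less placeholder topology
            continue
        smi = Chem.MolToSmiles(r.mol)
        if smi in first_by_smiles:
            r.duplicate_of = first_by_smiles[smi]
            logger.warning("%s is a structural duplicate of %s", r.id, r.duplicate_of)
        else:
            first_by_smiles[smi] = r.id


# ---------------------------------------------------------------------------
# Writing


def _rdkit_mol_for_record(record: MoleculeRecord) -> Chem.Mol:
    if record.atoms is not None:
        return _pointset_to_mol(record)
    if record.mol is None:
        raise ChemIOError(f"record {record.id} has no structure to write")
    return Chem.Mol(record.mol)


_CLASS_TO_ELEMENT = {"D": "N", "H": "C", "N": "O", "P": "N", "W": "O", "X": "C"}
_CLASS_TO_CHARGE = {"P": 1, "N": -1}


def _pointset_to_mol(record: MoleculeRecord) -> Chem.Mol:
    """Serialize a classed point-set as a bond-less V2000 molecule.

    Element symbols are only placeholders; the authoritative classes, radii
    and feature sites ride along as SDF properties.
    """
    rw = Chem.RWMol()
    assert record.atoms is not None
    for cls in record.atoms.classes:
        atom = Chem.Atom(_CLASS_TO_ELEMENT.get(cls, "C"))
        atom.SetFormalCharge(_CLASS_TO_CHARGE.get(cls, 0))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(record.atoms.coords):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    mol.SetProp("atom_classes", " ".join(record.atoms.classes))
    mol.SetProp("atom_radii", " ".join(f"{r:.4f}" for r in record.atoms.radii))
    if record.sites is not None:
        mol.SetProp(
            "feature_sites", json.dumps([s.to_dict() for s in record.sites])
        )
    return mol


def write_molecules(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records to SDF with Ki_nM and set properties preserved."""
    if not records:
        raise ChemIOError("no records to write")
    writer = Chem.SDWriter(str(path))
    for r in records:
        mol = _rdkit_mol_for_record(r)
        mol.SetProp("_Name", r.id)
        if r.ki is not None:
            mol.SetProp("Ki_nM", f"{r.ki * 1e9:.6g}")
        mol.SetProp("set", r.set_label)
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# Splitting and prediction output


def split_train_test(
    records: Sequence[MoleculeRecord],
    train_fraction: float = 0.6,
    seed: int = 42,
    stratify: bool = False,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Random train/test partition; deterministic for a fixed seed.

    |train| = round(train_fraction * n). With ``stratify`` the split is done
    within each activity class (sizes then sum from per-class rounding).
    Updates each record's ``set_label`` in place.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    if stratify:
        groups: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            groups.setdefault(r.activity_class, []).append(i)
        train_idx: list[int] = []
        for key in sorted(groups):
            idx = np.array(groups[key])
            perm = rng.permutation(len(idx))
            k = round(train_fraction * len(idx))
            train_idx.extend(idx[perm[:k]].tolist())
        train_set = set(train_idx)
    else:
        perm = rng.permutation(n)
        k = round(train_fraction * n)
        train_set = set(perm[:k].tolist())
    train, test = [], []
    for i, r in enumerate(records):
        if i in train_set:
            r.set_label = "train"
            train.append(r)
        else:
            r.set_label = "test"
            test.append(r)
    return train, test


def write_predictions(
    rows: Iterable[tuple[str, float, int | None, float | None]], path: str | Path
) -> None:
    """CSV of (id, predicted pKi, matched sites, alignment RMSD), 4 decimals."""
    rows = list(rows)
    if not rows:
        raise ValueError("no prediction rows to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "pred_pKi", "matched_sites", "align_rmsd"])
        for mol_id, pred, n_sites, rmsd_ in rows:
            writer.writerow(
                [
                    mol_id,
                    f"{pred:.4f}",
                    "" if n_sites is None else n_sites,
                    "" if rmsd_ is None else f"{rmsd_:.4f}",
                ]
            )


# ---------------------------------------------------------------------------
# Protonation


_PROTONATION_RULES = (
    # (SMARTS, atom map index in match, formal charge, H delta)
    ("[NX3;H2,H1,H0;+0;!$(N-[a]);!$(N-C=[O,N,S]);!$(N=*);!$(N-[O,N])]", 0, +1, +1),
    ("[CX3](=O)[OX2H1]", 2, -1, -1),
)


def standardize_protonation(mol: Chem.Mol) -> Chem.Mol:
    """Single rule-based protonation pass approximating pH 7.4.

    Aliphatic amines are protonated (+1); carboxylic acids deprotonated (-1).
    This replaces a full protonation-state enumeration: one state per input.
    """
    mol = Chem.Mol(mol)
    rw = Chem.RWMol(mol)
    for smarts, pos, charge, h_delta in _PROTONATION_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetMol().GetSubstructMatches(patt):
            atom = rw.GetAtomWithIdx(match[pos])
            if atom.GetFormalCharge() != 0:
                continue
            atom.SetFormalCharge(charge)
            atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() + h_delta))
            atom.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out
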