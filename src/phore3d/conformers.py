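"""Conformer ensembles under an energy-window / RMSD-redundancy contract.

The retention contract is what the downstream pharmacophore and QSAR stages
rely on: every kept conformer lies within ``energy_window`` kJ/mol of the
ensemble minimum and differs from every other kept conformer by at least
``rmsd_cutoff`` Angstrom heavy-atom RMSD after optimal rigid superposition.
Raw conformer generation is delegated to RDKit's ETKDG distance-geometry
embedder followed by MMFF94 minimisation; the engine name and version are
recorded in the ensemble metadata so results remain attributable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import rdkit
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import MoleculeRecord
from .geometry import rmsd as plain_rmsd
from .geometry import superposed_rmsd

logger = logging.getLogger(__name__)

__all__ = [
    "ConformerEnsemble",
    "ConformerError",
    "generate_ensemble",
    "prune_ensemble",
    "heavy_atom_rmsd",
    "ensemble_from_record",
]

KCAL_TO_KJ = 4.184

DEFAULT_ENERGY_WINDOW = 21.0  # kJ/mol
DEFAULT_RMSD_CUTOFF = 0.5  # Angstrom
DEFAULT_MAX_CONFS = 200


class ConformerError(RuntimeError):
    pass


@dataclass
class ConformerEnsemble:
    """Ordered conformers of one molecule, energies relative to the minimum."""

    molecule_id: str
    coords: list[np.ndarray]  # each (n_atoms, 3)
    rel_energies: np.ndarray  # kJ/mol, ascending, first element 0
    heavy_idx: np.ndarray  # indices of heavy atoms within coords rows
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rel_energies = np.asarray(self.rel_energies, dtype=float)
        self.heavy_idx = np.asarray(self.heavy_idx, dtype=int)
        if len(self.coords) != len(self.rel_energies):
            raise ValueError("coords and rel_energies length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    def heavy_coords(self, i: int) -> np.ndarray:
        return self.coords[i][self.heavy_idx]


def heavy_atom_rmsd(
    conf_a: np.ndarray, conf_b: np.ndarray, superpose: bool = True
) -> float:
    """RMSD between two same-ordered heavy-atom coordinate sets.

    With ``superpose`` the minimum over rigid transforms is returned.
    """
    conf_a = np.asarray(conf_a, dtype=float)
    conf_b = np.asarray(conf_b, dtype=float)
    if conf_a.shape != conf_b.shape:
        raise ValueError(f"atom-count mismatch: {conf_a.shape} vs {conf_b.shape}")
    if len(conf_a) == 0:
        raise ValueError("need at least one atom")
    if superpose:
        return superposed_rmsd(conf_a, conf_b)
    return plain_rmsd(conf_a, conf_b)


def prune_ensemble(
    ensemble: ConformerEnsemble,
    energy_window: float = DEFAULT_ENERGY_WINDOW,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
) -> ConformerEnsemble:
    """Greedy retention in ascending-energy order.

    A conformer is kept iff its relative energy is within the window and its
    superposed heavy-atom RMSD to every already-kept conformer is at least
    the cutoff. Idempotent on its own output.
    """
    order = np.argsort(ensemble.rel_energies, kind="stable")
    kept: list[int] = []
    for i in order:
        rel = ensemble.rel_energies[i] - ensemble.rel_energies[order[0]]
        if rel > energy_window:
            continue
        ci = ensemble.coords[i][ensemble.heavy_idx]
        if all(
            heavy_atom_rmsd(ci, ensemble.coords[j][ensemble.heavy_idx]) >= rmsd_cutoff
            for j in kept
        ):
            kept.append(int(i))
    min_e = ensemble.rel_energies[order[0]] if len(order) else 0.0
    return ConformerEnsemble(
        molecule_id=ensemble.molecule_id,
        coords=[ensemble.coords[i] for i in kept],
        rel_energies=np.array([ensemble.rel_energies[i] - min_e for i in kept]),
        heavy_idx=ensemble.heavy_idx,
        metadata=dict(
            ensemble.metadata,
            energy_window_kJmol=energy_window,
            rmsd_cutoff_A=rmsd_cutoff,
        ),
    )


def generate_ensemble(
    molecule: MoleculeRecord,
    max_confs: int = DEFAULT_MAX_CONFS,
    energy_window: float = DEFAULT_ENERGY_WINDOW,
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
    seed: int = 42,
) -> ConformerEnsemble:
    """Embed, minimise and prune conformers for one molecule.

    Deterministic for a fixed seed. Rigid molecules collapse to a single
    conformer through the redundancy cutoff.
    """
    if molecule.mol is None:
        raise ConformerError(f"{molecule.id}: no structure for conformer generation")
    if max_confs < 1:
        raise ValueError("max_confs must be >= 1")
    mol = Chem.AddHs(Chem.Mol(molecule.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = -1.0  # pruning is ours, below
    params.useRandomCoords = False
    conf_ids = list(AllChem.EmbedMultipleConfs(mol, numConfs=max_confs, params=params))
    if not conf_ids:
        raise ConformerError(f"{molecule.id}: conformer embedding failed")
    results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    energies_kcal = []
    ok_ids = []
    for cid, (converged, energy) in zip(conf_ids, results):
        if energy is None or not np.isfinite(energy):
            continue
        ok_ids.append(cid)
        energies_kcal.append(energy)
    if not ok_ids:
        raise ConformerError(f"{molecule.id}: no conformer could be minimised")
    energies = np.array(energies_kcal) * KCAL_TO_KJ
    energies -= energies.min()
    order = np.argsort(energies, kind="stable")
    heavy_idx = np.array(
        [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1], dtype=int
    )
    coords = []
    for i in order:
        conf = mol.GetConformer(ok_ids[i])
        coords.append(np.array(conf.GetPositions(), dtype=float))
    raw = ConformerEnsemble(
        molecule_id=molecule.id,
        coords=coords,
        rel_energies=energies[order],
        heavy_idx=heavy_idx,
        metadata={
            "engine": f"rdkit-ETKDGv3+MMFF94 {rdkit.__version__}",
            "seed": int(seed),
            "max_confs": int(max_confs),
        },
    )
    pruned = prune_ensemble(raw, energy_window=energy_window, rmsd_cutoff=rmsd_cutoff)
    if len(pruned) == 0:
        raise ConformerError(f"{molecule.id}: no conformer survived pruning")
    pruned.metadata["n_raw"] = len(raw)
    return pruned


def ensemble_from_record(record: MoleculeRecord) -> ConformerEnsemble:
    """Single rigid 'conformer' for a classed point-set record."""
    if record.atoms is None:
        raise ConformerError(f"{record.id}: record carries no point-set atoms")
    n = len(record.atoms.classes)
    return ConformerEnsemble(
        molecule_id=record.id,
        coords=[np.asarray(record.atoms.coords, dtype=float)],
        rel_energies=np.array([0.0]),
        heavy_idx=np.arange(n),
        metadata={"engine": "synthetic-rigid"},
    )
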