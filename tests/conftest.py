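"""Shared fixtures: small 3D molecules and a compact synthetic benchmark."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from phore3d.synthdata import (
    SyntheticSpec,
    _make_layout,
    assign_activities,
    generate_actives,
    generate_decoys,
)


def embed(smiles: str, seed: int = 7) -> Chem.Mol:
    """SMILES -> 3D molecule with explicit hydrogens."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    AllChem.MMFFOptimizeMolecule(mol)
    return mol


@pytest.fixture(scope="session")
def benzene():
    return embed("c1ccccc1")


@pytest.fixture(scope="session")
def acetone():
    return embed("CC(=O)C")


@pytest.fixture(scope="session")
def methylammonium():
    return embed("C[NH3+]")


@pytest.fixture(scope="session")
def small_bench():
    """Compact synthetic benchmark: 40 actives + 80 decoys, seed 11."""
    spec = SyntheticSpec(seed=11, n_actives=40, n_decoys=80)
    layout = _make_layout(spec)
    actives, truth = generate_actives(spec, layout=layout)
    decoys = generate_decoys(spec, actives=actives, layout=layout)
    activities = assign_activities(actives, decoys, spec, truth)
    return {
        "spec": spec,
        "layout": layout,
        "actives": actives,
        "decoys": decoys,
        "truth": truth,
        "activities": activities,
    }
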