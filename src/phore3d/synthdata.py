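"""Synthetic benchmark generator for the whole screening stack.

Actives are rigid classed point-sets that all carry a planted five-feature
AHPRR pharmacophore (one acceptor, one hydrophobe, one positive ionizable,
two aromatic rings) jittered by Gaussian noise, plus distractor feature
sites, a shared scaffold, and a per-molecule subset of substituent atoms at
fixed anchor positions.  Activity is a linear function of which substituent
anchors are occupied, plus Gaussian noise — so after hypothesis recovery
and alignment, atom-based grid occupancy can recover the planted
coefficients and the screen can separate actives from decoys.

Decoys match the actives in atom count, class composition and radius of
gyration, but their geometries are resampled uniformly, so they rarely
present the planted feature arrangement.

Synthetic molecules bypass conformer generation by design: they isolate
the hypothesis-search/alignment/QSAR/enrichment mathematics from the
chemistry of real conformers, which is exercised separately by real
molecules in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import AtomSet, MoleculeRecord, ki_to_pki, pki_to_ki, split_train_test, write_molecules
from .pharmacophore import FeatureSite, PharmacophoreHypothesis

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "plant_hypothesis",
    "generate_actives",
    "generate_decoys",
    "assign_activities",
    "make_benchmark",
]

# feature kind -> atom class carried by the realising atom
KIND_TO_CLASS = {"A": "W", "D": "D", "H": "H", "N": "N", "P": "P", "R": "H"}
DEFAULT_RADIUS = 1.7  # Angstrom, all synthetic atoms


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic benchmark."""

    seed: int = 1
    n_actives: int = 200
    n_decoys: int = 2000
    site_jitter_sigma: float = 0.3  # Angstrom, per coordinate
    n_distractor_sites: int = 3
    n_scaffold_atoms: int = 8
    activity_intercept: float = 6.5  # pKi
    activity_coefficients: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, -0.4, -0.6, -0.8, -1.0)
    noise_sigma: float = 0.3  # pKi units
    ki_range: tuple[float, float] = (1e-9, 1e-4)  # molar

    def __post_init__(self) -> None:
        if self.n_actives < 5:
            raise ValueError("need at least 5 actives to build a hypothesis")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 < self.ki_range[0] < self.ki_range[1]:
            raise ValueError("ki_range must be positive and increasing")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_actives": self.n_actives,
            "n_decoys": self.n_decoys,
            "site_jitter_sigma": self.site_jitter_sigma,
            "n_distractor_sites": self.n_distractor_sites,
            "n_scaffold_atoms": self.n_scaffold_atoms,
            "activity_intercept": self.activity_intercept,
            "activity_coefficients": list(self.activity_coefficients),
            "noise_sigma": self.noise_sigma,
            "ki_range": list(self.ki_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "activity_coefficients" in d:
            d["activity_coefficients"] = tuple(d["activity_coefficients"])
        if "ki_range" in d:
            d["ki_range"] = tuple(d["ki_range"])
        return cls(**d)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), int(stream)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def plant_hypothesis(seed: int) -> PharmacophoreHypothesis:
    """Deterministic non-degenerate AHPRR geometry for one seed.

    Five sites with kinds {A, H, P, R, R}, pairwise distances in [3, 12] A,
    not coplanar, centred at the origin.
    """
    rng = _rng(seed, 0)
    kinds = ["A", "H", "P", "R", "R"]
    while True:
        pts = rng.uniform(0.0, 9.0, size=(5, 3))
        diffs = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diffs**2).sum(-1))
        off = dist[np.triu_indices(5, 1)]
        if off.min() < 3.0 or off.max() > 12.0:
            continue
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[2] < 0.5:  # nearly coplanar
            continue
        break
    pts = pts - pts.mean(axis=0)
    sites = []
    for kind, pos in zip(kinds, pts):
        direction = None
        if kind in ("A", "R"):
            v = rng.normal(size=3)
            direction = v / np.linalg.norm(v)
        sites.append(FeatureSite(kind=kind, position=pos, direction=direction))
    return PharmacophoreHypothesis(
        id="AHPRR.planted",
        sites=sites,
        provenance={"generator": "synthdata.plant_hypothesis", "seed": int(seed)},
    )


def _sample_away(rng, existing: np.ndarray, low: float, high: float, min_dist: float) -> np.ndarray:
    for _ in range(1000):
        p = rng.uniform(low, high, size=3)
        if len(existing) == 0 or np.min(np.linalg.norm(existing - p, axis=1)) >= min_dist:
            return p
    raise RuntimeError("could not place a point away from existing ones")


@dataclass
class _Layout:
    """Frame-level geometry shared by all actives of one benchmark."""

    hypothesis: PharmacophoreHypothesis
    anchors: np.ndarray  # (n_sub, 3) substituent anchor positions
    anchor_classes: list[str]
    scaffold: np.ndarray  # (n_scaffold, 3)


def _make_layout(spec: SyntheticSpec) -> _Layout:
    hyp = plant_hypothesis(spec.seed)
    rng = _rng(spec.seed, 1)
    planted = hyp.positions
    taken = planted.copy()
    anchors = []
    for _ in spec.activity_coefficients:
        p = _sample_away(rng, taken, -6.0, 6.0, 2.0)
        anchors.append(p)
        taken = np.vstack([taken, p])
    anchor_classes = [str(rng.choice(["H", "W", "D"])) for _ in anchors]
    scaffold = []
    for _ in range(spec.n_scaffold_atoms):
        p = _sample_away(rng, taken, -6.0, 6.0, 1.5)
        scaffold.append(p)
        taken = np.vstack([taken, p])
    return _Layout(
        hypothesis=hyp,
        anchors=np.array(anchors).reshape(-1, 3),
        anchor_classes=anchor_classes,
        scaffold=np.array(scaffold).reshape(-1, 3),
    )


def generate_actives(
    spec: SyntheticSpec, layout: _Layout | None = None
) -> tuple[list[MoleculeRecord], dict]:
    """Planted-pharmacophore actives plus ground truth.

    Every active carries the 5 planted sites (jittered), distractor sites,
    the shared scaffold, and its substituent subset; each molecule is then
    moved by a random rigid transform so alignment is non-trivial.
    """
    layout = layout or _make_layout(spec)
    rng = _rng(spec.seed, 2)
    hyp = layout.hypothesis
    n_sub = len(spec.activity_coefficients)
    records: list[MoleculeRecord] = []
    z_matrix = np.zeros((spec.n_actives, n_sub), dtype=int)
    for i in range(spec.n_actives):
        jitter = rng.normal(0.0, spec.site_jitter_sigma, size=(hyp.k, 3))
        site_pos = hyp.positions + jitter
        kinds = [s.kind for s in hyp.sites]
        dirs = [None if s.direction is None else s.direction.copy() for s in hyp.sites]

        taken = np.vstack([site_pos, layout.anchors, layout.scaffold])
        distract_pos, distract_kinds = [], []
        for _ in range(spec.n_distractor_sites):
            p = _sample_away(rng, taken, -7.0, 7.0, 2.0)
            distract_pos.append(p)
            distract_kinds.append(str(rng.choice(["A", "D", "H", "N", "P", "R"])))
            taken = np.vstack([taken, p])

        z = rng.integers(0, 2, size=n_sub)
        z_matrix[i] = z

        atom_pos = [site_pos, np.array(distract_pos).reshape(-1, 3), layout.scaffold]
        atom_cls = (
            [KIND_TO_CLASS[k] for k in kinds]
            + [KIND_TO_CLASS[k] for k in distract_kinds]
            + ["H"] * len(layout.scaffold)
        )
        sub_idx = np.flatnonzero(z)
        if len(sub_idx):
            atom_pos.append(layout.anchors[sub_idx])
            atom_cls.extend(layout.anchor_classes[j] for j in sub_idx)
        coords = np.vstack([a for a in atom_pos if len(a)])

        rot = _random_rotation(rng)
        trans = rng.uniform(-20.0, 20.0, size=3)
        coords = coords @ rot.T + trans
        all_site_pos = np.vstack([site_pos, np.array(distract_pos).reshape(-1, 3)])
        all_site_pos = all_site_pos @ rot.T + trans
        all_kinds = kinds + distract_kinds
        sites = []
        for j, (kind, pos) in enumerate(zip(all_kinds, all_site_pos)):
            d = dirs[j] if j < hyp.k else None
            sites.append(
                FeatureSite(
                    kind=kind,
                    position=pos,
                    direction=None if d is None else rot @ d,
                )
            )
        records.append(
            MoleculeRecord(
                id=f"act{i:04d}",
                atoms=AtomSet(
                    classes=atom_cls,
                    coords=coords,
                    radii=np.full(len(atom_cls), DEFAULT_RADIUS),
                ),
                sites=sites,
                set_label="active",
                source_ref="synthdata",
            )
        )
    truth = {
        "hypothesis": hyp.to_dict(),
        "anchors": layout.anchors.tolist(),
        "anchor_classes": layout.anchor_classes,
        "scaffold": layout.scaffold.tolist(),
        "z_matrix": z_matrix.tolist(),
        "spec": spec.to_dict(),
    }
    return records, truth


def generate_decoys(
    spec: SyntheticSpec, actives: list[MoleculeRecord] | None = None, layout: _Layout | None = None
) -> list[MoleculeRecord]:
    """Property-matched decoys with resampled geometry.

    Each decoy copies the atom count, class multiset and site kinds of a
    randomly chosen active; positions are redrawn uniformly in a ball whose
    radius reproduces the template's radius of gyration, so the class
    composition and size distributions match while the planted geometry is
    destroyed.
    """
    if actives is None:
        actives, _ = generate_actives(spec, layout=layout)
    rng = _rng(spec.seed, 3)
    decoys: list[MoleculeRecord] = []
    for i in range(spec.n_decoys):
        tmpl = actives[int(rng.integers(0, len(actives)))]
        n_atoms = len(tmpl.atoms.classes)
        centered = tmpl.atoms.coords - tmpl.atoms.coords.mean(axis=0)
        r_gyr = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
        ball_r = r_gyr * np.sqrt(5.0 / 3.0)  # uniform ball with matching R_g
        u = rng.normal(size=(n_atoms, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii_frac = rng.uniform(0.0, 1.0, size=n_atoms) ** (1.0 / 3.0)
        coords = u * (radii_frac * ball_r)[:, None]
        site_kinds = [s.kind for s in tmpl.sites]
        sites = []
        for j, kind in enumerate(site_kinds):
            direction = None
            if kind in ("A", "R"):
                v = rng.normal(size=3)
                direction = v / np.linalg.norm(v)
            sites.append(FeatureSite(kind=kind, position=coords[j], direction=direction))
        decoys.append(
            MoleculeRecord(
                id=f"dec{i:04d}",
                atoms=AtomSet(
                    classes=list(tmpl.atoms.classes),
                    coords=coords,
                    radii=np.full(n_atoms, DEFAULT_RADIUS),
                ),
                sites=sites,
                set_label="decoy",
                source_ref="synthdata",
            )
        )
    return decoys


def assign_activities(
    actives: list[MoleculeRecord],
    decoys: list[MoleculeRecord],
    spec: SyntheticSpec,
    truth: dict,
) -> pd.DataFrame:
    """Planted linear activities for actives; inactive-range Ki for decoys.

    active pKi = intercept + sum_j coef_j z_ij + N(0, noise_sigma^2),
    clipped into the pKi range implied by ki_range.  Decoys draw Ki
    log-uniformly from [5 uM, 54 uM] (the inactive class).
    """
    rng = _rng(spec.seed, 4)
    z = np.array(truth["z_matrix"], dtype=float)
    coefs = np.array(spec.activity_coefficients, dtype=float)
    pki = (
        spec.activity_intercept
        + z @ coefs
        + rng.normal(0.0, spec.noise_sigma, size=len(actives))
    )
    lo, hi = ki_to_pki(spec.ki_range[1]), ki_to_pki(spec.ki_range[0])
    pki = np.clip(pki, lo, hi)
    rows = []
    for record, value in zip(actives, pki):
        record.ki = pki_to_ki(float(value))
        rows.append({"id": record.id, "ki_nM": record.ki * 1e9, "pki": float(value), "set": "active"})
    log_lo, log_hi = np.log10(5e-6), np.log10(5.4e-5)
    for record in decoys:
        ki = 10.0 ** rng.uniform(log_lo, log_hi)
        record.ki = float(ki)
        rows.append({"id": record.id, "ki_nM": ki * 1e9, "pki": ki_to_pki(ki), "set": "decoy"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Small chemically real family

# 1-benzyl-4-arylpiperidines: the classic hERG-blocker motif (two aromatic
# rings, a basic amine that is positively charged at physiological pH, and
# hydrophobic bulk).  Ki values are synthetic benchmark labels spanning the
# potent-to-inactive range, not literature measurements.
REAL_FAMILY: tuple[tuple[str, str, float], ...] = (
    ("rf01", "C1CN(Cc2ccccc2)CCC1c1ccccc1", 5.0),
    ("rf02", "C1CN(Cc2ccccc2)CCC1c1ccc(F)cc1", 12.0),
    ("rf03", "C1CN(Cc2ccccc2)CCC1c1ccc(Cl)cc1", 30.0),
    ("rf04", "C1CN(Cc2ccccc2)CCC1c1ccc(OC)cc1", 150.0),
    ("rf05", "C1CN(Cc2ccccc2)CCC1c1ccc(C)cc1", 800.0),
    ("rf06", "C1CN(Cc2ccccc2)CCC1c1ccc(O)cc1", 4000.0),
    ("rf07", "C1CN(Cc2ccccc2)CCC1c1ccc(C#N)cc1", 20000.0),
    ("rf08", "C1CN(Cc2ccccc2)CCC1c1ccc(C(F)(F)F)cc1", 50000.0),
)


def real_family() -> list[MoleculeRecord]:
    """Small chemically real ligand family (synthetic Ki labels).

    Exercises SMILES parsing, protonation, conformer generation and feature
    perception end-to-end, complementing the rigid point-set benchmark.
    """
    from rdkit import Chem

    from .chemio import standardize_protonation

    records = []
    for mol_id, smiles, ki_nM in REAL_FAMILY:
        mol = standardize_protonation(Chem.MolFromSmiles(smiles))
        records.append(
            MoleculeRecord(
                id=mol_id,
                mol=mol,
                ki=ki_nM * 1e-9,
                set_label="unlabeled",
                source_ref="synthdata.real_family",
            )
        )
    return records


def make_benchmark(spec: SyntheticSpec, outdir: str | Path, force: bool = False) -> dict:
    """Write a self-contained benchmark bundle; returns its file map.

    Contents: actives.sdf (with train/test labels), decoys.sdf,
    activities.csv, truth.json.  Deterministic per seed.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    layout = _make_layout(spec)
    actives, truth = generate_actives(spec, layout=layout)
    decoys = generate_decoys(spec, actives=actives, layout=layout)
    activities = assign_activities(actives, decoys, spec, truth)
    train, test = split_train_test(actives, train_fraction=0.6, seed=spec.seed)
    truth["train_ids"] = sorted(r.id for r in train)
    truth["test_ids"] = sorted(r.id for r in test)

    paths = {
        "actives": outdir / "actives.sdf",
        "decoys": outdir / "decoys.sdf",
        "activities": outdir / "activities.csv",
        "active_ids": outdir / "actives.txt",
        "truth": outdir / "truth.json",
    }
    paths["active_ids"].write_text("\n".join(r.id for r in actives) + "\n")
    write_molecules(actives, paths["actives"])
    write_molecules(decoys, paths["decoys"])
    activities.to_csv(paths["activities"], index=False)
    paths["truth"].write_text(json.dumps(truth, sort_keys=True, indent=1))
    return {k: str(v) for k, v in paths.items()}
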