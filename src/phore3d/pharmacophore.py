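"""Pharmacophore perception, common-hypothesis search, matching, alignment.

A pharmacophore hypothesis is a set of k feature sites (acceptor, donor,
hydrophobe, negative/positive ionizable, aromatic ring) in a reference
frame.  Hypotheses common to a family of active ligands are found by
enumerating k-site combinations over each ligand's conformer ensemble,
encoding every combination as a sorted-kind label plus inter-site distance
vector, and partitioning distance space with a recursive bisection tree:
leaf boxes of edge <= ``bin_size`` that contain variants from at least a
``must_match`` fraction of the ligands yield one hypothesis each, with the
box medoid providing the reference geometry.

Ligands are matched to a hypothesis by exhaustive kind-consistent site
correspondence search with closed-form (Kabsch) rigid superposition, and
aligned into the hypothesis frame for atom-based QSAR.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from rdkit import Chem

from .conformers import ConformerEnsemble
from .geometry import RigidTransform, kabsch

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSite",
    "PharmacophoreHypothesis",
    "HypothesisMatch",
    "AlignedLigand",
    "DegenerateSitesError",
    "perceive_features",
    "sites_for_ensemble",
    "find_common_hypotheses",
    "score_hypothesis",
    "match_ligand",
    "align_ligand",
    "hypothesis_label",
]

FEATURE_KINDS = ("A", "D", "H", "N", "P", "R")
DEFAULT_SITE_TOLERANCE = 2.0  # Angstrom
DEFAULT_BIN_SIZE = 1.0  # Angstrom, final partition-box edge


class DegenerateSitesError(RuntimeError):
    """Matched sites are too close to collinear for a stable alignment."""


@dataclass
class FeatureSite:
    kind: str
    position: np.ndarray
    direction: np.ndarray | None = None
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("feature position must be finite")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float).reshape(3)
            norm = float(np.linalg.norm(self.direction))
            if abs(norm - 1.0) > 1e-6:
                if norm <= 0:
                    raise ValueError("zero-length feature direction")
                self.direction = self.direction / norm

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "position": [float(v) for v in self.position],
            "direction": None
            if self.direction is None
            else [float(v) for v in self.direction],
            "atom_indices": list(self.atom_indices),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSite":
        return cls(
            kind=d["kind"],
            position=np.array(d["position"], dtype=float),
            direction=None if d.get("direction") is None else np.array(d["direction"]),
            atom_indices=tuple(d.get("atom_indices", ())),
        )


def hypothesis_label(kinds) -> str:
    """Sorted kind letters, e.g. {A,H,P,R,R} -> 'AHPRR'."""
    return "".join(sorted(kinds))


@dataclass
class PharmacophoreHypothesis:
    """k feature sites in a reference frame, with per-site match tolerances."""

    id: str
    sites: list[FeatureSite]
    site_tolerance: np.ndarray | float = DEFAULT_SITE_TOLERANCE
    score: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tol = np.asarray(self.site_tolerance, dtype=float)
        if tol.ndim == 0:
            tol = np.full(len(self.sites), float(tol))
        if len(tol) != len(self.sites) or np.any(tol <= 0):
            raise ValueError("site_tolerance must be positive, one per site")
        self.site_tolerance = tol

    @property
    def label(self) -> str:
        return hypothesis_label(s.kind for s in self.sites)

    @property
    def k(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def distance_matrix(self) -> np.ndarray:
        pos = self.positions
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=-1))

    def to_dict(self) -> dict:
        return {
            "schema": "phore3d-hypothesis/1",
            "id": self.id,
            "label": self.label,
            "sites": [s.to_dict() for s in self.sites],
            "site_tolerance": [float(t) for t in self.site_tolerance],
            "distance_matrix": self.distance_matrix.tolist(),
            "score": None if math.isnan(self.score) else float(self.score),
            "provenance": {
                k: v for k, v in self.provenance.items() if _json_safe(v)
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreHypothesis":
        return cls(
            id=d["id"],
            sites=[FeatureSite.from_dict(s) for s in d["sites"]],
            site_tolerance=np.array(d["site_tolerance"], dtype=float),
            score=float("nan") if d.get("score") is None else float(d["score"]),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PharmacophoreHypothesis":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass
class HypothesisMatch:
    molecule_id: str
    conformer_index: int
    correspondence: tuple[tuple[int, int], ...]  # (hypothesis site, ligand site)
    n_matched: int
    match_rmsd: float


@dataclass
class AlignedLigand:
    molecule_id: str
    conformer_index: int
    transform: RigidTransform
    coordinates_aligned: np.ndarray  # all-atom coordinates in hypothesis frame
    match: HypothesisMatch


# ---------------------------------------------------------------------------
# Feature perception


_DEFS_CACHE: dict | None = None


def load_feature_definitions() -> dict:
    """Shipped SMARTS rule table, compiled once."""
    global _DEFS_CACHE
    if _DEFS_CACHE is None:
        raw = yaml.safe_load(
            resources.files("phore3d.data").joinpath("features.yaml").read_text()
        )
        compiled = {"version": raw["version"], "hydrophobic_min_group": raw.get("hydrophobic_min_group", 1)}
        for key in ("acceptor", "donor", "positive", "negative", "hydrophobic"):
            compiled[key] = []
            for smarts in raw[key]:
                patt = Chem.MolFromSmarts(smarts)
                if patt is None:
                    raise ValueError(f"bad SMARTS in feature table: {smarts}")
                compiled[key].append((smarts, patt))
        _DEFS_CACHE = compiled
    return _DEFS_CACHE


def _matched_atoms(mol: Chem.Mol, patterns) -> set[int]:
    out: set[int] = set()
    for _, patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            out.add(match[0])
    return out


def perceive_features(mol: Chem.Mol, coords: np.ndarray | None = None) -> list[FeatureSite]:
    """Perceive feature sites from the shipped rule table.

    ``coords`` overrides the molecule's first conformer (rows must follow
    atom order).  Deterministic: sites are sorted by (kind, atom indices).
    """
    defs = load_feature_definitions()
    if coords is None:
        if mol.GetNumConformers() == 0:
            raise ValueError("molecule has no 3D coordinates")
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    else:
        coords = np.asarray(coords, dtype=float)
        if len(coords) != mol.GetNumAtoms():
            raise ValueError("coords length does not match atom count")

    sites: list[FeatureSite] = []
    for kind, key in (("A", "acceptor"), ("D", "donor"), ("P", "positive"), ("N", "negative")):
        for idx in sorted(_matched_atoms(mol, defs[key])):
            direction = None
            if kind == "A":
                direction = _acceptor_direction(mol, idx, coords)
            sites.append(
                FeatureSite(kind=kind, position=coords[idx], direction=direction, atom_indices=(idx,))
            )

    # Hydrophobic groups: connected components of matched atoms -> centroid.
    hyd = _matched_atoms(mol, defs["hydrophobic"])
    for group in _connected_groups(mol, hyd):
        if len(group) < defs["hydrophobic_min_group"]:
            continue
        idx = tuple(sorted(group))
        sites.append(
            FeatureSite(kind="H", position=coords[list(idx)].mean(axis=0), atom_indices=idx)
        )

    # Aromatic rings: centroid + normal per aromatic SSSR ring.
    for ring in Chem.GetSymmSSSR(mol):
        ring = tuple(ring)
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        pts = coords[list(ring)]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        sites.append(
            FeatureSite(kind="R", position=centroid, direction=vt[2], atom_indices=tuple(sorted(ring)))
        )

    sites.sort(key=lambda s: (s.kind, s.atom_indices))
    return sites


def _acceptor_direction(mol: Chem.Mol, idx: int, coords: np.ndarray) -> np.ndarray | None:
    """Lone-pair-ish projection: away from the mean of heavy neighbours."""
    nbrs = [n.GetIdx() for n in mol.GetAtomWithIdx(idx).GetNeighbors() if n.GetAtomicNum() > 1]
    if not nbrs:
        return None
    v = coords[idx] - coords[nbrs].mean(axis=0)
    norm = np.linalg.norm(v)
    return None if norm < 1e-9 else v / norm


def _connected_groups(mol: Chem.Mol, atoms: set[int]) -> list[set[int]]:
    remaining = set(atoms)
    groups = []
    while remaining:
        seed = min(remaining)
        group = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for nbr in mol.GetAtomWithIdx(cur).GetNeighbors():
                j = nbr.GetIdx()
                if j in remaining and j not in group:
                    group.add(j)
                    frontier.append(j)
        remaining -= group
        groups.append(group)
    return groups


def sites_for_ensemble(record, ensemble: ConformerEnsemble) -> list[list[FeatureSite]]:
    """Feature sites per conformer (stored sites for point-set records)."""
    if record.sites is not None:
        return [record.sites for _ in range(len(ensemble))]
    if record.mol is None:
        raise ValueError(f"{record.id}: no structure for feature perception")
    mol = Chem.AddHs(Chem.Mol(record.mol))
    out = []
    for coords in ensemble.coords:
        if len(coords) == mol.GetNumAtoms():
            out.append(perceive_features(mol, coords))
        elif len(coords) == record.mol.GetNumAtoms():
            out.append(perceive_features(record.mol, coords))
        else:
            raise ValueError(f"{record.id}: conformer/atom count mismatch")
    return out


# ---------------------------------------------------------------------------
# Common-hypothesis search


@dataclass(frozen=True)
class _Variant:
    mol_index: int
    conformer_index: int
    site_indices: tuple[int, ...]  # canonical (kind-sorted) order
    dvec: tuple[float, ...]  # condensed inter-site distances


def _canonical_variant(sites: list[FeatureSite], combo: tuple[int, ...]):
    """Kind-sorted site order; equal-kind ties resolved to the
    lexicographically smallest distance vector."""
    by_kind = sorted(combo, key=lambda i: (sites[i].kind, i))
    kinds = [sites[i].kind for i in by_kind]
    # group equal kinds; enumerate permutations within groups only
    groups: list[list[int]] = []
    for i, idx in enumerate(by_kind):
        if i and kinds[i] == kinds[i - 1]:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    best = None
    for perm_parts in itertools.product(*[itertools.permutations(g) for g in groups]):
        order = tuple(itertools.chain.from_iterable(perm_parts))
        pos = np.array([sites[i].position for i in order])
        dvec = tuple(
            float(np.linalg.norm(pos[i] - pos[j]))
            for i in range(len(order))
            for j in range(i + 1, len(order))
        )
        if best is None or dvec < best[1]:
            best = (order, dvec)
    assert best is not None
    return "".join(kinds), best[0], best[1]


def _leaf_cells(dvecs: np.ndarray, bin_size: float):
    """Uniform leaf-cell geometry of the bisection tree.

    Each dimension's extent is halved until the edge is <= bin_size; leaves
    are the resulting uniform grid cells.  Returns per-variant integer cell
    coordinates plus (lo, n_cells) describing the grid.
    """
    lo = dvecs.min(axis=0)
    hi = dvecs.max(axis=0)
    extent = hi - lo
    n_cells = np.ones(dvecs.shape[1], dtype=int)
    for d in range(dvecs.shape[1]):
        if extent[d] > bin_size:
            n_cells[d] = 2 ** int(math.ceil(math.log2(extent[d] / bin_size)))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(extent > 0, (dvecs - lo) / np.where(extent > 0, extent, 1.0), 0.0)
    cells = np.minimum((frac * n_cells).astype(int), n_cells - 1)
    return cells, lo, n_cells


def find_common_hypotheses(
    ensembles: list[ConformerEnsemble],
    sites_per_ensemble: list[list[list[FeatureSite]]],
    n_features: int = 5,
    must_match: float = 0.9,
    bin_size: float = DEFAULT_BIN_SIZE,
    site_tolerance: float = DEFAULT_SITE_TOLERANCE,
    score: bool = True,
    score_kwargs: dict | None = None,
    match_filter: bool = True,
    box_coverage: float | None = None,
) -> list[PharmacophoreHypothesis]:
    """Find k-feature hypotheses common to >= must_match of the ligands.

    A hypothesis is seeded from every leaf box holding variants from at
    least a ``box_coverage`` fraction of the ligands (default: the
    ``must_match`` fraction); with ``match_filter`` each emitted hypothesis
    must additionally be fully matched (all k sites, at
    ``site_tolerance``) by a ``must_match`` fraction of the ligands.
    Decoupling the two lets sparse inputs (one conformer per ligand, whose
    jittered variants scatter across adjacent boxes) still seed the
    consensus geometry, while the emission guarantee stays at full
    strength.

    ``bin_size`` should exceed the inter-site distance scatter of the
    inputs: with one conformer per rigid ligand the distances of the
    common arrangement spread by ~2*sqrt(2)*sigma for site jitter sigma,
    whereas densely sampled conformer ensembles populate boxes at the
    default 1 A edge.

    Deterministic given fixed input ordering.  Returns hypotheses ranked by
    :func:`score_hypothesis` (or by coverage and box tightness when
    ``score`` is off).
    """
    if len(ensembles) < 2:
        raise ValueError("need at least two ligand ensembles")
    if n_features < 3:
        raise ValueError("n_features must be >= 3")
    if not 0 < must_match <= 1:
        raise ValueError("must_match must be in (0, 1]")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")

    n_mols = len(ensembles)
    if box_coverage is None:
        box_coverage = must_match
    if not 0 < box_coverage <= 1:
        raise ValueError("box_coverage must be in (0, 1]")
    threshold = math.ceil(must_match * n_mols - 1e-9)
    box_threshold = math.ceil(box_coverage * n_mols - 1e-9)

    variants_by_label: dict[str, list[_Variant]] = {}
    any_enough_sites = False
    for m, conf_sites in enumerate(sites_per_ensemble):
        for c, sites in enumerate(conf_sites):
            if len(sites) < n_features:
                continue
            any_enough_sites = True
            for combo in itertools.combinations(range(len(sites)), n_features):
                label, order, dvec = _canonical_variant(sites, combo)
                variants_by_label.setdefault(label, []).append(
                    _Variant(m, c, order, dvec)
                )
    if not any_enough_sites:
        logger.warning("no ligand has %d feature sites; no hypotheses", n_features)
        return []

    raw: list[tuple[str, tuple[int, ...], list[_Variant]]] = []
    for label in sorted(variants_by_label):
        variants = variants_by_label[label]
        if len({v.mol_index for v in variants}) < box_threshold:
            continue
        dvecs = np.array([v.dvec for v in variants])
        cells, _, n_cells = _leaf_cells(dvecs, bin_size)
        for cell_key, members in _partition_tree(variants, cells, n_cells, box_threshold):
            raw.append((label, cell_key, members))

    # one hypothesis per surviving leaf; medoid variant gives the geometry
    seen_medoids: set = set()
    emitted = []
    for label, cell_key, members in raw:
        medoid = _medoid(members, ensembles)
        key = (medoid.mol_index, medoid.conformer_index, medoid.site_indices)
        if key in seen_medoids:
            continue
        seen_medoids.add(key)
        sites = sites_per_ensemble[medoid.mol_index][medoid.conformer_index]
        chosen = [sites[i] for i in medoid.site_indices]
        centroid = np.mean([s.position for s in chosen], axis=0)
        hyp_sites = [
            FeatureSite(
                kind=s.kind,
                position=s.position - centroid,
                direction=None if s.direction is None else s.direction.copy(),
                atom_indices=s.atom_indices,
            )
            for s in chosen
        ]
        emitted.append(
            (
                label,
                cell_key,
                members,
                PharmacophoreHypothesis(
                    id=f"{label}.0",  # renumbered after ranking
                    sites=hyp_sites,
                    site_tolerance=site_tolerance,
                    provenance={
                        "label": label,
                        "cell": list(cell_key),
                        "medoid": [
                            ensembles[medoid.mol_index].molecule_id,
                            medoid.conformer_index,
                            list(medoid.site_indices),
                        ],
                        "n_molecules": len({v.mol_index for v in members}),
                        "bin_size": bin_size,
                        "must_match": must_match,
                        "box_coverage": box_coverage,
                    },
                ),
            )
        )

    if match_filter:
        kept = []
        for label, cell_key, members, hyp in emitted:
            n_matched = 0
            for remaining, (ens, conf_sites) in enumerate(zip(ensembles, sites_per_ensemble)):
                if n_matched + (n_mols - remaining) < threshold:
                    break  # cannot reach the threshold any more
                if match_ligand(hyp, ens, conf_sites, min_sites=hyp.k) is not None:
                    n_matched += 1
            if n_matched >= threshold:
                hyp.provenance["n_matched_ligands"] = n_matched
                kept.append((label, cell_key, members, hyp))
        emitted = kept

    score_kwargs = dict(score_kwargs or {})
    ranked = []
    for label, cell_key, members, hyp in emitted:
        if score:
            try:
                hyp.score = score_hypothesis(hyp, ensembles, sites_per_ensemble, **score_kwargs)
            except ValueError:
                hyp.score = float("-inf")
        else:
            spread = float(np.mean(np.std([v.dvec for v in members], axis=0)))
            hyp.score = hyp.provenance["n_molecules"] - spread
        ranked.append(hyp)
    ranked.sort(key=lambda h: (-h.score, h.label, tuple(h.provenance["cell"])))
    for i, hyp in enumerate(ranked, start=1):
        hyp.id = f"{hyp.label}.{i}"
    return ranked


def _partition_tree(variants, cells: np.ndarray, n_cells: np.ndarray, threshold: int):
    """Recursive bisection with coverage pruning; yields surviving leaves.

    Boxes are integer cell ranges; a box whose variants span fewer than
    ``threshold`` distinct molecules cannot improve by refinement and is
    dropped.  Leaves (all ranges of size 1) are yielded with their members.
    """
    n_dim = cells.shape[1]

    def recurse(idx: np.ndarray, lo: np.ndarray, hi: np.ndarray):
        if len({variants[i].mol_index for i in idx}) < threshold:
            return
        split_dim = -1
        for d in range(n_dim):
            if hi[d] - lo[d] > 1:
                split_dim = d
                break
        if split_dim < 0:
            yield tuple(int(v) for v in lo), [variants[i] for i in idx]
            return
        mid = (lo[split_dim] + hi[split_dim]) // 2
        mask = cells[idx, split_dim] < mid
        for sub, new_lo, new_hi in (
            (idx[mask], lo, _replace(hi, split_dim, mid)),
            (idx[~mask], _replace(lo, split_dim, mid), hi),
        ):
            if len(sub):
                yield from recurse(sub, new_lo, new_hi)

    idx0 = np.arange(len(variants))
    lo0 = np.zeros(n_dim, dtype=int)
    yield from recurse(idx0, lo0, n_cells.copy())


def _replace(arr: np.ndarray, d: int, value: int) -> np.ndarray:
    out = arr.copy()
    out[d] = value
    return out


def _medoid(members: list[_Variant], ensembles) -> _Variant:
    dvecs = np.array([v.dvec for v in members])
    dist = np.sqrt(((dvecs[:, None, :] - dvecs[None, :, :]) ** 2).sum(-1))
    totals = dist.sum(axis=1)
    best = min(
        range(len(members)),
        key=lambda i: (
            totals[i],
            members[i].mol_index,
            members[i].conformer_index,
            members[i].site_indices,
        ),
    )
    return members[best]


# ---------------------------------------------------------------------------
# Matching and alignment


def match_ligand(
    hypothesis: PharmacophoreHypothesis,
    ensemble: ConformerEnsemble,
    sites_per_conformer: list[list[FeatureSite]],
    min_sites: int = 4,
    tolerance: np.ndarray | float | None = None,
) -> HypothesisMatch | None:
    """Best partial match of a ligand onto a hypothesis, or None.

    Over all conformers and kind-consistent correspondences of size >=
    ``min_sites``: feasible when every matched site pair lies within the
    hypothesis site's tolerance after optimal superposition.  Best =
    maximal n_matched, then minimal RMSD, then lowest conformer energy.
    """
    k = hypothesis.k
    if not 3 <= min_sites <= k:
        raise ValueError(f"min_sites must be in [3, {k}]")
    tol = hypothesis.site_tolerance if tolerance is None else np.broadcast_to(
        np.asarray(tolerance, dtype=float), (k,)
    )
    hyp_pos = hypothesis.positions
    hyp_kinds = [s.kind for s in hypothesis.sites]

    for m in range(k, min_sites - 1, -1):
        best: tuple | None = None
        for conf_i, sites in enumerate(sites_per_conformer):
            lig_by_kind: dict[str, list[int]] = {}
            for j, s in enumerate(sites):
                lig_by_kind.setdefault(s.kind, []).append(j)
            for subset in itertools.combinations(range(k), m):
                for assignment in _kind_assignments(
                    [hyp_kinds[i] for i in subset], lig_by_kind
                ):
                    lig_pts = np.array([sites[j].position for j in assignment])
                    hyp_pts = hyp_pos[list(subset)]
                    t = kabsch(lig_pts, hyp_pts)
                    moved = t.apply(lig_pts)
                    dev = np.linalg.norm(moved - hyp_pts, axis=1)
                    if np.any(dev > tol[list(subset)]):
                        continue
                    r = float(np.sqrt(np.mean(dev**2)))
                    energy = float(ensemble.rel_energies[conf_i])
                    corr = tuple(zip(subset, assignment))
                    cand = (r, energy, conf_i, corr)
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            r, _, conf_i, corr = best
            return HypothesisMatch(
                molecule_id=ensemble.molecule_id,
                conformer_index=conf_i,
                correspondence=corr,
                n_matched=m,
                match_rmsd=r,
            )
    return None


def _kind_assignments(wanted_kinds: list[str], lig_by_kind: dict[str, list[int]]):
    """Injective assignments of ligand sites to the wanted kind sequence."""
    groups: dict[str, list[int]] = {}
    for pos, kind in enumerate(wanted_kinds):
        groups.setdefault(kind, []).append(pos)
    per_kind_choices = []
    for kind, positions in groups.items():
        avail = lig_by_kind.get(kind, [])
        if len(avail) < len(positions):
            return
        per_kind_choices.append(
            (positions, list(itertools.permutations(avail, len(positions))))
        )
    for combo in itertools.product(*[c for _, c in per_kind_choices]):
        assignment = [0] * len(wanted_kinds)
        for (positions, _), chosen in zip(per_kind_choices, combo):
            for pos, lig_idx in zip(positions, chosen):
                assignment[pos] = lig_idx
        yield tuple(assignment)


def align_ligand(
    hypothesis: PharmacophoreHypothesis,
    match: HypothesisMatch,
    ensemble: ConformerEnsemble,
    sites_per_conformer: list[list[FeatureSite]],
) -> AlignedLigand:
    """Rigidly superpose the matched conformer into the hypothesis frame."""
    if match.n_matched < 3:
        raise ValueError("need >= 3 matched sites for a rigid alignment")
    sites = sites_per_conformer[match.conformer_index]
    lig_pts = np.array([sites[j].position for _, j in match.correspondence])
    hyp_pts = hypothesis.positions[[i for i, _ in match.correspondence]]
    centered = lig_pts - lig_pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise DegenerateSitesError(
            f"{match.molecule_id}: matched sites are collinear; manual tolerance needed"
        )
    t = kabsch(lig_pts, hyp_pts)
    moved = t.apply(lig_pts)
    r = float(np.sqrt(np.mean(np.sum((moved - hyp_pts) ** 2, axis=1))))
    coords = t.apply(ensemble.coords[match.conformer_index])
    return AlignedLigand(
        molecule_id=match.molecule_id,
        conformer_index=match.conformer_index,
        transform=t,
        coordinates_aligned=coords,
        match=HypothesisMatch(
            molecule_id=match.molecule_id,
            conformer_index=match.conformer_index,
            correspondence=match.correspondence,
            n_matched=match.n_matched,
            match_rmsd=r,
        ),
    )


# ---------------------------------------------------------------------------
# Hypothesis scoring


def score_hypothesis(
    hypothesis: PharmacophoreHypothesis,
    ensembles: list[ConformerEnsemble],
    sites_per_ensemble: list[list[list[FeatureSite]]],
    w_align: float = 1.0,
    w_vec: float = 1.0,
    w_vol: float = 1.0,
    rmsd_norm: float = 1.2,
    max_overlap_mols: int = 10,
) -> float:
    """Surrogate hypothesis score; higher is better.

    score = w_align * (1 - mean match RMSD / rmsd_norm)
          + w_vec * mean direction cosine over matched A/R sites
          + w_vol * mean pairwise Gaussian volume-overlap Tanimoto of the
            aligned ligands (first ``max_overlap_mols`` ligands).
    """
    matches = []
    aligned = []
    for ens, conf_sites in zip(ensembles, sites_per_ensemble):
        m = match_ligand(hypothesis, ens, conf_sites, min_sites=hypothesis.k)
        if m is None:
            continue
        matches.append((m, conf_sites))
        try:
            aligned.append(align_ligand(hypothesis, m, ens, conf_sites))
        except DegenerateSitesError:
            continue
    if not matches:
        raise ValueError("no ligand matches the hypothesis")

    align_term = 1.0 - float(np.mean([m.match_rmsd for m, _ in matches])) / rmsd_norm

    cosines = []
    for m, conf_sites in matches:
        sites = conf_sites[m.conformer_index]
        al = next((a for a in aligned if a.molecule_id == m.molecule_id), None)
        rot = np.eye(3) if al is None else al.transform.rotation
        for hyp_i, lig_j in m.correspondence:
            hs = hypothesis.sites[hyp_i]
            ls = sites[lig_j]
            if hs.kind not in ("A", "R") or hs.direction is None or ls.direction is None:
                continue
            c = float(np.dot(rot @ ls.direction, hs.direction))
            cosines.append(abs(c) if hs.kind == "R" else c)
    vec_term = float(np.mean(cosines)) if cosines else 0.0

    vol_term = 0.0
    subset = aligned[:max_overlap_mols]
    if len(subset) >= 2:
        overlaps = []
        for a, b in itertools.combinations(subset, 2):
            overlaps.append(_gaussian_overlap_tanimoto(a.coordinates_aligned, b.coordinates_aligned))
        vol_term = float(np.mean(overlaps))
    elif len(subset) == 1:
        vol_term = 1.0

    return w_align * align_term + w_vec * vec_term + w_vol * vol_term


def _gaussian_overlap_tanimoto(a: np.ndarray, b: np.ndarray, sigma: float = 1.0) -> float:
    def overlap(p, q):
        d2 = np.sum((p[:, None, :] - q[None, :, :]) ** 2, axis=-1)
        return float(np.exp(-d2 / (2.0 * sigma**2)).sum())

    oab = overlap(a, b)
    return oab / (overlap(a, a) + overlap(b, b) - oab)
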