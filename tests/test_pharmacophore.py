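"""Feature perception, common-hypothesis search, matching and alignment."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from phore3d.conformers import ConformerEnsemble
from phore3d.pharmacophore import (
    DegenerateSitesError,
    FeatureSite,
    PharmacophoreHypothesis,
    align_ligand,
    find_common_hypotheses,
    hypothesis_label,
    load_feature_definitions,
    match_ligand,
    perceive_features,
    score_hypothesis,
)
from phore3d.synthdata import plant_hypothesis


# ---------------------------------------------------------------------------
# helpers


def _point_molecule(mol_id: str, site_list: list[FeatureSite]) -> ConformerEnsemble:
    coords = np.array([s.position for s in site_list])
    return ConformerEnsemble(
        molecule_id=mol_id,
        coords=[coords],
        rel_energies=np.array([0.0]),
        heavy_idx=np.arange(len(site_list)),
    )


def _sites(kinds: str, coords, rng=None) -> list[FeatureSite]:
    out = []
    for kind, xyz in zip(kinds, coords):
        direction = None
        if kind in ("A", "R"):
            v = np.array([0.0, 0.0, 1.0]) if rng is None else rng.normal(size=3)
            direction = v / np.linalg.norm(v)
        out.append(FeatureSite(kind=kind, position=np.asarray(xyz, float), direction=direction))
    return out


# ---------------------------------------------------------------------------
# perception


class TestPerception:
    def test_benzene_single_ring_site(self, benzene):
        sites = perceive_features(benzene)
        rings = [s for s in sites if s.kind == "R"]
        assert len(rings) == 1
        heavy = np.array(
            [benzene.GetConformer().GetAtomPosition(a.GetIdx()) for a in benzene.GetAtoms() if a.GetAtomicNum() > 1]
        )
        np.testing.assert_allclose(rings[0].position, heavy.mean(axis=0), atol=1e-6)
        assert np.linalg.norm(rings[0].direction) == pytest.approx(1.0, abs=1e-6)
        assert [s.kind for s in sites] == ["R"]  # aromatic C is not a hydrophobe site

    def test_methylammonium_positive_and_donor(self, methylammonium):
        sites = perceive_features(methylammonium)
        kinds = [s.kind for s in sites]
        assert kinds.count("P") == 1
        assert kinds.count("D") >= 1
        assert "A" not in kinds

    def test_acetone_single_acceptor(self, acetone):
        sites = perceive_features(acetone)
        acceptors = [s for s in sites if s.kind == "A"]
        assert len(acceptors) == 1
        # oracle: apply the shipped SMARTS table by hand
        defs = load_feature_definitions()
        matched = set()
        for smarts, _ in defs["acceptor"]:
            for m in acetone.GetSubstructMatches(Chem.MolFromSmarts(smarts)):
                matched.add(m[0])
        assert matched == {acceptors[0].atom_indices[0]}
        carbonyl_o = next(
            a.GetIdx() for a in acetone.GetAtoms() if a.GetSymbol() == "O"
        )
        assert acceptors[0].atom_indices == (carbonyl_o,)
        assert acceptors[0].direction is not None

    def test_missing_coordinates_rejected(self):
        with pytest.raises(ValueError):
            perceive_features(Chem.MolFromSmiles("CCO"))

    def test_real_family_motif(self):
        """The benzylpiperidine family shows the P + two-ring hERG motif."""
        from phore3d.conformers import generate_ensemble
        from phore3d.pharmacophore import sites_for_ensemble
        from phore3d.synthdata import real_family

        record = real_family()[0]
        ens = generate_ensemble(record, max_confs=5, seed=3)
        sites = sites_for_ensemble(record, ens)[0]
        kinds = [s.kind for s in sites]
        assert kinds.count("P") == 1
        assert kinds.count("R") == 2
        assert kinds.count("H") >= 1


class TestLabel:
    def test_label_from_kind_multiset(self):
        assert hypothesis_label(["R", "P", "A", "R", "H"]) == "AHPRR"
        assert plant_hypothesis(3).label == "AHPRR"


# ---------------------------------------------------------------------------
# brute-force oracle for the hypothesis search


def _oracle_common_hypotheses(ensembles, sites_per_ensemble, k, must_match, bin_size, tolerance=2.0):
    """Independent enumeration: all k-subsets, all orderings, direct
    floor-hash binning into uniform leaf cells, medoid by O(n^2) sums."""
    n_mols = len(ensembles)
    threshold = math.ceil(must_match * n_mols - 1e-9)
    variants = {}
    for m, conf_sites in enumerate(sites_per_ensemble):
        for c, sites in enumerate(conf_sites):
            for combo in itertools.combinations(range(len(sites)), k):
                best = None
                for perm in itertools.permutations(combo):
                    kinds = [sites[i].kind for i in perm]
                    if kinds != sorted(kinds):
                        continue
                    pos = np.array([sites[i].position for i in perm])
                    dvec = tuple(
                        float(np.linalg.norm(pos[i] - pos[j]))
                        for i in range(k)
                        for j in range(i + 1, k)
                    )
                    key = (perm, dvec)
                    if best is None or dvec < best[1]:
                        best = key
                if best is None:
                    continue
                label = "".join(sorted(sites[i].kind for i in combo))
                variants.setdefault(label, []).append((m, c, best[0], np.array(best[1])))
    out = set()
    for label, var in variants.items():
        dvecs = np.array([v[3] for v in var])
        lo = dvecs.min(axis=0)
        extent = dvecs.max(axis=0) - lo
        n_cells = np.array(
            [
                2 ** math.ceil(math.log2(e / bin_size)) if e > bin_size else 1
                for e in extent
            ]
        )
        frac = np.where(extent > 0, (dvecs - lo) / np.where(extent > 0, extent, 1), 0.0)
        cells = np.minimum((frac * n_cells).astype(int), n_cells - 1)
        seen_cells = {}
        for i, cell in enumerate(map(tuple, cells)):
            seen_cells.setdefault(cell, []).append(i)
        for cell, idx in seen_cells.items():
            mols = {var[i][0] for i in idx}
            if len(mols) < threshold:
                continue
            sub = dvecs[idx]
            totals = np.sqrt(((sub[:, None] - sub[None, :]) ** 2).sum(-1)).sum(1)
            best_i = min(
                range(len(idx)),
                key=lambda j: (totals[j], var[idx[j]][0], var[idx[j]][1], var[idx[j]][2]),
            )
            m, c, perm, _ = var[idx[best_i]]
            # same match-based emission requirement as the implementation
            chosen = [sites_per_ensemble[m][c][i] for i in perm]
            centroid = np.mean([s.position for s in chosen], axis=0)
            hyp = PharmacophoreHypothesis(
                id="oracle",
                sites=[
                    FeatureSite(kind=s.kind, position=s.position - centroid, direction=s.direction)
                    for s in chosen
                ],
                site_tolerance=tolerance,
            )
            n_matched = sum(
                match_ligand(hyp, e, s, min_sites=k) is not None
                for e, s in zip(ensembles, sites_per_ensemble)
            )
            if n_matched < threshold:
                continue
            out.add((label, cell, ensembles[m].molecule_id, c, perm))
    return out


def _random_instance(seed: int):
    rng = np.random.default_rng(seed)
    n_mols = int(rng.integers(2, 5))
    ensembles, sites_per = [], []
    for m in range(n_mols):
        n_confs = int(rng.integers(1, 4))
        conf_sites = []
        for _ in range(n_confs):
            n_sites = int(rng.integers(3, 7))
            kinds = rng.choice(list("AHR"), size=n_sites)
            coords = rng.uniform(-5, 5, size=(n_sites, 3))
            conf_sites.append(_sites("".join(kinds), coords, rng))
        sites_per.append(conf_sites)
        coords0 = np.array([s.position for s in conf_sites[0]])
        ensembles.append(
            ConformerEnsemble(
                molecule_id=f"m{m}",
                coords=[np.array([s.position for s in cs]) for cs in conf_sites],
                rel_energies=np.arange(n_confs, dtype=float),
                heavy_idx=np.arange(len(conf_sites[0])),
            )
        )
    return ensembles, sites_per


class TestHypothesisSearch:
    def test_identical_molecules_zero_spread(self):
        rng = np.random.default_rng(0)
        sites = _sites("ADR", rng.uniform(-4, 4, (3, 3)), rng)
        ens = [_point_molecule("a", sites), _point_molecule("b", sites)]
        hyps = find_common_hypotheses(
            ens, [[sites], [sites]], n_features=3, must_match=1.0, bin_size=1.0, score=False
        )
        assert len(hyps) == 1
        assert hyps[0].provenance["n_molecules"] == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_bruteforce_enumeration(self, seed):
        """Tree-partition output equals direct exhaustive grid binning."""
        ensembles, sites_per = _random_instance(seed)
        got = find_common_hypotheses(
            ensembles, sites_per, n_features=3, must_match=0.5, bin_size=1.5, score=False
        )
        got_keys = {
            (
                h.provenance["label"],
                tuple(h.provenance["cell"]),
                h.provenance["medoid"][0],
                h.provenance["medoid"][1],
                tuple(h.provenance["medoid"][2]),
            )
            for h in got
        }
        want = _oracle_common_hypotheses(ensembles, sites_per, 3, 0.5, 1.5)
        assert got_keys == want

    def test_planted_family_recovered(self):
        """Five rigid molecules sharing an AHPRR geometry + one distractor."""
        rng = np.random.default_rng(42)
        planted = plant_hypothesis(7)
        ens, sites_per = [], []
        for m in range(5):
            sites = [
                FeatureSite(kind=s.kind, position=s.position, direction=s.direction)
                for s in planted.sites
            ]
            sites.append(
                FeatureSite(kind="D", position=rng.uniform(8, 12, size=3))
            )
            ens.append(_point_molecule(f"m{m}", sites))
            sites_per.append([sites])
        hyps = find_common_hypotheses(
            ens, sites_per, n_features=5, must_match=0.9, bin_size=1.0
        )
        assert hyps
        top = hyps[0]
        assert top.label == "AHPRR"
        tri = np.triu_indices(5, 1)
        np.testing.assert_allclose(
            np.sort(top.distance_matrix[tri]),
            np.sort(planted.distance_matrix[tri]),
            atol=1.0,
        )
        # coverage invariant: every emitted hypothesis fully matched by >= 90%
        for h in hyps:
            n = sum(
                match_ligand(h, e, s, min_sites=5) is not None
                for e, s in zip(ens, sites_per)
            )
            assert n >= math.ceil(0.9 * len(ens))

    def test_no_molecule_with_enough_sites(self):
        rng = np.random.default_rng(1)
        sites = _sites("AR", rng.uniform(-3, 3, (2, 3)), rng)
        out = find_common_hypotheses(
            [_point_molecule("a", sites), _point_molecule("b", sites)],
            [[sites], [sites]],
            n_features=5,
        )
        assert out == []

    def test_bad_must_match(self):
        rng = np.random.default_rng(2)
        sites = _sites("AHR", rng.uniform(-3, 3, (3, 3)), rng)
        ens = [_point_molecule("a", sites), _point_molecule("b", sites)]
        with pytest.raises(ValueError):
            find_common_hypotheses(ens, [[sites], [sites]], 3, must_match=1.5)


# ---------------------------------------------------------------------------
# scoring


class TestScore:
    def _perfect_setup(self):
        rng = np.random.default_rng(5)
        sites = _sites("AHPRR", rng.uniform(-4, 4, (5, 3)), rng)
        hyp = PharmacophoreHypothesis(id="AHPRR.t", sites=sites)
        ens = [_point_molecule(f"m{i}", sites) for i in range(3)]
        return hyp, ens, [[sites]] * 3

    def test_perfect_case_sums_weights(self):
        hyp, ens, sp = self._perfect_setup()
        s = score_hypothesis(hyp, ens, sp, w_align=1.0, w_vec=1.0, w_vol=1.0)
        assert s == pytest.approx(3.0, abs=1e-9)

    def test_alignment_term_linear_in_weight(self):
        hyp, ens, sp = self._perfect_setup()
        s0 = score_hypothesis(hyp, ens, sp, w_align=0.0)
        s1 = score_hypothesis(hyp, ens, sp, w_align=1.0)
        s2 = score_hypothesis(hyp, ens, sp, w_align=2.0)
        assert s2 - s0 == pytest.approx(2 * (s1 - s0), abs=1e-12)

    def test_jitter_lowers_score_in_expectation(self):
        rng0 = np.random.default_rng(6)
        sites = _sites("AHPRR", rng0.uniform(-4, 4, (5, 3)), rng0)
        hyp = PharmacophoreHypothesis(id="AHPRR.j", sites=sites)
        clean = score_hypothesis(hyp, *_copies(sites, 3))
        noisy = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            ens, sp = _copies(sites, 3, jitter=0.3, rng=rng)
            noisy.append(score_hypothesis(hyp, ens, sp))
        assert np.mean(noisy) < clean

    def test_no_matching_ligand_is_error(self):
        hyp, _, _ = self._perfect_setup()
        rng = np.random.default_rng(8)
        other = _sites("DDD", rng.uniform(-3, 3, (3, 3)))
        with pytest.raises(ValueError):
            score_hypothesis(hyp, [_point_molecule("x", other)], [[other]])


def _copies(sites, n, jitter=0.0, rng=None):
    ens, sp = [], []
    for i in range(n):
        if jitter and rng is not None:
            moved = [
                FeatureSite(
                    kind=s.kind,
                    position=s.position + rng.normal(0, jitter, 3),
                    direction=s.direction,
                )
                for s in sites
            ]
        else:
            moved = sites
        ens.append(_point_molecule(f"c{i}", moved))
        sp.append([moved])
    return ens, sp


# ---------------------------------------------------------------------------
# matching


class TestMatch:
    def setup_method(self):
        self.hyp = plant_hypothesis(1)
        self.sites = [
            FeatureSite(kind=s.kind, position=s.position, direction=s.direction)
            for s in self.hyp.sites
        ]

    def test_self_match_is_exact(self):
        ens = _point_molecule("self", self.sites)
        m = match_ligand(self.hyp, ens, [self.sites], min_sites=5)
        assert m is not None
        assert m.n_matched == 5
        assert m.match_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_missing_mandatory_kind_no_match(self):
        no_p = [s for s in self.sites if s.kind != "P"]
        ens = _point_molecule("nop", no_p)
        assert match_ligand(self.hyp, ens, [no_p], min_sites=5) is None

    def test_four_of_five_partial_match(self):
        """Ligand lacking one planted site matches 4 sites with the
        planted correspondence (verified by exhaustive enumeration)."""
        rng = np.random.default_rng(3)
        partial = [s for i, s in enumerate(self.sites) if i != 1]  # drop the H site
        rot = Rotation.random(random_state=4).as_matrix()
        moved = [
            FeatureSite(
                kind=s.kind,
                position=rot @ s.position + np.array([5.0, 1.0, -2.0]),
                direction=None if s.direction is None else rot @ s.direction,
            )
            for s in partial
        ]
        ens = _point_molecule("part", moved)
        m = match_ligand(self.hyp, ens, [moved], min_sites=4)
        assert m is not None and m.n_matched == 4
        assert m.match_rmsd == pytest.approx(0.0, abs=1e-8)
        # planted correspondence: hypothesis sites {0,2,3,4} -> ligand 0..3
        assert dict(m.correspondence) == {0: 0, 2: 1, 3: 2, 4: 3}

    def test_min_sites_bounds(self):
        ens = _point_molecule("self", self.sites)
        with pytest.raises(ValueError):
            match_ligand(self.hyp, ens, [self.sites], min_sites=2)
        with pytest.raises(ValueError):
            match_ligand(self.hyp, ens, [self.sites], min_sites=6)


# ---------------------------------------------------------------------------
# alignment


class TestAlign:
    def _match(self, hyp, sites):
        ens = _point_molecule("m", sites)
        return match_ligand(hyp, ens, [sites], min_sites=hyp.k), ens

    def test_coincident_identity(self):
        hyp = plant_hypothesis(2)
        sites = [FeatureSite(s.kind, s.position.copy(), s.direction) for s in hyp.sites]
        m, ens = self._match(hyp, sites)
        al = align_ligand(hyp, m, ens, [sites])
        np.testing.assert_allclose(al.transform.rotation, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(al.transform.translation, 0.0, atol=1e-8)
        assert al.match.match_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_known_rotation_recovered(self):
        hyp = plant_hypothesis(2)
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        shift = np.array([1.0, -3.0, 2.0])
        sites = [
            FeatureSite(s.kind, rot @ s.position + shift,
                        None if s.direction is None else rot @ s.direction)
            for s in hyp.sites
        ]
        m, ens = self._match(hyp, sites)
        al = align_ligand(hyp, m, ens, [sites])
        assert al.match.match_rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(al.transform.rotation @ rot, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(
            al.coordinates_aligned, hyp.positions, atol=1e-6
        )

    def test_noisy_rmsd_matches_reference(self):
        """RMSD equals scipy's independent closed-form superposition."""
        hyp = plant_hypothesis(3)
        rng = np.random.default_rng(9)
        sites = [
            FeatureSite(s.kind, s.position + rng.normal(0, 0.4, 3), s.direction)
            for s in hyp.sites
        ]
        m, ens = self._match(hyp, sites)
        al = align_ligand(hyp, m, ens, [sites])
        lig = np.array([sites[j].position for _, j in m.correspondence])
        ref = hyp.positions[[i for i, _ in m.correspondence]]
        _, rssd = Rotation.align_vectors(ref - ref.mean(0), lig - lig.mean(0))
        assert al.match.match_rmsd == pytest.approx(rssd / np.sqrt(len(lig)), abs=1e-9)

    def test_rigid_pretransform_invariance(self):
        hyp = plant_hypothesis(4)
        rng = np.random.default_rng(10)
        base = [
            FeatureSite(s.kind, s.position + rng.normal(0, 0.3, 3), s.direction)
            for s in hyp.sites
        ]
        m0, ens0 = self._match(hyp, base)
        r0 = align_ligand(hyp, m0, ens0, [base]).match.match_rmsd
        rot = Rotation.random(random_state=11).as_matrix()
        moved = [
            FeatureSite(s.kind, rot @ s.position + 7.0,
                        None if s.direction is None else rot @ s.direction)
            for s in base
        ]
        m1, ens1 = self._match(hyp, moved)
        r1 = align_ligand(hyp, m1, ens1, [moved]).match.match_rmsd
        assert r1 == pytest.approx(r0, abs=1e-8)

    def test_collinear_sites_rejected(self):
        sites = _sites("AHP", [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        hyp = PharmacophoreHypothesis(id="AHP.line", sites=sites)
        ens = _point_molecule("line", sites)
        m = match_ligand(hyp, ens, [sites], min_sites=3)
        with pytest.raises(DegenerateSitesError):
            align_ligand(hyp, m, ens, [sites])
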