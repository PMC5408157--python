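# Methods

This note records the models, parameter choices and numerical conventions
behind `phore3d`, and what the synthetic benchmark does and does not show
about real data.

## Affinities and activity classes

Binding affinities are stored in molar units internally and in nanomolar in
files (`Ki_nM` SDF property / `ki_nM` CSV column). The regression response
is pKi = −log₁₀ Ki[M]. Activity classes follow the hERG displacement-assay
convention: potent Ki ≤ 50 nM, moderate 50 nM < Ki < 5 µM, inactive
Ki ≥ 5 µM. The 50 nM boundary is inclusive to *potent* and the 5 µM
boundary goes to *inactive*; ties at a toxicity threshold are resolved
toward the risk-flagging class. Train/test splitting is a seeded uniform
permutation with |train| = round(f·n) (default f = 0.6, seed 42, recorded
in outputs); an optional stratified mode splits within activity classes.

## Conformer ensembles

Downstream stages depend only on the retention contract: every kept
conformer lies within 21 kJ/mol of the ensemble minimum, and every pair of
kept conformers differs by ≥ 0.5 Å heavy-atom RMSD after optimal rigid
superposition. Retention is greedy in ascending energy order, which is
idempotent and makes "keep the lowest-energy representative of each
geometric cluster" the operative semantics. Raw conformers come from
RDKit's ETKDGv3 distance-geometry embedder followed by MMFF94 minimisation
(energies converted to kJ/mol); the engine name/version and seed are
recorded in ensemble metadata. Hydrogens are excluded from the redundancy
RMSD. Default cap: 200 embeddings per molecule. No Boltzmann weighting and
no solvation model — the ensemble is a geometric cover, not a thermodynamic
average.

## Feature perception

The six feature kinds (A, D, H, N, P, R) are perceived from an editable
YAML rule table shipped with the package (`data/features.yaml`): per-atom
SMARTS for acceptors, donors and the ionizable kinds; hydrophobic atoms
clustered into connected groups with one site per group centroid; one site
per aromatic ring at its centroid with the ring normal as direction.
Acceptors carry a lone-pair-like direction (away from the mean heavy
neighbour). Aromatic carbons are deliberately not hydrophobic sites —
rings are represented by their R site. A single rule-based protonation
pass (aliphatic amines +1, carboxylic acids −1) approximates pH 7.4; no
state enumeration is attempted.

## Common-hypothesis search

Every k-subset of a conformer's sites becomes a *variant*: a sorted kind
label plus the condensed vector of inter-site distances, canonicalised
over equal-kind permutations by choosing the lexicographically smallest
vector. Within each label group, distance space is partitioned by
recursive bisection: each dimension is halved until its edge is
≤ `bin_size`, so the leaves form a uniform grid with edges in
(bin/2, bin]; boxes whose variants span too few distinct molecules are
pruned without refinement. A surviving leaf seeds one hypothesis, whose
geometry is the leaf's medoid variant translated to its centroid
(deterministic tie-breaks: total distance, then molecule/conformer/site
indices).

Two fractions govern emission:

* `box_coverage` — the fraction of molecules a leaf must contain to seed a
  hypothesis (default: equal to `must_match`);
* `must_match` — the fraction of ligands that must *fully match* the
  seeded hypothesis (all k sites within the 2 Å per-site tolerance after
  optimal superposition) for it to be emitted.

The decoupling matters for sparse inputs. With one rigid conformer per
ligand and site jitter σ, inter-site distances scatter with standard
deviation √2·σ per dimension; a fixed grid cell of edge ~1 Å then captures
each ligand's single variant with probability well below one per dimension,
and essentially never captures 90 % of ligands across 10 dimensions. Dense
conformer ensembles populate boxes (each ligand contributes many nearby
variants), so the 1 Å default edge is appropriate there; for the rigid
synthetic family the study conditions are bin 4 Å with `box_coverage` 0.1
and `must_match` 0.5 — the box is a seed, the match filter carries the
consensus guarantee. Recovered geometry quality is limited by jitter, not
by the bin, because the medoid is an actual observed variant (measured
recovery ≤ 0.8 Å at σ = 0.3).

Ranking uses a documented surrogate score

    w_align·(1 − mean match RMSD / 1.2 Å)
  + w_vec ·(mean direction cosine over matched A/R sites)
  + w_vol ·(mean pairwise Gaussian volume-overlap Tanimoto, σ = 1 Å,
            capped at the first 10 aligned ligands)

with unit default weights; it rewards tight alignment, consistent acceptor
and ring directionality, and shape coherence.

## Matching and alignment

Matching enumerates kind-consistent injective site correspondences of size
m from k down to `min_sites` (≥ 3) over all conformers, superposes with
the closed-form Kabsch solution (proper rotations only), and accepts a
correspondence when every matched site pair lies within the hypothesis
site's tolerance. Best match = maximal m, then minimal RMSD, then lowest
conformer energy, then input order — fully deterministic. Alignment
requires ≥ 3 matched sites and rejects near-collinear site sets (second
singular value < 10⁻⁶ of the first) rather than returning an arbitrary
rotation.

## Atom-based QSAR

Heavy atoms are classed D (N/O/S bearing H), P/N (formal charge, plus both
carboxylate oxygens), W (other N/O/S — electron-withdrawing), H (carbon
and heavy halogens), X (anything else, with a warning); van der Waals
radii come from a bundled Bondi-style table. The grid covers the training
ligands' union bounding box plus a 2 Å margin at 0.5 Å spacing, with the
origin snapped down to a spacing multiple so matrices are bit-exact and
order-independent. A bit (cube, class) is set when the cube centre lies
within the atom's vdW radius (≤, with a 10⁻¹² slack against float
round-off); columns occupied by fewer than 2 ligands are dropped.

PLS1 is the iterative score/loading (NIPALS) algorithm on mean-centred X
and y — no unit-variance scaling, since binary occupancy columns share a
scale. The collapsed coefficient vector B = W(PᵀW)⁻¹q and intercept
ȳ − x̄·B make prediction a single dot product; the factor-score path is
retained and agrees to 10⁻⁸ (tested). Requested factors are capped at the
effective rank with a warning. The factor cap of 7 guards against
over-fitting. Note that the all-zero row predicts the *intercept*, which
differs from ȳ whenever x̄·B ≠ 0.

Cross-validation realises leave-n-out as seeded k-fold (default 10 folds):
Q² = 1 − Σ(y_held − ŷ)² / Σ(y_held − ȳ_train-fold)², pooled over folds.
The statistics panel per factor count k on n compounds: r² = 1 − RSS/TSS,
RMSE = √(RSS/n), SD = √(RSS/(n−k−1)), F = (r²/k)/((1−r²)/(n−k−1)), P the
upper tail of F at (k, n−k−1), and the product-moment Pearson r.
Coefficient volumes export the cubes whose |coefficient| exceeds a
quantile of the nonzero magnitudes, signed — positive cubes mark occupancy
that raises predicted pKi.

## Screening validation

The database is ranked by predicted pKi; molecules failing the
minimum-site match receive the floor prediction (training-set minimum pKi)
and sink below all matched molecules, ordered by id. Ties in the ranked
list break by molecule id; the ROC is computed from scores with tied
groups entering together, which makes the trapezoidal AUC equal the
Mann–Whitney statistic with half credit for ties (so the headline AUC is
robust to the tie policy). EF, GH, %YA, %RA follow the standard formulas
at a hit-list cutoff defaulting to ⌈1 % of D⌉. Validity of a contingency
requires Ht − Ha ≤ D − A (a hit list cannot contain more inactives than
the database holds); with that constraint GH is provably in [0, 1].
Metrics are kept at full precision; two-decimal presentation (EF
conventionally truncated) happens only at the reporting layer.

## Synthetic benchmark

The generator plants a five-feature AHPRR hypothesis (pairwise distances
3–12 Å, demonstrably non-coplanar) and emits three populations:

* **Actives** — rigid classed point-sets carrying the planted sites
  jittered by N(0, σ²) per coordinate (default σ = 0.3 Å), plus 3
  random-kind distractor sites, a shared 8-atom scaffold, and a
  per-molecule random subset of 8 substituent atoms at fixed anchor
  positions. Activity is linear in the substituent indicators: pKi = 6.5 +
  Σcⱼzⱼ + N(0, 0.3²), coefficients ±0.4…±1.0, giving a ~5-log-unit Ki span
  and ~25 % potent compounds, mirroring a realistic blocker panel. Every
  molecule is then moved by a random rigid transform so alignment is
  earned, not given.
* **Decoys** — copy a random active's atom count, class multiset and site
  kinds, but redraw all positions uniformly in a ball whose radius
  reproduces the template's radius of gyration: property-matched in
  composition and size, divergent in geometry. Measured: 0 % of decoys
  fully match the planted hypothesis; partial (4-of-5) coincidences do
  occur, which is the realistic weak-binder pathway. Decoy Ki is drawn
  log-uniformly from the inactive range (5–54 µM).
* **A real family** — eight 1-benzyl-4-arylpiperidines shipped as SMILES
  with synthetic Ki labels, exercising parsing, protonation, conformers
  and perception on genuine chemistry.

Because activity in this family is modulated by substituent occupancy and
never by feature deletion, the benchmark's screening study condition is
full five-site matching; partial matching (default `min_sites` 4 for real
screens) is exercised by the unit suite instead. What passing the
benchmark shows: the search recovers a planted consensus geometry from
jittered observations, alignment + grid occupancy recover a planted linear
activity model (held-out Q² ≥ 0.7 at noise 0.3 pKi), and the ranked screen
separates planted actives from composition-matched decoys (AUC ≥ 0.9,
EF@1 % ≥ 10, seeds 1–5). What it does not show: conformational flexibility
of real actives, feature-definition errors on real chemistry, activity
cliffs, or assay noise structure beyond i.i.d. Gaussian.

Benchmark sizes in the recovery tests — 200 training actives, 100
held-out actives versus 2,000 decoys — keep the full five-seed sweep
around a minute while leaving all effects far from their decision
thresholds.

## Pipeline and provenance

The orchestrator hashes each stage's inputs and parameters; a stage reruns
only when its key or its outputs' recorded content hashes change, so
caching is reproducible across checkouts and a corrupted intermediate is
regenerated (deterministically, so byte-identical regeneration revalidates
descendants). The run configuration is embedded in the manifest, and every
model/hypothesis file carries a schema version.

## Known limitations

* The hypothesis score is a surrogate; absolute scores are not comparable
  across feature-definition versions.
* Matching cost grows combinatorially with sites per kind; it is intended
  for drug-like site counts (≲ 15 sites).
* Excluded volumes, field-based alignment and pharmacophore-based (site
  only) QSAR are out of scope by design.
* The protonation pass covers amines and carboxylic acids only.
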