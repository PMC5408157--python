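"""Atom-based 3D-QSAR on aligned ligands.

Each aligned ligand is encoded as a binary occupancy vector over a regular
cubic grid (default spacing 0.5 A) crossed with an atom-class alphabet
{D, H, N, P, W, X}: a bit is set when an atom of that class has its centre
within its van der Waals radius of the cube centre.  Partial least squares
(PLS1, the iterative score/loading algorithm) regresses pKi on the
mean-centred binary matrix with 1..7 factors; leave-n-out cross-validation
(realised as seeded k-fold) reports Q2.

The PLS and statistics code here is self-contained so that the collapsed
coefficient vector, the per-factor statistics panel (r2, SD, F, P, RMSE,
Q2, Pearson r) and the coefficient-volume export all come from one audited
path.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from rdkit import Chem
from scipy import stats as sps

from .chemio import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ATOM_CLASSES",
    "AtomClassing",
    "OccupancyGridSpec",
    "FeatureMatrix",
    "PLSModel",
    "ModelStats",
    "assign_atom_classes",
    "classed_atoms",
    "build_grid",
    "encode_ligand",
    "assemble_matrix",
    "encode_on_matrix",
    "fit_pls",
    "fit_pls_series",
    "cross_validate",
    "predict",
    "regression_stats",
    "factor_series_stats",
    "coefficient_volumes",
    "save_model",
    "load_model",
]

# donor-H heavy atom, hydrophobic/nonpolar, negative ionizable, positive
# ionizable, electron-withdrawing, miscellaneous
ATOM_CLASSES = ("D", "H", "N", "P", "W", "X")

DEFAULT_SPACING = 0.5  # Angstrom
DEFAULT_MARGIN = 2.0  # Angstrom
DEFAULT_MIN_OCCUPANCY = 2
MAX_FACTORS = 7


_VDW_CACHE: dict | None = None


def vdw_radius(symbol: str) -> float:
    global _VDW_CACHE
    if _VDW_CACHE is None:
        _VDW_CACHE = yaml.safe_load(
            resources.files("phore3d.data").joinpath("vdw_radii.yaml").read_text()
        )
    return float(_VDW_CACHE.get(symbol, _VDW_CACHE["default"]))


@dataclass
class AtomClassing:
    classes: list[str]
    radii: np.ndarray
    heavy_indices: np.ndarray  # original atom indices of the classed atoms

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.heavy_indices = np.asarray(self.heavy_indices, dtype=int)
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        bad = set(self.classes) - set(ATOM_CLASSES)
        if bad:
            raise ValueError(f"unknown atom classes {bad}")


_CARBOXYLATE = Chem.MolFromSmarts("[CX3](=[OX1])[OX1-]")


def assign_atom_classes(mol: Chem.Mol) -> AtomClassing:
    """Deterministic atom classing of the heavy atoms of a molecule.

    Rules, in priority order: formal +/- charge -> P/N; carboxylate oxygens
    -> N (both resonance forms ionizable); N/O/S bearing H -> D; other
    N/O/S -> W (electron-withdrawing); carbon and heavy halogens -> H;
    anything else -> X with a warning.
    """
    carboxylate_os: set[int] = set()
    for match in mol.GetSubstructMatches(_CARBOXYLATE):
        carboxylate_os.update(match[1:])
    classes: list[str] = []
    radii: list[float] = []
    heavy: list[int] = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1:
            continue
        heavy.append(atom.GetIdx())
        radii.append(vdw_radius(atom.GetSymbol()))
        z = atom.GetAtomicNum()
        charge = atom.GetFormalCharge()
        if charge > 0:
            cls = "P"
        elif charge < 0 or atom.GetIdx() in carboxylate_os:
            cls = "N"
        elif z in (7, 8, 16):
            cls = "D" if atom.GetTotalNumHs() > 0 else "W"
        elif z == 6 or z in (9, 17, 35, 53):
            cls = "H"
        else:
            cls = "X"
            logger.warning(
                "atom %d (%s): unsupported element, classed X", atom.GetIdx(), atom.GetSymbol()
            )
        classes.append(cls)
    return AtomClassing(classes=classes, radii=np.array(radii), heavy_indices=np.array(heavy))


def classed_atoms(
    record: MoleculeRecord, coords: np.ndarray | None = None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(classes, coordinates, radii) of a record's heavy atoms.

    Synthetic point-set records carry their classes; real molecules are
    classed by :func:`assign_atom_classes`.  ``coords`` (all-atom rows for
    real molecules) overrides stored coordinates.
    """
    if record.atoms is not None:
        xyz = record.atoms.coords if coords is None else np.asarray(coords, dtype=float)
        return list(record.atoms.classes), xyz, record.atoms.radii
    if record.mol is None:
        raise ValueError(f"{record.id}: no structure to class")
    classing = assign_atom_classes(record.mol)
    if coords is None:
        if record.mol.GetNumConformers() == 0:
            raise ValueError(f"{record.id}: no 3D coordinates")
        coords = np.array(record.mol.GetConformer().GetPositions(), dtype=float)
    else:
        coords = np.asarray(coords, dtype=float)
    return classing.classes, coords[classing.heavy_indices], classing.radii


# ---------------------------------------------------------------------------
# Grid


@dataclass
class OccupancyGridSpec:
    origin: np.ndarray  # centre of cube (0,0,0)
    spacing: float
    dims: tuple[int, int, int]
    atom_classes: tuple[str, ...] = ATOM_CLASSES

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be >= 1 per axis")
        self.dims = tuple(int(d) for d in self.dims)

    @property
    def n_cubes(self) -> int:
        return self.dims[0] * self.dims[1] * self.dims[2]

    @property
    def n_columns(self) -> int:
        return self.n_cubes * len(self.atom_classes)

    def cube_center(self, linear: np.ndarray) -> np.ndarray:
        """Cube centres for linear cube indices (C order)."""
        linear = np.asarray(linear, dtype=int)
        nz = self.dims[2]
        ny = self.dims[1]
        k = linear % nz
        j = (linear // nz) % ny
        i = linear // (nz * ny)
        return self.origin + self.spacing * np.stack([i, j, k], axis=-1)

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "spacing": self.spacing,
            "dims": list(self.dims),
            "atom_classes": list(self.atom_classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OccupancyGridSpec":
        return cls(
            origin=np.array(d["origin"]),
            spacing=float(d["spacing"]),
            dims=tuple(d["dims"]),
            atom_classes=tuple(d["atom_classes"]),
        )


def build_grid(
    coord_sets: list[np.ndarray],
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
    atom_classes: tuple[str, ...] = ATOM_CLASSES,
) -> OccupancyGridSpec:
    """Axis-aligned grid covering the union bounding box plus margin.

    The origin is snapped down to a multiple of the spacing so that
    identical inputs give bit-exact matrices regardless of ligand order.
    """
    if not coord_sets:
        raise ValueError("no coordinates to grid")
    allpts = np.vstack([np.asarray(c, dtype=float) for c in coord_sets])
    lo = np.floor((allpts.min(axis=0) - margin) / spacing) * spacing
    hi = np.ceil((allpts.max(axis=0) + margin) / spacing) * spacing
    dims = tuple(int(round((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return OccupancyGridSpec(origin=lo, spacing=spacing, dims=dims, atom_classes=atom_classes)


def encode_ligand(
    coords: np.ndarray,
    classes: list[str],
    radii: np.ndarray,
    grid: OccupancyGridSpec,
) -> np.ndarray:
    """Sorted set of occupied column indices for one aligned ligand.

    Column layout is class-major: column = class_index * n_cubes + cube.
    A bit is set when the cube centre lies within the atom's van der Waals
    radius of the atom centre.  Atoms with no in-grid cube are logged.
    """
    coords = np.asarray(coords, dtype=float)
    cols: list[int] = []
    n_outside = 0
    class_index = {c: i for i, c in enumerate(grid.atom_classes)}
    for xyz, cls, r in zip(coords, classes, radii):
        ci = class_index.get(cls)
        if ci is None:
            continue
        rel = (xyz - grid.origin) / grid.spacing
        lo_idx = np.maximum(np.ceil(rel - r / grid.spacing), 0).astype(int)
        hi_idx = np.minimum(np.floor(rel + r / grid.spacing), np.array(grid.dims) - 1).astype(int)
        if np.any(lo_idx > hi_idx):
            n_outside += 1
            continue
        ii = np.arange(lo_idx[0], hi_idx[0] + 1)
        jj = np.arange(lo_idx[1], hi_idx[1] + 1)
        kk = np.arange(lo_idx[2], hi_idx[2] + 1)
        gi, gj, gk = np.meshgrid(ii, jj, kk, indexing="ij")
        centers = grid.origin + grid.spacing * np.stack(
            [gi.ravel(), gj.ravel(), gk.ravel()], axis=1
        )
        d2 = np.sum((centers - xyz) ** 2, axis=1)
        inside = d2 <= r * r + 1e-12
        if not inside.any():
            n_outside += 1
            continue
        linear = (
            gi.ravel()[inside] * grid.dims[1] * grid.dims[2]
            + gj.ravel()[inside] * grid.dims[2]
            + gk.ravel()[inside]
        )
        cols.extend((ci * grid.n_cubes + linear).tolist())
    if n_outside:
        logger.debug("%d atoms occupied no grid cube", n_outside)
    return np.unique(np.array(cols, dtype=np.int64))


@dataclass
class FeatureMatrix:
    X: np.ndarray  # (n_ligands, n_kept) binary, float64
    row_ids: list[str]
    col_ids: np.ndarray  # original column indices into the full grid space
    grid: OccupancyGridSpec

    @property
    def col_classes(self) -> list[str]:
        return [self.grid.atom_classes[c // self.grid.n_cubes] for c in self.col_ids]

    @property
    def col_centers(self) -> np.ndarray:
        return self.grid.cube_center(self.col_ids % self.grid.n_cubes)


def assemble_matrix(
    rows: list[np.ndarray],
    row_ids: list[str],
    grid: OccupancyGridSpec,
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
) -> FeatureMatrix:
    """Stack encoded rows, dropping columns occupied by < min_occupancy ligands."""
    if len(rows) != len(row_ids):
        raise ValueError("rows and row_ids length mismatch")
    if not rows:
        raise ValueError("no rows to assemble")
    concat = np.concatenate([np.asarray(r, dtype=np.int64) for r in rows]) if any(
        len(r) for r in rows
    ) else np.array([], dtype=np.int64)
    uniq, counts = np.unique(concat, return_counts=True)
    kept = uniq[counts >= min_occupancy]
    if len(kept) == 0:
        raise ValueError("all columns dropped by the occupancy filter")
    pos = {int(c): i for i, c in enumerate(kept)}
    X = np.zeros((len(rows), len(kept)))
    for i, r in enumerate(rows):
        for c in np.asarray(r, dtype=np.int64):
            j = pos.get(int(c))
            if j is not None:
                X[i, j] = 1.0
    return FeatureMatrix(X=X, row_ids=list(row_ids), col_ids=kept, grid=grid)


def encode_on_matrix(matrix: FeatureMatrix, occupied_cols: np.ndarray) -> np.ndarray:
    """Dense row over the matrix's kept columns from a full-grid index set."""
    row = np.zeros(len(matrix.col_ids))
    mask = np.isin(matrix.col_ids, np.asarray(occupied_cols, dtype=np.int64))
    row[mask] = 1.0
    return row


# ---------------------------------------------------------------------------
# PLS


@dataclass
class PLSModel:
    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, a)
    x_loadings: np.ndarray  # (p, a)
    y_loadings: np.ndarray  # (a,)
    coef: np.ndarray  # (p,), on the original (uncentred) columns
    intercept: float
    col_ids: np.ndarray | None = None
    grid: OccupancyGridSpec | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef + self.intercept

    def predict_via_scores(self, X: np.ndarray) -> np.ndarray:
        """Prediction through factor scores; equals :meth:`predict` to 1e-8."""
        Xc = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean
        a = self.weights.shape[1]
        rotation = np.linalg.solve(self.x_loadings.T @ self.weights, np.eye(a))
        scores = Xc @ self.weights @ rotation  # T = Xc W (P^T W)^-1
        return scores @ self.y_loadings + self.y_mean


def fit_pls(X: np.ndarray, y: np.ndarray, n_factors: int) -> PLSModel:
    """PLS1 via the iterative score/loading (NIPALS) algorithm.

    X is mean-centred only (binary occupancy columns are not scaled to unit
    variance).  If the requested factor count exceeds the effective rank the
    extraction stops early with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X row count and y length differ")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors >= n:
        raise ValueError("n_factors must be < number of rows")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to regress")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    actual = 0
    y_scale = float(np.linalg.norm(yc)) or 1.0
    for a in range(n_factors):
        w = Xc.T @ yc
        norm_w = np.linalg.norm(w)
        if norm_w < 1e-12 * y_scale:
            logger.warning("PLS rank exhausted at %d of %d factors", a, n_factors)
            break
        w /= norm_w
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-24:
            logger.warning("PLS degenerate score at factor %d", a + 1)
            break
        p_a = Xc.T @ t / tt
        q_a = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a] = w
        P[:, a] = p_a
        q[a] = q_a
        actual += 1
    if actual == 0:
        raise ValueError("no PLS factor could be extracted")
    W, P, q = W[:, :actual], P[:, :actual], q[:actual]
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_factors=actual,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        intercept=intercept,
    )


def fit_pls_series(X: np.ndarray, y: np.ndarray, max_factors: int = MAX_FACTORS) -> list[PLSModel]:
    """Models with 1..max_factors factors (each capped by the data rank)."""
    out = []
    for a in range(1, max_factors + 1):
        m = fit_pls(X, y, a)
        out.append(m)
        if m.n_factors < a:
            break
    return out


def predict(
    model: PLSModel,
    rows: np.ndarray,
    no_match: np.ndarray | None = None,
    floor: float | None = None,
) -> np.ndarray:
    """Predict pKi; rows flagged no-match receive the floor prediction."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != len(model.coef):
        raise ValueError(
            f"row length {rows.shape[1]} does not match model columns {len(model.coef)}"
        )
    y = model.predict(rows)
    if no_match is not None:
        if floor is None:
            raise ValueError("floor prediction required when no_match rows present")
        y = y.copy()
        y[np.asarray(no_match, dtype=bool)] = floor
    return y


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    folds: int = 10,
    seed: int = 42,
) -> tuple[float, list["ModelStats"]]:
    """Leave-n-out cross-validation realised as seeded k-fold.

    Q2 = 1 - sum((y_held - yhat)^2) / sum((y_held - mean(y_train_fold))^2),
    pooled over folds.  Also returns the per-factor statistics panel for
    1..n_factors from the pooled held-out predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_sizes = np.full(folds, n // folds)
    fold_sizes[: n % folds] += 1
    bounds = np.concatenate([[0], np.cumsum(fold_sizes)])

    press = np.zeros(n_factors)
    tss = 0.0
    preds = np.full((n_factors, n), np.nan)
    for f in range(folds):
        held = order[bounds[f] : bounds[f + 1]]
        train = np.setdiff1d(order, held)
        if len(train) < 2:
            raise ValueError(f"fold {f}: fewer than 2 training rows")
        models = fit_pls_series(X[train], y[train], n_factors)
        ybar = y[train].mean()
        tss += float(np.sum((y[held] - ybar) ** 2))
        for a in range(n_factors):
            model = models[min(a, len(models) - 1)]
            yhat = model.predict(X[held])
            preds[a, held] = yhat
            press[a] += float(np.sum((y[held] - yhat) ** 2))
    q2 = 1.0 - press / tss
    stats_panel = []
    for a in range(n_factors):
        ms = regression_stats(y, preds[a], n_factors=a + 1)
        ms.q2 = float(q2[a])
        stats_panel.append(ms)
    return float(q2[n_factors - 1]), stats_panel


# ---------------------------------------------------------------------------
# Statistics


@dataclass
class ModelStats:
    n_factors: int
    r2: float
    sd: float
    f: float
    p: float
    rmse: float
    pearson_r: float
    q2: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "r2": self.r2,
            "sd": self.sd,
            "f": self.f,
            "p": self.p,
            "rmse": self.rmse,
            "q2": self.q2,
            "pearson_r": self.pearson_r,
        }


def regression_stats(
    y_obs: np.ndarray, y_pred: np.ndarray, n_factors: int
) -> ModelStats:
    """Statistics panel for one factor count.

    r2 = 1 - RSS/TSS; RMSE = sqrt(RSS/n); SD = sqrt(RSS/(n-k-1));
    F = (r2/k) / ((1-r2)/(n-k-1)); P = upper tail of F at (k, n-k-1);
    Pearson r by the product-moment formula.
    """
    y_obs = np.asarray(y_obs, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if len(y_obs) != len(y_pred) or len(y_obs) < 3:
        raise ValueError("need matched vectors of length >= 3")
    n = len(y_obs)
    k = int(n_factors)
    tss = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero variance in observed values")
    rss = float(np.sum((y_obs - y_pred) ** 2))
    r2 = 1.0 - rss / tss
    rmse = math.sqrt(rss / n)
    dof = n - k - 1
    sd = math.sqrt(rss / dof) if dof > 0 else float("nan")
    if dof > 0 and r2 < 1.0:
        f = (r2 / k) / ((1.0 - r2) / dof)
        p = float(sps.f.sf(f, k, dof))
    else:
        f, p = float("inf"), 0.0
    pr = float(sps.pearsonr(y_obs, y_pred)[0]) if np.ptp(y_pred) > 0 else float("nan")
    return ModelStats(n_factors=k, r2=r2, sd=sd, f=f, p=p, rmse=rmse, pearson_r=pr)


def factor_series_stats(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int = MAX_FACTORS,
    folds: int = 10,
    seed: int = 42,
) -> list[ModelStats]:
    """Training-fit statistics per factor count, with cross-validated Q2."""
    models = fit_pls_series(X, y, max_factors)
    _, cv_panel = cross_validate(X, y, len(models), folds=folds, seed=seed)
    panel = []
    for model, cv in zip(models, cv_panel):
        ms = regression_stats(y, model.predict(X), n_factors=model.n_factors)
        ms.q2 = cv.q2
        panel.append(ms)
    return panel


# ---------------------------------------------------------------------------
# Coefficient volumes and model IO


def coefficient_volumes(
    model: PLSModel, matrix: FeatureMatrix, quantile_threshold: float = 0.9
) -> list[tuple[np.ndarray, str, int, float]]:
    """(cube centre, class, sign, |coef|) for the strongest coefficients.

    Emits columns whose |coefficient| strictly exceeds the given quantile of
    the nonzero magnitudes; positive cubes mark activity-increasing
    occupancy, negative cubes activity-decreasing.
    """
    mags = np.abs(model.coef)
    nz = mags[mags > 0]
    if len(nz) == 0:
        return []
    thr = float(np.quantile(nz, quantile_threshold))
    centers = matrix.col_centers
    classes = matrix.col_classes
    out = []
    for j in np.flatnonzero(mags > thr):
        out.append(
            (centers[j], classes[j], int(np.sign(model.coef[j])), float(mags[j]))
        )
    out.sort(key=lambda t: -t[3])
    return out


def save_model(model: PLSModel, path: str | Path) -> None:
    payload = {
        "schema": "phore3d-pls/1",
        "n_factors": model.n_factors,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coef": model.coef.tolist(),
        "intercept": model.intercept,
        "col_ids": None if model.col_ids is None else model.col_ids.tolist(),
        "grid": None if model.grid is None else model.grid.to_dict(),
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PLSModel:
    d = json.loads(Path(path).read_text())
    return PLSModel(
        n_factors=int(d["n_factors"]),
        x_mean=np.array(d["x_mean"]),
        y_mean=float(d["y_mean"]),
        weights=np.array(d["weights"]),
        x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]),
        coef=np.array(d["coef"]),
        intercept=float(d["intercept"]),
        col_ids=None if d["col_ids"] is None else np.array(d["col_ids"], dtype=np.int64),
        grid=None if d["grid"] is None else OccupancyGridSpec.from_dict(d["grid"]),
        metadata=d.get("metadata", {}),
    )
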