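"""Virtual-screening validation: ranking, enrichment metrics, ROC/AUC.

A screening database (known actives + presumed-inactive decoys) is ranked
by predicted pKi.  The hit list of the top ``Ht`` compounds is scored with
the classical retrieval metrics:

    EF  = (Ha/Ht) / (A/D)                           enrichment factor
    GH  = [Ha(3A+Ht) / (4 Ht A)] [1 - (Ht-Ha)/(D-A)] Guner-Henry score
    %YA = 100 Ha/Ht                                  yield of actives
    %RA = 100 Ha/A                                   ratio of actives

with D the database size, A the total actives, Ha the actives in the hit
list.  The ROC curve is built from the predicted scores with proper tie
handling, so the trapezoidal AUC equals the Mann-Whitney pair statistic
(ties counted one half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemio import MoleculeRecord, ki_to_pki
from .conformers import ConformerEnsemble, ensemble_from_record, generate_ensemble
from .pharmacophore import (
    PharmacophoreHypothesis,
    align_ligand,
    match_ligand,
    sites_for_ensemble,
    DegenerateSitesError,
)
from .qsar3d import PLSModel, classed_atoms, encode_ligand

__all__ = [
    "ScreeningResult",
    "EnrichmentReport",
    "rank_database",
    "enrichment_factor",
    "goodness_of_hit",
    "yield_of_actives",
    "ratio_of_actives",
    "roc_curve_auc",
    "enrichment_report",
]


@dataclass
class ScreeningResult:
    """Database ranked by predicted pKi (descending).

    No-match molecules carry the floor prediction and rank below every
    matched molecule; ties are broken by molecule id.
    """

    table: pd.DataFrame  # columns: id, pred_pki, is_active, no_match

    def __post_init__(self) -> None:
        required = {"id", "pred_pki", "is_active", "no_match"}
        if not required <= set(self.table.columns):
            raise ValueError(f"result table needs columns {sorted(required)}")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "ScreeningResult":
        df = pd.DataFrame(rows)
        df = df.sort_values(
            by=["no_match", "pred_pki", "id"],
            ascending=[True, False, True],
            kind="stable",
        ).reset_index(drop=True)
        # no-match block is ordered by id alone
        nm = df["no_match"].to_numpy(dtype=bool)
        if nm.any():
            tail = df[nm].sort_values("id", kind="stable")
            df = pd.concat([df[~nm], tail]).reset_index(drop=True)
        df.index = pd.RangeIndex(1, len(df) + 1, name="rank")
        return cls(table=df)

    def __len__(self) -> int:
        return len(self.table)


def rank_database(
    model: PLSModel,
    hypothesis: PharmacophoreHypothesis,
    records: list[MoleculeRecord],
    matrix_col_ids: np.ndarray | None = None,
    min_sites: int = 4,
    floor: float | None = None,
    active_ids: set[str] | None = None,
    conformer_seed: int = 42,
) -> ScreeningResult:
    """Match, align, encode and predict every molecule, then rank.

    ``matrix_col_ids`` defaults to the model's stored column ids; ``floor``
    defaults to the model's recorded training minimum (metadata
    ``floor_pki``) and is assigned to molecules that fail the minimum-site
    match.  ``active_ids`` defaults to records labelled 'active'.
    """
    if not records:
        raise ValueError("empty screening database")
    col_ids = model.col_ids if matrix_col_ids is None else matrix_col_ids
    if col_ids is None or model.grid is None:
        raise ValueError("model lacks grid/column metadata for screening")
    if floor is None:
        floor = model.metadata.get("floor_pki")
        if floor is None:
            raise ValueError("no floor prediction available")
    if active_ids is None:
        active_ids = {r.id for r in records if r.set_label == "active"}

    sorter = np.argsort(col_ids, kind="stable")
    sorted_cols = col_ids[sorter]
    rows = []
    for record in sorted(records, key=lambda r: r.id):
        ensemble = (
            ensemble_from_record(record)
            if record.atoms is not None
            else generate_ensemble(record, seed=conformer_seed)
        )
        conf_sites = sites_for_ensemble(record, ensemble)
        m = match_ligand(hypothesis, ensemble, conf_sites, min_sites=min_sites)
        pred, no_match, n_matched, rmsd_ = float(floor), True, 0, None
        if m is not None:
            try:
                aligned = align_ligand(hypothesis, m, ensemble, conf_sites)
            except DegenerateSitesError:
                aligned = None
            if aligned is not None:
                classes, _, radii = classed_atoms(record)
                heavy = aligned.coordinates_aligned[ensemble.heavy_idx]
                occ = encode_ligand(heavy, classes, radii, model.grid)
                row = np.zeros(len(col_ids))
                hit = np.searchsorted(sorted_cols, occ)
                ok = (hit < len(sorted_cols)) & (sorted_cols[np.minimum(hit, len(sorted_cols) - 1)] == occ)
                row[sorter[hit[ok]]] = 1.0
                pred = float(model.predict(row)[0])
                no_match = False
                n_matched = m.n_matched
                rmsd_ = aligned.match.match_rmsd
        rows.append(
            {
                "id": record.id,
                "pred_pki": pred,
                "is_active": record.id in active_ids,
                "no_match": no_match,
                "n_matched": n_matched,
                "align_rmsd": rmsd_,
            }
        )
    return ScreeningResult.from_rows(rows)


# ---------------------------------------------------------------------------
# Enrichment metrics


def _check_counts(ha: int, ht: int, a: int, d: int) -> None:
    if ht <= 0 or a <= 0 or d <= 0:
        raise ValueError("Ht, A and D must be positive")
    if ha < 0 or ha > ht or ha > a or a > d or ht > d:
        raise ValueError(f"inconsistent counts Ha={ha}, Ht={ht}, A={a}, D={d}")
    if ht - ha > d - a:
        # the hit list cannot contain more inactives than the database holds
        raise ValueError(f"impossible contingency: Ht-Ha={ht - ha} > D-A={d - a}")


def enrichment_factor(ha: int, ht: int, a: int, d: int) -> float:
    """EF = (Ha/Ht) / (A/D), full precision."""
    _check_counts(ha, ht, a, d)
    return (ha / ht) / (a / d)


def goodness_of_hit(ha: int, ht: int, a: int, d: int) -> float:
    """GH = [Ha(3A+Ht) / (4 Ht A)] * [1 - (Ht-Ha)/(D-A)], in [0, 1]."""
    _check_counts(ha, ht, a, d)
    if d <= a:
        raise ValueError("D must exceed A for the GH penalty term")
    yield_term = ha * (3 * a + ht) / (4.0 * ht * a)
    penalty = 1.0 - (ht - ha) / float(d - a)
    return yield_term * penalty


def yield_of_actives(ha: int, ht: int) -> float:
    """%YA = 100 Ha/Ht."""
    if ht <= 0:
        raise ValueError("Ht must be positive")
    if ha < 0 or ha > ht:
        raise ValueError("need 0 <= Ha <= Ht")
    return 100.0 * ha / ht


def ratio_of_actives(ha: int, a: int) -> float:
    """%RA = 100 Ha/A."""
    if a <= 0:
        raise ValueError("A must be positive")
    if ha < 0 or ha > a:
        raise ValueError("need 0 <= Ha <= A")
    return 100.0 * ha / a


# ---------------------------------------------------------------------------
# ROC


def roc_curve_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Tie-aware ROC points and trapezoidal AUC.

    Thresholds sweep the distinct score values in descending order; tied
    scores enter together, which makes the trapezoidal area identical to
    the Mann-Whitney statistic with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one active and one inactive")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    # close each group of tied scores
    boundary = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([boundary, [len(s) - 1]])
    tp = np.cumsum(l)[ends]
    fp = np.cumsum(~l)[ends]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class EnrichmentReport:
    d: int
    a: int
    ht: int
    ha: int
    ef: float
    gh: float
    pct_ya: float
    pct_ra: float
    roc_points: np.ndarray = field(repr=False)
    auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "D": self.d,
            "A": self.a,
            "Ht": self.ht,
            "Ha": self.ha,
            "EF": self.ef,
            "GH": self.gh,
            "pct_YA": self.pct_ya,
            "pct_RA": self.pct_ra,
            "AUC": self.auc,
            "roc_points": np.asarray(self.roc_points).tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def summary(self) -> str:
        return (
            f"D={self.d}  A={self.a}  Ht={self.ht}  Ha={self.ha}\n"
            f"EF={self.ef:.2f}  GH={self.gh:.2f}  "
            f"%YA={self.pct_ya:.1f}  %RA={self.pct_ra:.1f}  AUC={self.auc:.3f}"
        )


def enrichment_report(result: ScreeningResult, cutoff: int | None = None) -> EnrichmentReport:
    """Full validation block at a hit-list cutoff (default ~1% of D)."""
    d = len(result)
    if d == 0:
        raise ValueError("empty screening result")
    if cutoff is None:
        cutoff = int(np.ceil(0.01 * d))
    if not 0 < cutoff <= d:
        raise ValueError(f"cutoff must be in [1, {d}]")
    table = result.table
    a = int(table["is_active"].sum())
    ha = int(table.iloc[:cutoff]["is_active"].sum())
    points, auc = roc_curve_auc(
        table["pred_pki"].to_numpy(), table["is_active"].to_numpy()
    )
    return EnrichmentReport(
        d=d,
        a=a,
        ht=cutoff,
        ha=ha,
        ef=enrichment_factor(ha, cutoff, a, d),
        gh=goodness_of_hit(ha, cutoff, a, d),
        pct_ya=yield_of_actives(ha, cutoff),
        pct_ra=ratio_of_actives(ha, a),
        roc_points=points,
        auc=auc,
    )
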