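"""End-to-end orchestration with content-hash caching.

Stages: simulate (optional synthetic benchmark) -> hypothesize -> align ->
train -> screen -> report.  Every stage is keyed by a content hash of its
inputs and the relevant configuration, so re-running an unchanged pipeline
performs no recomputation, and corrupting an intermediate file invalidates
that stage and its descendants.  A machine-readable manifest records the
stage keys, output hashes and wall times; the run configuration is embedded
in every manifest for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemio
from .chemio import MoleculeRecord, ki_to_pki
from .conformers import ensemble_from_record, generate_ensemble
from .pharmacophore import (
    DegenerateSitesError,
    PharmacophoreHypothesis,
    align_ligand,
    find_common_hypotheses,
    match_ligand,
    sites_for_ensemble,
)
from .qsar3d import (
    assemble_matrix,
    build_grid,
    classed_atoms,
    encode_ligand,
    encode_on_matrix,
    factor_series_stats,
    fit_pls,
    load_model,
    regression_stats,
    save_model,
)
from .screenval import enrichment_report, rank_database
from .synthdata import SyntheticSpec, make_benchmark

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "prepare_record", "align_records"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Workflow parameters; defaults mirror the published study settings.

    Conformer energy window 21 kJ/mol, redundancy cutoff 0.5 A, grid
    spacing 0.5 A, at most 7 PLS factors, 60/40 train/test split, potent
    threshold Ki <= 50 nM, hit-list cutoff ~1% of the database.
    """

    # inputs: either a synthetic benchmark spec, or explicit files
    synthetic: dict | None = None
    actives_path: str | None = None
    decoys_path: str | None = None

    # pharmacophore
    n_features: int = 5
    must_match: float = 0.9
    box_coverage: float | None = None
    bin_size: float = 1.0
    site_tolerance: float = 2.0
    min_sites: int = 4

    # conformers
    energy_window: float = 21.0
    rmsd_cutoff: float = 0.5
    max_confs: int = 200

    # QSAR
    spacing: float = 0.5
    margin: float = 2.0
    min_occupancy: int = 2
    max_factors: int = 7
    folds: int = 10
    train_fraction: float = 0.6

    # screening
    cutoff: int | None = None

    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _hash_file(path: Path) -> str:
    return _hash_bytes(Path(path).read_bytes())


def _hash_obj(obj) -> str:
    return _hash_bytes(json.dumps(obj, sort_keys=True, default=str).encode())


class _Runner:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.config = config
        self.manifest_path = outdir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"schema": "phore3d-manifest/1", "stages": {}}
        self.manifest["config"] = config.to_dict()
        self.events: list[tuple[str, str]] = []

    def stage(self, name: str, inputs: list[Path], params: dict, outputs: list[Path], fn):
        key = _hash_obj(
            {
                "stage": name,
                "inputs": [_hash_file(p) for p in inputs],
                "params": params,
            }
        )
        entry = self.manifest["stages"].get(name)
        if (
            entry
            and entry.get("key") == key
            and entry.get("status") == "ok"
            and all(Path(p).exists() for p in entry.get("outputs", {}))
            and all(
                _hash_file(Path(p)) == h for p, h in entry.get("outputs", {}).items()
            )
        ):
            logger.info("stage %s: cache hit", name)
            self.events.append((name, "cached"))
            return
        start = time.monotonic()
        try:
            fn()
        except Exception as exc:
            self.manifest["stages"][name] = {"key": key, "status": "failed", "error": str(exc)}
            self._flush()
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        self.manifest["stages"][name] = {
            "key": key,
            "status": "ok",
            "outputs": {str(p): _hash_file(p) for p in outputs if Path(p).exists()},
            "wall_time_s": round(time.monotonic() - start, 3),
        }
        self.events.append((name, "ran"))
        self._flush()

    def _flush(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Shared helpers


def prepare_record(record: MoleculeRecord, config: RunConfig):
    """(ensemble, per-conformer feature sites) for any record type."""
    if record.atoms is not None:
        ensemble = ensemble_from_record(record)
    else:
        ensemble = generate_ensemble(
            record,
            max_confs=config.max_confs,
            energy_window=config.energy_window,
            rmsd_cutoff=config.rmsd_cutoff,
            seed=config.seed,
        )
    return ensemble, sites_for_ensemble(record, ensemble)


def align_records(
    records: list[MoleculeRecord],
    hypothesis: PharmacophoreHypothesis,
    config: RunConfig,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Match and align records into the hypothesis frame.

    Returns new records carrying aligned coordinates (non-matching records
    are dropped with a warning) and a per-molecule alignment table.
    """
    out: list[MoleculeRecord] = []
    rows = []
    for record in records:
        ensemble, conf_sites = prepare_record(record, config)
        m = match_ligand(hypothesis, ensemble, conf_sites, min_sites=config.min_sites)
        if m is None:
            logger.warning("%s: no match; excluded from alignment", record.id)
            rows.append({"id": record.id, "matched": False, "n_matched": 0, "rmsd": np.nan})
            continue
        try:
            aligned = align_ligand(hypothesis, m, ensemble, conf_sites)
        except DegenerateSitesError as exc:
            logger.warning("%s: %s", record.id, exc)
            rows.append({"id": record.id, "matched": False, "n_matched": 0, "rmsd": np.nan})
            continue
        new = _with_aligned_coords(record, aligned.coordinates_aligned, ensemble, aligned.transform)
        out.append(new)
        rows.append(
            {
                "id": record.id,
                "matched": True,
                "n_matched": m.n_matched,
                "rmsd": aligned.match.match_rmsd,
            }
        )
    return out, pd.DataFrame(rows)


def _with_aligned_coords(record, coords, ensemble, transform) -> MoleculeRecord:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    from .chemio import AtomSet
    from .pharmacophore import FeatureSite

    if record.atoms is not None:
        sites = None
        if record.sites is not None:
            sites = [
                FeatureSite(
                    kind=s.kind,
                    position=transform.apply(s.position.reshape(1, 3))[0],
                    direction=None
                    if s.direction is None
                    else transform.rotation @ s.direction,
                    atom_indices=s.atom_indices,
                )
                for s in record.sites
            ]
        return MoleculeRecord(
            id=record.id,
            name=record.name,
            atoms=AtomSet(
                classes=list(record.atoms.classes),
                coords=coords,
                radii=record.atoms.radii.copy(),
            ),
            sites=sites,
            ki=record.ki,
            set_label=record.set_label,
            source_ref=record.source_ref,
        )
    mol = Chem.AddHs(Chem.Mol(record.mol))
    if mol.GetNumAtoms() != len(coords):
        mol = Chem.Mol(record.mol)
        coords = coords[: mol.GetNumAtoms()]
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*[float(v) for v in xyz]))
    mol.RemoveAllConformers()
    mol.AddConformer(conf)
    return MoleculeRecord(
        id=record.id,
        name=record.name,
        mol=mol,
        ki=record.ki,
        set_label=record.set_label,
        source_ref=record.source_ref,
    )


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full workflow into ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = _Runner(outdir, config)

    # --- stage: simulate -------------------------------------------------
    if config.synthetic is not None:
        spec = SyntheticSpec.from_dict(config.synthetic)
        bench = outdir / "bench"
        actives_path = bench / "actives.sdf"
        decoys_path = bench / "decoys.sdf"

        def do_simulate():
            if bench.exists():
                for p in bench.iterdir():
                    p.unlink()
            make_benchmark(spec, bench, force=True)

        runner.stage(
            "simulate",
            inputs=[],
            params=spec.to_dict(),
            outputs=[actives_path, decoys_path, bench / "activities.csv", bench / "truth.json"],
            fn=do_simulate,
        )
    else:
        if not config.actives_path:
            raise PipelineError("config needs either synthetic spec or actives_path")
        actives_path = Path(config.actives_path)
        decoys_path = Path(config.decoys_path) if config.decoys_path else None

    hyp_path = outdir / "hypothesis.json"
    aligned_path = outdir / "aligned.sdf"
    alignment_csv = outdir / "alignment.csv"
    model_path = outdir / "model.json"
    stats_path = outdir / "stats.csv"
    screen_path = outdir / "screen.csv"
    enrich_path = outdir / "enrichment.json"
    report_path = outdir / "report.txt"

    phar_params = {
        k: getattr(config, k)
        for k in ("n_features", "must_match", "box_coverage", "bin_size", "site_tolerance", "seed")
    }

    # --- stage: hypothesize ----------------------------------------------
    def do_hypothesize():
        records = chemio.read_molecules(actives_path)
        potent = [r for r in records if r.activity_class == "potent"]
        if len(potent) < 2:
            raise PipelineError(f"only {len(potent)} potent actives; cannot hypothesize")
        prepared = [prepare_record(r, config) for r in potent]
        hyps = find_common_hypotheses(
            [e for e, _ in prepared],
            [s for _, s in prepared],
            n_features=config.n_features,
            must_match=config.must_match,
            box_coverage=config.box_coverage,
            bin_size=config.bin_size,
            site_tolerance=config.site_tolerance,
        )
        if not hyps:
            raise PipelineError("no common hypothesis found")
        hyps[0].save(hyp_path)

    runner.stage("hypothesize", [actives_path], phar_params, [hyp_path], do_hypothesize)

    # --- stage: align -----------------------------------------------------
    def do_align():
        records = chemio.read_molecules(actives_path)
        hyp = PharmacophoreHypothesis.load(hyp_path)
        aligned, table = align_records(records, hyp, config)
        if not aligned:
            raise PipelineError("no molecule aligned to the hypothesis")
        chemio.write_molecules(aligned, aligned_path)
        table.to_csv(alignment_csv, index=False)

    runner.stage(
        "align",
        [actives_path, hyp_path],
        {"min_sites": config.min_sites, "seed": config.seed},
        [aligned_path, alignment_csv],
        do_align,
    )

    # --- stage: train ------------------------------------------------------
    qsar_params = {
        k: getattr(config, k)
        for k in (
            "spacing",
            "margin",
            "min_occupancy",
            "max_factors",
            "folds",
            "train_fraction",
            "seed",
        )
    }

    def do_train():
        records = chemio.read_molecules(aligned_path)
        with_ki = [r for r in records if r.ki is not None]
        if len(with_ki) < 10:
            raise PipelineError("too few molecules with affinities for QSAR")
        train, test = chemio.split_train_test(
            with_ki, train_fraction=config.train_fraction, seed=config.seed
        )
        train_data = [classed_atoms(r) for r in train]
        grid = build_grid(
            [c for _, c, _ in train_data], spacing=config.spacing, margin=config.margin
        )
        rows = [encode_ligand(c, cls, rad, grid) for cls, c, rad in train_data]
        matrix = assemble_matrix(rows, [r.id for r in train], grid, config.min_occupancy)
        y = np.array([r.pki for r in train])
        max_f = min(config.max_factors, len(train) - 1)
        panel = factor_series_stats(
            matrix.X, y, max_factors=max_f, folds=config.folds, seed=config.seed
        )
        model = fit_pls(matrix.X, y, panel[-1].n_factors)
        model.col_ids = matrix.col_ids
        model.grid = grid
        model.metadata = {
            "floor_pki": float(y.min()),
            "n_train": len(train),
            "n_factors": model.n_factors,
            "seed": config.seed,
        }
        # external evaluation on the held-out 40%
        test_rows = []
        y_test = []
        for r in test:
            cls, c, rad = classed_atoms(r)
            test_rows.append(encode_on_matrix(matrix, encode_ligand(c, cls, rad, grid)))
            y_test.append(r.pki)
        stats_rows = [dict(s.to_dict(), split="train") for s in panel]
        if len(y_test) >= 3:
            y_test = np.array(y_test)
            pred_test = model.predict(np.array(test_rows))
            ext = regression_stats(y_test, pred_test, n_factors=model.n_factors)
            stats_rows.append(dict(ext.to_dict(), split="test"))
        save_model(model, model_path)
        pd.DataFrame(stats_rows).to_csv(stats_path, index=False)

    runner.stage("train", [aligned_path], qsar_params, [model_path, stats_path], do_train)

    # --- stage: screen ------------------------------------------------------
    if decoys_path is not None:

        def do_screen():
            actives = chemio.read_molecules(actives_path)
            for r in actives:
                r.set_label = "active"
            decoys = chemio.read_molecules(decoys_path)
            model = load_model(model_path)
            hyp = PharmacophoreHypothesis.load(hyp_path)
            result = rank_database(
                model, hyp, actives + decoys, min_sites=config.min_sites
            )
            result.table.to_csv(screen_path)
            report = enrichment_report(result, cutoff=config.cutoff)
            report.save(enrich_path)

        runner.stage(
            "screen",
            [actives_path, decoys_path, model_path, hyp_path],
            {"min_sites": config.min_sites, "cutoff": config.cutoff},
            [screen_path, enrich_path],
            do_screen,
        )

    # --- stage: report -------------------------------------------------------
    report_inputs = [stats_path] + ([enrich_path] if decoys_path is not None else [])

    def do_report():
        lines = ["phore3d pipeline report", "=" * 60, ""]
        stats = pd.read_csv(stats_path)
        lines.append("Per-factor PLS statistics (train split):")
        lines.append(
            f"{'PLS':>3} {'r2':>7} {'SD':>7} {'F':>9} {'P':>10} {'RMSE':>7} {'Q2':>7} {'Pearson':>8}"
        )
        for _, row in stats[stats["split"] == "train"].iterrows():
            lines.append(
                f"{int(row['n_factors']):>3} {row['r2']:>7.3f} {row['sd']:>7.3f} "
                f"{row['f']:>9.1f} {row['p']:>10.2e} {row['rmse']:>7.3f} "
                f"{row['q2']:>7.3f} {row['pearson_r']:>8.3f}"
            )
        ext = stats[stats["split"] == "test"]
        if len(ext):
            row = ext.iloc[0]
            lines.append("")
            lines.append(
                f"Held-out test set: r2={row['r2']:.3f} RMSE={row['rmse']:.3f} "
                f"Pearson={row['pearson_r']:.3f}"
            )
        if decoys_path is not None and Path(enrich_path).exists():
            e = json.loads(Path(enrich_path).read_text())
            lines += [
                "",
                "Screening enrichment:",
                f"D={e['D']}  A={e['A']}  Ht={e['Ht']}  Ha={e['Ha']}",
                f"EF={e['EF']:.2f}  GH={e['GH']:.2f}  %YA={e['pct_YA']:.1f}  "
                f"%RA={e['pct_RA']:.1f}  AUC={e['AUC']:.3f}",
            ]
        report_path.write_text("\n".join(lines) + "\n")

    runner.stage("report", report_inputs, {}, [report_path], do_report)

    runner.manifest["events"] = runner.events
    runner._flush()
    return runner.manifest
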