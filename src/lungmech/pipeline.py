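"""End-to-end workflow orchestration.

A run starts from either a synthetic phantom specification or a directory
of per-phase meshes + surface displacement fields, then walks the stages:
geometry QC -> material-model selection (volume ratio J) -> per-transition
elasticity optimization -> cycle propagation -> validation metrics ->
temporal fitting -> traction analysis -> feature extraction.  Every stage
logs its wall time and artifacts into a JSON manifest; any failure aborts
with a machine-readable stage tag.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ego import EGOConfig, optimize_cycle, transition_mid_times
from .features import extract_features, features_frame
from .fem import SolverConfig, phase_cycle_order, solve_displacement
from .materials import Material, select_material_model, tumor_material
from .mesh import geometry_qc
from .metrics import evaluate_pair, report_frame
from .phantom import PhantomSpec, generate_phantom, read_bundle, write_bundle
from .temporal import fit_trajectory
from .traction import directional_summary, traction_field

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; lists the offending keys."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration (one input mode: phantom | files)."""

    seed: int = 0
    output_dir: str = "lungmech_out"
    phantom: dict | None = None
    phases_dir: str | None = None
    clinical: dict = field(default_factory=lambda: {"age": 64.0, "bmi": 21.8})
    solver: dict = field(default_factory=dict)
    ego: dict = field(default_factory=dict)
    voxel_mm: float | None = None
    traction_cone_deg: float = 10.0
    run_optimization: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        bad = sorted(set(raw) - known)
        if bad:
            raise ConfigError(f"unknown config keys: {bad}")
        cfg = cls(**raw)
        modes = [m for m in ("phantom", "phases_dir") if getattr(cfg, m) is not None]
        if len(modes) != 1:
            raise ConfigError(
                f"exactly one input mode required (phantom | phases_dir), got {modes}"
            )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def solver_config(self) -> SolverConfig:
        return SolverConfig(**self.solver)

    def ego_config(self) -> EGOConfig:
        return EGOConfig(**{"seed": self.seed, **self.ego})


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "artifacts": [],
    }

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                    _write_manifest(manifest, outdir)
                    raise StageError(name, exc) from exc
                manifest["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.perf_counter() - self.t0, 3),
                }
                return False

        return _Ctx()

    def emit(path: Path):
        manifest["artifacts"].append(str(path))

    solver_cfg = config.solver_config()

    with stage("input"):
        if config.phantom is not None:
            spec = PhantomSpec(**{"seed": config.seed, **config.phantom})
            bundle = generate_phantom(spec)
            write_bundle(bundle, outdir / "bundle")
            emit(outdir / "bundle")
        else:
            bundle = read_bundle(config.phases_dir)

    with stage("qc"):
        ref = bundle.mesh_for("P50")
        rows = []
        for tag in bundle.phase_tags:
            qc = geometry_qc(bundle.mesh_for(tag), ref)
            rows.append(
                {"phase": tag, "volume_mm3": qc.volume,
                 "surface_area_mm2": qc.surface_area,
                 "rel_vol_diff": qc.rel_vol_diff,
                 "rel_area_diff": qc.rel_area_diff,
                 "watertight": qc.watertight}
            )
        qc_path = outdir / "qc.csv"
        pd.DataFrame(rows).to_csv(qc_path, index=False)
        emit(qc_path)

    with stage("model_selection"):
        v50 = bundle.mesh_for("P50").volume("lung")
        v00 = bundle.mesh_for("P00").volume("lung")
        model, J = select_material_model(v50, v00)
        manifest["model"] = model
        manifest["J"] = J

    if config.run_optimization:
        with stage("optimize"):
            samples, records = optimize_cycle(
                bundle, cfg=config.ego_config(), solver_cfg=solver_cfg,
                voxel_mm=config.voxel_mm, lung_model=model,
            )
            elast_path = outdir / "elasticity_samples.csv"
            pd.DataFrame(samples).to_csv(elast_path, index=False)
            emit(elast_path)
            for k, rec in enumerate(records):
                rec.to_json(outdir / f"optimization_{k:02d}.json")
            emit(outdir / "optimization_00.json")
        E_rec = np.array([s["E_kPa"] for s in samples])
        v_rec = np.array([s["v"] for s in samples])
        t_rec = np.array([s["t"] for s in samples])
    else:
        # fall back to the bundle's ground-truth trajectory (phantom mode)
        t_rec = transition_mid_times(bundle)
        E_rec, v_rec = bundle.spec.elasticity_truth(t_rec)
        samples = None

    with stage("propagate_metrics"):
        order = phase_cycle_order(bundle.n_phases)
        mats = [Material(model, 1000.0 * E, v) for E, v in zip(E_rec, v_rec)]
        from .fem import propagate_cycle

        solutions, tumor_meshes, _ = propagate_cycle(
            bundle, mats, tumor_material(), solver_cfg
        )
        reports = []
        for k, tag in enumerate(order[1:]):
            obs = bundle.observed_tumor(tag)
            reports.append(
                evaluate_pair(tumor_meshes[k], obs, (order[k], tag),
                              config.voxel_mm)
            )
        metrics_path = outdir / "metrics.csv"
        report_frame(reports).to_csv(metrics_path, index=False)
        emit(metrics_path)
        manifest["mean_delta_tcm_mm"] = float(
            np.mean([r.delta_tcm for r in reports])
        )
        manifest["mean_vdsc"] = float(np.mean([r.vdsc for r in reports]))

    with stage("fit_temporal"):
        srt = np.argsort(t_rec)
        traj = fit_trajectory(t_rec[srt], E_rec[srt], v_rec[srt],
                              seed=config.seed,
                              period=bundle.spec.cycle_period)
        temporal = {
            "best_model_E": traj.best_model_E,
            "best_model_v": traj.best_model_v,
            "E_fits": {m: {"coefficients": f.coefficients.tolist(),
                           "r2": f.r2, "mse": f.mse}
                       for m, f in traj.E_fits.items() if f.success},
            "v_fits": {m: {"coefficients": f.coefficients.tolist(),
                           "r2": f.r2, "mse": f.mse}
                       for m, f in traj.v_fits.items() if f.success},
        }
        tpath = outdir / "temporal_fits.json"
        tpath.write_text(json.dumps(temporal, indent=2))
        emit(tpath)
        manifest["best_model_E"] = traj.best_model_E
        manifest["best_model_v"] = traj.best_model_v

    with stage("traction"):
        i_mid = len(E_rec) // 2
        lung_mat = Material(model, 1000.0 * float(E_rec[i_mid]), float(v_rec[i_mid]))
        m50 = bundle.mesh_for("P50")
        sol = solve_displacement(m50, lung_mat, tumor_material(),
                                 bundle.boundary_field("P00"), solver_cfg)
        tf = traction_field(sol)
        summary = directional_summary(
            tf,
            {
                "G50": m50.centroid("tumor"),
                "G00_true": bundle.observed_tumor("P00").centroid(),
                "G00_sim": sol.deformed_mesh().centroid("tumor"),
            },
            m50,
            cone_deg=config.traction_cone_deg,
        )
        tr_path = outdir / "traction_faces.csv"
        tf.to_frame().to_csv(tr_path, index=False)
        emit(tr_path)
        manifest["traction_summary"] = summary.as_dict()
        manifest["traction_equilibrium_residual"] = tf.equilibrium_residual()
        p00_solution = sol

    with stage("features"):
        feats = extract_features(bundle, config.clinical, p00_solution)
        fpath = outdir / "features.csv"
        features_frame([feats]).to_csv(fpath, index=False)
        emit(fpath)
        manifest["features"] = {
            k: float(v) for k, v in zip(
                features_frame([feats]).columns, feats.as_array()
            )
        }

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=float)
    )
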