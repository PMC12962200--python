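"""End-to-end reproducible runs: simulate -> shim -> evaluate.

A run is fully determined by its configuration and seed; every output
carries the seed and a configuration hash.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io
from .evaluate import convergence_study, strategy_comparison
from .grid import CoilGeometry, VoxelGrid
from .shim import (
    CostSpec,
    ShimConstraints,
    ShimVector,
    cp_mode,
    optimize_subject,
    optimize_universal,
)
from .simulate import TrainingDatabase, generate_population

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_train: int = 19
    n_validation: int = 6
    grid_shape: tuple[int, int, int] = (48, 48, 32)
    voxel_size_mm: float = 4.0
    wavelength_mm: float = 90.0
    jitter_mm: float = 3.0
    jitter_deg: float = 3.0
    alpha_min: float = 0.8
    alpha_max: float = 1.3
    w_max: float = 0.35
    cost: str = "efficiency"
    mode: str = "phase_magnitude"
    n_restarts: int = 8
    convergence_n_restarts: int = 4

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @property
    def hash(self) -> str:
        return io.config_hash(self.to_dict())

    def constraints(self) -> ShimConstraints:
        return ShimConstraints(
            alpha_max=self.alpha_max, alpha_min=self.alpha_min,
            w_max=self.w_max, mode=self.mode,
        )

    def cost_spec(self) -> CostSpec:
        return CostSpec(kind=self.cost)


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if "grid_shape" in data:
        data["grid_shape"] = tuple(data["grid_shape"])
    return RunConfig(**data)


def simulate_split(config: RunConfig) -> tuple[TrainingDatabase, TrainingDatabase]:
    """Generate one population and split it into training / validation."""
    geometry = CoilGeometry()
    grid = VoxelGrid(shape=config.grid_shape, voxel_size_mm=(config.voxel_size_mm,) * 3)
    n_total = config.n_train + config.n_validation
    pop = generate_population(
        n_total, geometry=geometry, grid=grid,
        jitter_scale=(config.jitter_mm, config.jitter_deg),
        wavelength_mm=config.wavelength_mm, seed=config.seed,
    )
    train = TrainingDatabase(pop.datasets[: config.n_train], geometry=geometry)
    val = TrainingDatabase(pop.datasets[config.n_train :], geometry=geometry)
    return train, val


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run the full study and persist all outputs under ``out_dir``.

    Stages: simulate the population, split train/validation, derive the
    CP-mode, subject-specific and universal shims, evaluate all strategies
    on the validation subjects, and run the incremental convergence study.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": config.seed, "config_hash": config.hash}
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))

    def _stage(name):
        logger.info("stage %s started", name)
        return time.perf_counter()

    t0 = _stage("simulate")
    try:
        train, val = simulate_split(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    logger.info("stage simulate done in %.1fs", time.perf_counter() - t0)
    geometry = train.geometry
    constraints = config.constraints()
    cost_spec = config.cost_spec()

    t0 = _stage("shim")
    try:
        cp = cp_mode(geometry)
        io.write_shim(cp, out / "shim_cp.json", mode="phase_only", provenance=provenance)

        uni = optimize_universal(
            train, constraints, cost_spec, n_restarts=config.n_restarts,
            seed=config.seed, geometry=geometry,
        )
        io.write_shim(
            uni.shim, out / "shim_universal.json", mode=config.mode,
            cost=uni.cost_value, constraint_report=uni.constraint_report,
            provenance={**provenance, "n_restarts": config.n_restarts},
        )

        subject_shims = []
        for i, ds in enumerate(val):
            res = optimize_subject(
                ds.field_map, ds.phantom.roi_mask, constraints, cost_spec,
                n_restarts=config.n_restarts, seed=config.seed + i, geometry=geometry,
            )
            subject_shims.append(res.shim.weights)
            io.write_shim(
                res.shim, out / f"shim_subject_{ds.subject_id}.json", mode=config.mode,
                cost=res.cost_value, constraint_report=res.constraint_report,
                provenance={**provenance, "n_restarts": config.n_restarts},
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'shim' failed: {exc}") from exc
    logger.info("stage shim done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("evaluate")
    try:
        table = strategy_comparison(
            val,
            {
                "cp_mode": ShimVector(cp.weights),
                "universal": uni.shim,
                "subject_specific": subject_shims,
            },
            constraints,
        )
        table.insert(0, "config_hash", config.hash)
        table.insert(0, "seed", config.seed)
        table.to_csv(out / "strategy_comparison.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc
    logger.info("stage evaluate done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("converge")
    try:
        curve = convergence_study(
            train, val, constraints, cost_spec, seed=config.seed,
            n_restarts=config.convergence_n_restarts,
            subject_n_restarts=config.n_restarts, geometry=geometry,
        )
        frame = curve.to_frame()
        frame.insert(0, "config_hash", config.hash)
        frame.insert(0, "seed", config.seed)
        frame.to_csv(out / "convergence.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'converge' failed: {exc}") from exc
    logger.info("stage converge done in %.1fs", time.perf_counter() - t0)

    summary = {
        "seed": config.seed,
        "config_hash": config.hash,
        "median_nrmse_pct": {
            label: float(
                np.median(
                    table.query("strategy == @label and region == 'roi'")["nrmse_pct"]
                )
            )
            for label in ("cp_mode", "universal", "subject_specific")
        },
        "convergence_start_pct": float(curve.median_validation_nrmse[0]),
        "convergence_end_pct": float(curve.median_validation_nrmse[-1]),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
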