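"""End-to-end orchestration: validated YAML configs, per-stage seeding,
and a single deterministic JSON report.

A run executes the requested stages in dependency order::

    synth -> fit / fractal / stats

Every stage derives its RNG seed from the global seed and a fixed stage
ordinal via ``numpy.random.SeedSequence([seed, ordinal])``, so adding or
removing one stage never perturbs another stage's stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import cohort_stats, fractal_spatial, synthetic_data, treg_dynamics
from .errors import ConfigError, TregSwitchError

logger = logging.getLogger("tregswitch")

STAGE_ORDER = ("synth", "fit", "fractal", "stats")

#: fixed ordinals of the per-stage seed streams (documented contract)
SEED_ORDINALS = {
    "trajectory": 0,
    "flow_treated": 1,
    "flow_control": 2,
    "images": 3,
    "scrna": 4,
    "fit": 5,
}


def stage_seed(global_seed: int, ordinal: int) -> int:
    """Derive an independent 32-bit stage seed from the global seed."""
    return int(np.random.SeedSequence([int(global_seed), int(ordinal)]).generate_state(1)[0])


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TrajectoryBlock(_StrictModel):
    model: Literal[
        "I_mutation", "II_proliferation", "III_plasticity"
    ] = "III_plasticity"
    params: dict[str, float] = Field(default_factory=lambda: {"k_f": 0.2, "k_r": 0.05})
    x0: float = Field(default=1000.0, ge=0)
    y0: float = Field(default=10.0, ge=0)
    t_max: float = Field(default=48.0, gt=0)
    n_times: int = Field(default=20, ge=4)
    noise_sd: float = Field(default=0.05, ge=0)


class FlowBlock(_StrictModel):
    n_events: int = Field(default=20000, ge=1)
    treated_fraction: float = Field(default=0.29, ge=0, le=1)
    control_fraction: float = Field(default=0.05, ge=0, le=1)


class ImagesBlock(_StrictModel):
    n_per_group: int = Field(default=10, ge=2)
    shape: tuple[int, int] = (64, 64)
    n_points: int = Field(default=400, ge=1)
    cluster_count: int = Field(default=5, ge=1)
    cluster_sd: float = Field(default=2.0, gt=0)


class ScrnaBlock(_StrictModel):
    n_genes: int = Field(default=30, ge=1)
    n_cells_per_group: int = Field(default=300, ge=1)
    isg_gene_ids: list[int] = Field(default_factory=lambda: [0, 1])
    mt_responder_fraction: float = Field(default=0.15, ge=0, le=1)
    baseline_mean: float = Field(default=3.0, gt=0)
    effect_multiplier: float = Field(default=8.0, gt=0)
    dropout_rate: float = Field(default=0.02, ge=0, lt=1)


class SynthBlock(_StrictModel):
    trajectory: Optional[TrajectoryBlock] = Field(default_factory=TrajectoryBlock)
    flow: Optional[FlowBlock] = Field(default_factory=FlowBlock)
    images: Optional[ImagesBlock] = Field(default_factory=ImagesBlock)
    scrna: Optional[ScrnaBlock] = Field(default_factory=ScrnaBlock)


class FitBlock(_StrictModel):
    n_starts: int = Field(default=8, ge=1)


class FractalBlock(_StrictModel):
    measures: list[Literal["fd", "lacunarity"]] = Field(
        default_factory=lambda: ["fd", "lacunarity"]
    )


class StatsBlock(_StrictModel):
    query_group: str = "MT"
    ref_group: str = "TREG"
    genes: Optional[list[str]] = None  # default: the configured ISG genes


class RunConfig(_StrictModel):
    """Validated pipeline configuration."""

    seed: int = 0
    log_level: str = "INFO"
    stages: list[Literal["synth", "fit", "fractal", "stats"]] = Field(
        default_factory=lambda: list(STAGE_ORDER)
    )
    synth: SynthBlock = Field(default_factory=SynthBlock)
    fit: FitBlock = Field(default_factory=FitBlock)
    fractal: FractalBlock = Field(default_factory=FractalBlock)
    stats: StatsBlock = Field(default_factory=StatsBlock)


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    stages: dict = dc_field(default_factory=dict)
    ok: bool = True

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "ok": self.ok,
            "stages": self.stages,
        }


def validate_config(raw) -> RunConfig:
    """Parse a YAML document / mapping into a RunConfig.

    Every schema violation is reported, not only the first.
    """
    if isinstance(raw, (str, Path)):
        with open(raw) as handle:
            raw = yaml.safe_load(handle)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["configuration document must be a mapping"])
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        problems = [
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(problems) from exc


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _run_synth(config: RunConfig, artifacts: dict) -> dict:
    payload: dict = {}
    block = config.synth
    if block.trajectory is not None:
        tb = block.trajectory
        spec = treg_dynamics.ModelSpec(tb.model)
        params = treg_dynamics.ModelParams(**tb.params)
        times = np.linspace(0.0, tb.t_max, tb.n_times)
        data = synthetic_data.generate_trajectories(
            spec,
            params,
            tb.x0,
            tb.y0,
            times,
            noise_sd=tb.noise_sd,
            seed=stage_seed(config.seed, SEED_ORDINALS["trajectory"]),
        )
        artifacts["trajectory"] = data
        artifacts["trajectory_model"] = tb.model
        payload["trajectory"] = {
            "model": tb.model,
            "n_times": int(data.times.size),
            "terminal_total": float(data.x_obs[-1] + data.y_obs[-1]),
        }
    if block.flow is not None:
        fb = block.flow
        treated = synthetic_data.generate_flow_events(
            fb.n_events,
            fb.treated_fraction,
            seed=stage_seed(config.seed, SEED_ORDINALS["flow_treated"]),
            condition="treated",
        )
        control = synthetic_data.generate_flow_events(
            fb.n_events,
            fb.control_fraction,
            seed=stage_seed(config.seed, SEED_ORDINALS["flow_control"]),
            condition="control",
        )
        artifacts["flow_treated"] = treated
        artifacts["flow_control"] = control
        payload["flow"] = {"n_events": fb.n_events}
    if block.images is not None:
        ib = block.images
        base = stage_seed(config.seed, SEED_ORDINALS["images"])
        clustered = [
            synthetic_data.generate_spatial_image(
                synthetic_data.SpatialImageSpec(
                    shape=tuple(ib.shape),
                    pattern="clustered",
                    n_points=ib.n_points,
                    cluster_count=ib.cluster_count,
                    cluster_sd=ib.cluster_sd,
                    seed=base + i,
                )
            )
            for i in range(ib.n_per_group)
        ]
        uniform = [
            synthetic_data.generate_spatial_image(
                synthetic_data.SpatialImageSpec(
                    shape=tuple(ib.shape),
                    pattern="uniform_random",
                    n_points=ib.n_points,
                    seed=base + 10_000 + i,
                )
            )
            for i in range(ib.n_per_group)
        ]
        artifacts["images_clustered"] = clustered
        artifacts["images_uniform"] = uniform
        payload["images"] = {"n_per_group": ib.n_per_group, "shape": list(ib.shape)}
    if block.scrna is not None:
        sb = block.scrna
        cfg = synthetic_data.SyntheticCountConfig(
            n_genes=sb.n_genes,
            n_cells_per_group=sb.n_cells_per_group,
            isg_gene_ids=tuple(sb.isg_gene_ids),
            mt_responder_fraction=sb.mt_responder_fraction,
            baseline_mean=sb.baseline_mean,
            effect_multiplier=sb.effect_multiplier,
            dropout_rate=sb.dropout_rate,
        )
        matrix = synthetic_data.generate_scrna_counts(
            cfg, seed=stage_seed(config.seed, SEED_ORDINALS["scrna"])
        )
        artifacts["scrna"] = matrix
        artifacts["scrna_isg_genes"] = [matrix.gene_ids[g] for g in sb.isg_gene_ids]
        payload["scrna"] = {
            "n_genes": sb.n_genes,
            "n_cells": len(matrix.cell_ids),
        }
    return payload


def _run_fit(config: RunConfig, artifacts: dict) -> dict:
    data = artifacts.get("trajectory")
    if data is None:
        raise TregSwitchError("fit stage requires the synth trajectory")
    ranking = treg_dynamics.select_model(
        data,
        n_starts=config.fit.n_starts,
        seed=stage_seed(config.seed, SEED_ORDINALS["fit"]),
    )
    return {
        "generating_model": artifacts.get("trajectory_model"),
        "ranking": [r.to_dict() for r in ranking],
        "selected": ranking[0].model_id,
    }


def _run_fractal(config: RunConfig, artifacts: dict) -> dict:
    clustered = artifacts.get("images_clustered")
    uniform = artifacts.get("images_uniform")
    if clustered is None or uniform is None:
        raise TregSwitchError("fractal stage requires the synth image groups")
    metrics_a = [fractal_spatial.compute_metrics(img) for img in clustered]
    metrics_b = [fractal_spatial.compute_metrics(img) for img in uniform]
    payload: dict = {"n_a": len(metrics_a), "n_b": len(metrics_b)}
    for measure in config.fractal.measures:
        payload[measure] = fractal_spatial.compare_groups(
            metrics_a, metrics_b, measure=measure
        ).to_dict()
    return payload


def _run_stats(config: RunConfig, artifacts: dict) -> dict:
    payload: dict = {}
    treated = artifacts.get("flow_treated")
    control = artifacts.get("flow_control")
    if treated is not None and control is not None:
        gate = synthetic_data.default_gate()
        payload["fold_conversion"] = cohort_stats.fold_conversion(
            treated, control, gate
        ).to_dict()
    matrix = artifacts.get("scrna")
    if matrix is not None:
        genes = config.stats.genes or artifacts.get("scrna_isg_genes", [])
        payload["isg_fractions"] = [
            cohort_stats.isg_upregulated_fraction(
                matrix, gene, config.stats.query_group, config.stats.ref_group
            ).to_dict()
            for gene in genes
        ]
    if not payload:
        raise TregSwitchError("stats stage requires synth flow tables or counts")
    return payload


_STAGE_RUNNERS = {
    "synth": _run_synth,
    "fit": _run_fit,
    "fractal": _run_fractal,
    "stats": _run_stats,
}


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the configured stages in dependency order.

    Stage failures are recorded in the report (``ok`` flips to False) and do
    not abort later stages that can still run. Identical config + seed give
    identical stage payloads.
    """
    from . import __version__

    logging.basicConfig(level=config.log_level.upper())
    report = RunReport(
        version=__version__, config_hash=config_hash(config), seed=config.seed
    )
    artifacts: dict = {}
    requested = [s for s in STAGE_ORDER if s in config.stages]
    for name in requested:
        logger.info("running stage %s", name)
        try:
            payload = _STAGE_RUNNERS[name](config, artifacts)
            report.stages[name] = {"status": "ok", **payload}
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            report.stages[name] = {"status": "error", "message": str(exc)}
            report.ok = False
    if out_dir is not None:
        _write_outputs(report, artifacts, Path(out_dir))
    return report


def _write_outputs(report: RunReport, artifacts: dict, out_dir: Path) -> None:
    from . import io as tio

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    if "trajectory" in artifacts:
        artifacts["trajectory"].to_csv(out_dir / "trajectory.csv")
    if "flow_treated" in artifacts:
        artifacts["flow_treated"].to_csv(out_dir / "flow_treated.csv")
        artifacts["flow_control"].to_csv(out_dir / "flow_control.csv")
    if "scrna" in artifacts:
        tio.write_count_matrix(artifacts["scrna"], out_dir / "scrna")
    for group in ("clustered", "uniform"):
        images = artifacts.get(f"images_{group}")
        if images:
            for i, img in enumerate(images):
                tio.write_mask(img, out_dir / f"image_{group}_{i:02d}.png")
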