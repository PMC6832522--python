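"""Synthetic inputs for every downstream analysis stage.

Four generators, all deterministic given their seed:

* :func:`generate_flow_events` — flow-cytometry-like event tables with a
  log-normal FOXP3-low/FOXP3-high mixture and a controllable converted
  fraction;
* :func:`generate_trajectories` — noisy observations of the two-population
  dynamics models (multiplicative log-normal observation noise);
* :func:`generate_spatial_image` — binary point/fixture patterns for the
  box-counting metrics, including an exact Sierpinski carpet;
* :func:`generate_scrna_counts` — grouped negative-binomial count matrices
  with dropout and an interferon-stimulated-gene (ISG) effect carried by a
  responder subset of the MT-treated group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import treg_dynamics
from .errors import ParameterError
from .fractal_spatial import BinaryImage

GROUPS = ("WT", "MT", "TREG")
SPATIAL_PATTERNS = ("uniform_random", "clustered", "sierpinski_carpet", "solid", "empty")


# ---------------------------------------------------------------------------
# flow cytometry events
# ---------------------------------------------------------------------------


@dataclass
class FlowChannelParams:
    """Log-normal population parameters (median intensity, log-scale sd)."""

    cd4_median: float = 1000.0
    cd4_sigma: float = 0.4
    foxp3_neg_median: float = 50.0
    foxp3_neg_sigma: float = 0.5
    foxp3_pos_median: float = 1000.0
    foxp3_pos_sigma: float = 0.5

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ParameterError(f"{name} must be positive, got {value}")

    def foxp3_gate(self) -> float:
        """Geometric midpoint between the two FOXP3 population medians."""
        return math.sqrt(self.foxp3_neg_median * self.foxp3_pos_median)


@dataclass
class FlowEventTable:
    """Per-cell channel intensities plus a condition label for the table."""

    events: pd.DataFrame
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if self.events.empty:
            raise ParameterError("FlowEventTable needs >= 1 event")
        if self.events.columns.duplicated().any():
            raise ParameterError("channel names must be unique")
        values = self.events.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ParameterError("intensities must be finite and >= 0")

    def to_csv(self, path) -> None:
        out = self.events.copy()
        out["condition"] = self.condition
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FlowEventTable":
        frame = pd.read_csv(path)
        if "condition" in frame.columns:
            condition = str(frame["condition"].iloc[0])
            frame = frame.drop(columns=["condition"])
        else:
            condition = "unknown"
        return cls(events=frame, condition=condition)


def generate_flow_events(
    n_events: int,
    converted_fraction: float,
    channel_params: FlowChannelParams | None = None,
    seed: int = 0,
    condition: str = "synthetic",
) -> FlowEventTable:
    """Mixture of FOXP3-low and FOXP3-high log-normal populations.

    The number of converted (FOXP3-high) events is binomial in
    ``converted_fraction``, so the expected gated-positive fraction matches
    the requested one up to the small gate leakage of each log-normal tail.
    """
    if n_events < 1:
        raise ParameterError("n_events must be >= 1")
    if not 0 <= converted_fraction <= 1:
        raise ParameterError("converted_fraction must lie in [0, 1]")
    params = channel_params or FlowChannelParams()
    rng = np.random.default_rng(seed)

    n_pos = int(rng.binomial(n_events, converted_fraction))
    cd4 = params.cd4_median * np.exp(rng.normal(0, params.cd4_sigma, n_events))
    foxp3 = np.empty(n_events)
    foxp3[:n_pos] = params.foxp3_pos_median * np.exp(
        rng.normal(0, params.foxp3_pos_sigma, n_pos)
    )
    foxp3[n_pos:] = params.foxp3_neg_median * np.exp(
        rng.normal(0, params.foxp3_neg_sigma, n_events - n_pos)
    )
    # shuffle so converted events are not a prefix block
    order = rng.permutation(n_events)
    frame = pd.DataFrame({"CD4": cd4[order], "FOXP3": foxp3[order]})
    return FlowEventTable(events=frame, condition=condition)


def default_gate(channel_params: FlowChannelParams | None = None):
    """Rectangular CD4+/FOXP3+ gate matched to the generator's populations."""
    from .cohort_stats import GateDefinition

    params = channel_params or FlowChannelParams()
    return GateDefinition(
        thresholds={
            "CD4": params.cd4_median / 10.0,
            "FOXP3": params.foxp3_gate(),
        }
    )


# ---------------------------------------------------------------------------
# population trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryDataset:
    """Observed (noisy) abundances of the two populations on a time grid."""

    times: np.ndarray
    x_obs: np.ndarray
    y_obs: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x_obs = np.asarray(self.x_obs, dtype=float)
        self.y_obs = np.asarray(self.y_obs, dtype=float)
        if not (self.times.size == self.x_obs.size == self.y_obs.size):
            raise ParameterError("times, x_obs, y_obs must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(self.x_obs < 0) or np.any(self.y_obs < 0):
            raise ParameterError("observed abundances must be >= 0")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time": self.times, "x_obs": self.x_obs, "y_obs": self.y_obs}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectoryDataset":
        frame = pd.read_csv(path)
        return cls(
            times=frame["time"].to_numpy(),
            x_obs=frame["x_obs"].to_numpy(),
            y_obs=frame["y_obs"].to_numpy(),
        )


def generate_trajectories(
    spec: treg_dynamics.ModelSpec,
    params: treg_dynamics.ModelParams,
    x0: float,
    y0: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TrajectoryDataset:
    """Noise-free model solution perturbed by i.i.d. log-scale Gaussian noise.

    Observations are ``x(t) * exp(noise_sd * Z)``, which keeps counts
    non-negative (a zero stays exactly zero); ``noise_sd=0`` reproduces the
    simulation output exactly.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    traj = treg_dynamics.simulate(spec, params, x0, y0, times)
    if noise_sd == 0:
        x_obs, y_obs = traj.x.copy(), traj.y.copy()
    else:
        rng = np.random.default_rng(seed)
        x_obs = traj.x * np.exp(rng.normal(0, noise_sd, traj.x.size))
        y_obs = traj.y * np.exp(rng.normal(0, noise_sd, traj.y.size))
    return TrajectoryDataset(
        times=traj.times.copy(), x_obs=x_obs, y_obs=y_obs, noise_sd=noise_sd
    )


# ---------------------------------------------------------------------------
# spatial images
# ---------------------------------------------------------------------------


@dataclass
class SpatialImageSpec:
    """Recipe for one binary test image."""

    shape: tuple[int, int] = (81, 81)
    pattern: str = "uniform_random"
    n_points: int = 500
    cluster_count: int = 5
    cluster_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in SPATIAL_PATTERNS:
            raise ParameterError(
                f"unknown pattern {self.pattern!r}; expected one of {SPATIAL_PATTERNS}"
            )
        h, w = self.shape
        if h < 2 or w < 2:
            raise ParameterError("image must be at least 2x2")
        if self.pattern == "sierpinski_carpet" and min(h, w) < 27:
            raise ParameterError("sierpinski_carpet needs shape >= 27x27")
        if self.pattern in ("uniform_random", "clustered"):
            if self.n_points < 1:
                raise ParameterError("point patterns need n_points >= 1")
            if self.n_points > h * w:
                raise ParameterError("n_points exceeds the pixel count")
        if self.pattern == "clustered" and (
            self.cluster_count < 1 or self.cluster_sd <= 0
        ):
            raise ParameterError("clustered pattern needs cluster_count>=1, cluster_sd>0")


def _sierpinski_carpet(shape: tuple[int, int]) -> tuple[np.ndarray, int]:
    """Standard central-ninth-removal carpet anchored at the origin.

    The carpet occupies the largest power-of-three square that fits; the
    remainder of the canvas stays background. Returns (pixels, side).
    """
    side = 3 ** int(math.floor(math.log(min(shape), 3) + 1e-12))
    levels = int(round(math.log(side, 3)))
    idx = np.arange(side)
    img = np.zeros(shape, dtype=bool)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    fg = np.ones((side, side), dtype=bool)
    for level in range(levels):
        scale = 3 ** (levels - 1 - level)
        fg &= ~(((ii // scale) % 3 == 1) & ((jj // scale) % 3 == 1))
    img[:side, :side] = fg
    return img, side


def _distinct_points(
    rng: np.random.Generator, draw, n_points: int, shape: tuple[int, int]
) -> np.ndarray:
    """Accumulate draws until n_points distinct in-bounds pixels are collected."""
    h, w = shape
    chosen: dict[int, None] = {}
    guard = 0
    while len(chosen) < n_points:
        guard += 1
        if guard > 10000:
            raise ParameterError("could not place the requested points; pattern too tight")
        pts = draw(max(n_points - len(chosen), 16))
        rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
        cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
        for flat in rows * w + cols:
            if len(chosen) >= n_points:
                break
            chosen.setdefault(int(flat), None)
    return np.fromiter(chosen.keys(), dtype=int, count=n_points)


def generate_spatial_image(spec: SpatialImageSpec) -> BinaryImage:
    """Render the requested pattern; point patterns place exactly n_points pixels."""
    h, w = spec.shape
    label = f"{spec.pattern}:{spec.seed}"
    if spec.pattern == "solid":
        return BinaryImage(np.ones(spec.shape, dtype=bool), provenance=label)
    if spec.pattern == "empty":
        return BinaryImage(np.zeros(spec.shape, dtype=bool), provenance=label)
    if spec.pattern == "sierpinski_carpet":
        pixels, side = _sierpinski_carpet(spec.shape)
        return BinaryImage(pixels, provenance=f"{label}:side={side}")

    rng = np.random.default_rng(spec.seed)
    if spec.pattern == "uniform_random":
        flat = rng.choice(h * w, size=spec.n_points, replace=False)
    else:  # clustered
        centers = np.column_stack(
            [rng.uniform(0, h, spec.cluster_count), rng.uniform(0, w, spec.cluster_count)]
        )

        def draw(k: int) -> np.ndarray:
            which = rng.integers(0, spec.cluster_count, size=k)
            return centers[which] + rng.normal(0, spec.cluster_sd, size=(k, 2))

        flat = _distinct_points(rng, draw, spec.n_points, spec.shape)
    pixels = np.zeros(h * w, dtype=bool)
    pixels[flat] = True
    return BinaryImage(pixels.reshape(spec.shape), provenance=label)


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x cells integer count matrix with a group label per cell."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.groups = np.asarray(self.groups)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ParameterError("counts shape must be (n_genes, n_cells)")
        if self.groups.size != len(self.cell_ids):
            raise ParameterError("one group label per cell required")

    def gene_vector(self, gene: str) -> np.ndarray:
        from .errors import SchemaError

        try:
            row = self.gene_ids.index(gene)
        except ValueError:
            raise SchemaError(f"gene {gene!r} not present") from None
        return np.asarray(self.counts[row], dtype=float)


@dataclass
class SyntheticCountConfig:
    """Parameters of the grouped negative-binomial + dropout generator.

    ISG genes are expressed at ``baseline_mean * effect_multiplier`` in the
    responder subset of MT cells and at ``baseline_mean * treg_multiplier``
    in TREG cells (default: sqrt of the effect multiplier, so the MT
    responders sit above the TREG reference level, and a unit effect leaves
    all groups identical). All other gene/group combinations are at
    baseline.
    """

    n_genes: int = 50
    n_cells_per_group: int = 500
    isg_gene_ids: Sequence[int] = field(default_factory=lambda: (0, 1))
    mt_responder_fraction: float = 0.15
    baseline_mean: float = 3.0
    effect_multiplier: float = 8.0
    dropout_rate: float = 0.02
    dispersion: float = 20.0
    treg_multiplier: float | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_group < 1:
            raise ParameterError("need >= 1 gene and >= 1 cell per group")
        if not 0 <= self.mt_responder_fraction <= 1:
            raise ParameterError("mt_responder_fraction must lie in [0, 1]")
        if not all(0 <= g < self.n_genes for g in self.isg_gene_ids):
            raise ParameterError("isg_gene_ids must index into the gene set")
        if self.baseline_mean <= 0 or self.effect_multiplier <= 0:
            raise ParameterError("means and multipliers must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        if self.treg_multiplier is not None and self.treg_multiplier <= 0:
            raise ParameterError("treg_multiplier must be positive")

    def resolved_treg_multiplier(self) -> float:
        if self.treg_multiplier is not None:
            return self.treg_multiplier
        return math.sqrt(self.effect_multiplier)


def generate_scrna_counts(config: SyntheticCountConfig, seed: int = 0) -> CountMatrix:
    """Draw the grouped count matrix (gamma-Poisson + Bernoulli dropout)."""
    rng = np.random.default_rng(seed)
    n = config.n_cells_per_group
    n_cells = n * len(GROUPS)
    groups = np.repeat(GROUPS, n)

    means = np.full((config.n_genes, n_cells), config.baseline_mean)
    isg = np.asarray(sorted(set(config.isg_gene_ids)), dtype=int)
    treg_slice = slice(2 * n, 3 * n)

    n_responders = int(round(config.mt_responder_fraction * n))
    responder_cols = n + rng.choice(n, size=n_responders, replace=False)
    if isg.size:
        means[np.ix_(isg, np.arange(*treg_slice.indices(n_cells)))] *= (
            config.resolved_treg_multiplier()
        )
        if n_responders:
            means[np.ix_(isg, responder_cols)] *= config.effect_multiplier

    # gamma-Poisson = negative binomial with shape `dispersion`
    lam = rng.gamma(config.dispersion, means / config.dispersion)
    counts = rng.poisson(lam)
    if config.dropout_rate > 0:
        counts = np.where(
            rng.random(counts.shape) < config.dropout_rate, 0, counts
        )

    gene_ids = [f"gene{g:04d}" for g in range(config.n_genes)]
    cell_ids = [f"cell{c:05d}" for c in range(n_cells)]
    return CountMatrix(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        groups=groups,
    )
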