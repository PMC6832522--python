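"""Two-population dynamics of non-Treg (X) / Treg (Y) cultures.

Three competing linear scenarios for the expansion of the Treg-like
compartment are implemented:

``I_mutation``
    heritable acquisition of the Treg-like state::

        dX/dt = g_x*X - mu*E*X
        dY/dt = g_y*Y + mu*E*X

``II_proliferation``
    dose-enhanced proliferation of pre-existing Treg-like cells::

        dX/dt = g_x*X
        dY/dt = (g_y + beta*E)*Y

``III_plasticity``
    reversible phenotypic exchange, conserving the total population::

        dX/dt = -k_f*E*X + k_r*Y
        dY/dt =  k_f*E*X - k_r*Y

All three systems are linear, so :func:`simulate` propagates the exact
matrix-exponential solution rather than calling a numerical integrator.
Model III admits the analytic fixed-point Treg fraction
``k_f*E / (k_f*E + k_r)`` (:func:`steady_state_fraction`); models I and II
grow without bound whenever the net Treg growth rate is positive, which is
the qualitative dichotomy that :func:`classify_regime` detects.

Fitting (:func:`fit`) minimizes the residual sum of squares between
``log1p`` counts over each model's free, non-negative rate constants with a
seeded multi-start local optimizer; :func:`select_model` ranks the three
fits by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .errors import (
    FitError,
    ParameterError,
    SelectionError,
    UndefinedSteadyStateError,
)

MODEL_IDS = ("I_mutation", "II_proliferation", "III_plasticity")

#: free parameter names per model; dose E and (for model II) g_y are held
#: fixed during fitting because they only enter through products/sums with
#: the free rates and are therefore not separately identifiable. Model I is
#: fitted with a single basal growth rate shared by both compartments
#: (g_y tied to g_x): the compartments are the same cell type, conversion is
#: the distinguishing mechanism, and an untied g_y would make model II an
#: exact sub-model of model I (mu=0), defeating AIC-based selection.
FREE_PARAMS = {
    "I_mutation": ("g_x", "mu"),
    "II_proliferation": ("g_x", "beta"),
    "III_plasticity": ("k_f", "k_r"),
}

#: parameters pinned to another parameter's fitted value
TIED_PARAMS = {"I_mutation": {"g_y": "g_x"}}

_RATE_BOUND = (0.0, 5.0)  # 1/hour; generous for culture time scales


@dataclass(frozen=True)
class ModelSpec:
    """Identifier of one of the three dynamical scenarios."""

    model_id: str

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ParameterError(
                f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}"
            )


@dataclass
class ModelParams:
    """Rate constants (1/hour) and the unitless exosome dose multiplier E.

    Parameters irrelevant to a given model are ignored but must be finite
    and non-negative.
    """

    g_x: float = 0.0
    g_y: float = 0.0
    mu: float = 0.0
    beta: float = 0.0
    k_f: float = 0.0
    k_r: float = 0.0
    E: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_x", "g_y", "mu", "beta", "k_f", "k_r", "E"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ParameterError(f"parameter {name} must be finite, got {value}")
            if value < 0:
                raise ParameterError(f"parameter {name} must be >= 0, got {value}")


@dataclass
class Trajectory:
    """Deterministic solution of one model on a time grid."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def treg_fraction(self) -> np.ndarray:
        """y/(x+y) per time point; NaN where the total population is zero."""
        total = self.x + self.y
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, self.y / np.where(total > 0, total, 1.0), np.nan)
        return frac

    @property
    def total(self) -> np.ndarray:
        return self.x + self.y


@dataclass
class FitResult:
    """Outcome of fitting one model to a trajectory dataset."""

    model_id: str
    params: ModelParams
    loss: float
    n_obs: int
    aic: float
    n_free: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": {k: getattr(self.params, k) for k in FREE_PARAMS[self.model_id]},
            "loss": self.loss,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "n_free": self.n_free,
        }


def rate_matrix(spec: ModelSpec, params: ModelParams) -> np.ndarray:
    """2x2 generator A of the linear system d[X,Y]/dt = A @ [X,Y]."""
    p = params
    if spec.model_id == "I_mutation":
        return np.array(
            [[p.g_x - p.mu * p.E, 0.0], [p.mu * p.E, p.g_y]], dtype=float
        )
    if spec.model_id == "II_proliferation":
        return np.array([[p.g_x, 0.0], [0.0, p.g_y + p.beta * p.E]], dtype=float)
    # III_plasticity: columns sum to zero => exact conservation of X+Y
    kf = p.k_f * p.E
    return np.array([[-kf, p.k_r], [kf, -p.k_r]], dtype=float)


def _validate_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ParameterError("times must be a non-empty 1-D grid")
    if times[0] < 0:
        raise ParameterError("times must start at >= 0")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ParameterError("times must be strictly increasing")
    return times


def _propagate(A: np.ndarray, z0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Exact linear-ODE solution expm(A*t) @ z0 for every t, vectorized.

    Uses the eigendecomposition when the eigenvector basis is well
    conditioned; falls back to per-point expm for (near-)defective A.
    """
    w, V = np.linalg.eig(A)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        c = np.linalg.solve(V, z0.astype(complex))
        with np.errstate(over="ignore"):
            modes = np.exp(np.outer(times, w))  # (T, 2)
        out = np.real(modes * c @ V.T)
        # spot-check the spectral route against expm at the final time;
        # ill-scaled (e.g. denormal) rates can pass the condition test yet
        # reconstruct badly
        ref = expm(A * times[-1]) @ z0
        if not np.all(np.isfinite(ref)):
            return out  # overflow horizon; both routes saturate
        scale = max(np.max(np.abs(ref)), 1.0)
        if np.max(np.abs(out[-1] - ref)) <= 1e-9 * scale:
            return out
    out = np.empty((times.size, 2))
    for i, t in enumerate(times):
        out[i] = expm(A * t) @ z0
    return out


def simulate(
    spec: ModelSpec,
    params: ModelParams,
    x0: float,
    y0: float,
    times: Sequence[float],
) -> Trajectory:
    """Propagate the exact solution expm(A*t) @ [x0, y0] on the grid."""
    if x0 < 0 or y0 < 0:
        raise ParameterError("initial conditions must be non-negative")
    times = _validate_times(np.asarray(times, dtype=float))
    A = rate_matrix(spec, params)
    z0 = np.array([x0, y0], dtype=float)
    out = _propagate(A, z0, times)
    # the exact solution is non-negative; clip float round-off only
    out = np.clip(out, 0.0, None)
    return Trajectory(times=times, x=out[:, 0], y=out[:, 1])


def steady_state_fraction(params: ModelParams) -> float:
    """Analytic fixed-point Treg fraction of model III: k_f*E/(k_f*E + k_r)."""
    kf = params.k_f * params.E
    denom = kf + params.k_r
    if denom <= 0:
        raise UndefinedSteadyStateError(
            "steady-state fraction undefined when k_f*E + k_r = 0"
        )
    return kf / denom


def classify_regime(
    traj: Trajectory, window: float = 0.2, tol: float = 0.01
) -> str:
    """Label the trajectory 'growing', 'saturating', or 'declining'.

    The relative change of the total population over the trailing ``window``
    fraction of the time grid is compared to ``tol``.
    """
    if not 0 < window < 1:
        raise ParameterError("window must lie in (0, 1)")
    if traj.times.size < 10:
        raise ParameterError("classify_regime needs >= 10 time points")
    total = traj.total
    t_lo = traj.times[-1] - window * (traj.times[-1] - traj.times[0])
    i0 = int(np.searchsorted(traj.times, t_lo))
    i0 = min(i0, traj.times.size - 2)
    base = total[i0]
    if base <= 0:
        change = 0.0 if total[-1] <= 0 else np.inf
    else:
        change = (total[-1] - base) / base
    if abs(change) < tol:
        return "saturating"
    return "growing" if change > 0 else "declining"


def _objective(
    theta: np.ndarray,
    spec: ModelSpec,
    names: tuple[str, ...],
    base: ModelParams,
    times: np.ndarray,
    x0: float,
    y0: float,
    target: np.ndarray,
) -> float:
    updates = dict(zip(names, theta))
    for tied, source in TIED_PARAMS.get(spec.model_id, {}).items():
        updates[tied] = updates[source]
    params = replace(base, **updates)
    traj = simulate(spec, params, x0, y0, times)
    pred = np.log1p(np.stack([traj.x, traj.y]))
    return float(np.sum((pred - target) ** 2))


def fit(
    spec: ModelSpec,
    data,
    n_starts: int = 8,
    seed: int = 0,
    E: float = 1.0,
) -> FitResult:
    """Fit one model to a TrajectoryDataset by multi-start bounded L-BFGS-B.

    The loss is the RSS between log1p(observed) and log1p(simulated) counts
    for both populations; initial conditions are pinned to the first
    observation. ``aic = 2k + n*ln(RSS/n)`` with n the residual count.
    """
    times = _validate_times(np.asarray(data.times, dtype=float))
    x_obs = np.asarray(data.x_obs, dtype=float)
    y_obs = np.asarray(data.y_obs, dtype=float)
    if times.size < 4:
        raise ParameterError("fit requires >= 4 time points")
    if np.any(x_obs < 0) or np.any(y_obs < 0):
        raise ParameterError("observed counts must be non-negative")

    names = FREE_PARAMS[spec.model_id]
    base = ModelParams(E=E)
    target = np.log1p(np.stack([x_obs, y_obs]))
    x0, y0 = float(x_obs[0]), float(y_obs[0])

    rng = np.random.default_rng(seed)
    starts = [np.full(len(names), 0.05)]
    starts += [
        10.0 ** rng.uniform(-3, 0, size=len(names)) for _ in range(n_starts - 1)
    ]

    best = None
    failures = []
    for start in starts:
        try:
            res = minimize(
                _objective,
                start,
                args=(spec, names, base, times, x0, y0, target),
                method="L-BFGS-B",
                bounds=[_RATE_BOUND] * len(names),
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(repr(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(
            f"all {len(starts)} optimizer starts failed for {spec.model_id}", failures
        )

    updates = dict(zip(names, (float(v) for v in np.clip(best.x, 0.0, None))))
    for tied, source in TIED_PARAMS.get(spec.model_id, {}).items():
        updates[tied] = updates[source]
    fitted = replace(base, **updates)
    n = target.size
    rss = max(float(best.fun), 1e-12)
    aic = 2 * len(names) + n * np.log(rss / n)
    return FitResult(
        model_id=spec.model_id,
        params=fitted,
        loss=float(best.fun),
        n_obs=n,
        aic=float(aic),
        n_free=len(names),
    )


def select_model(data, n_starts: int = 8, seed: int = 0, E: float = 1.0) -> list[FitResult]:
    """Fit all three models and rank by AIC (ties: fewer params, then I<II<III)."""
    results = []
    errors = []
    for model_id in MODEL_IDS:
        try:
            results.append(fit(ModelSpec(model_id), data, n_starts=n_starts, seed=seed, E=E))
        except FitError as exc:
            errors.append(exc)
    if len(results) < 2:
        raise SelectionError(f"only {len(results)} of 3 models could be fitted", errors)
    order = {m: i for i, m in enumerate(MODEL_IDS)}
    results.sort(key=lambda r: (r.aic, r.n_free, order[r.model_id]))
    return results
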