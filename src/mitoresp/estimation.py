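"""Parameter estimation and identifiability diagnostics.

The objective is a normalized sum of squared errors over respirometry
features: for each substrate dataset j with observations x_ij (state-3 peak
oxygen consumption per ADP dose, optionally the state-2 mean as one extra
point),

    E(P) = sum_j (1/N_j) sum_i ((x_ij - X_ij(P)) / max_i x_ij)^2,

where X_ij(P) are the model features from a sequential-ADP simulation at
parameters P.  Fitting runs a global evolutionary stage (differential
evolution, log-uniform over the bounds) followed by constrained local
refinement.  Diagnostics are the normalized central-difference sensitivities
of E, the 0.5-1.5 sweep of E/E0 per parameter, and the parameter correlation
matrix from the Gauss-Newton information matrix of the feature Jacobian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .params import TMAX_KEYS, VMAX_KEYS, TissueParameterSet
from .protocols import SUBSTRATE_COMBOS, extract_features, protocol_A, run_schedule

__all__ = [
    "FeatureDataset",
    "FitResult",
    "DiagnosticsReport",
    "make_model_runner",
    "sse_objective",
    "make_objective",
    "fit_tissue",
    "normalized_sensitivity",
    "sensitivity_sweep",
    "correlation_matrix",
]

log = logging.getLogger(__name__)

#: objective value substituted when a simulation fails at a parameter point
PENALTY_BASE = 1.0e6


@dataclass(frozen=True)
class FeatureDataset:
    """Observed respirometry features for one substrate combination."""

    substrate: str
    adp_doses: tuple[float, ...]
    state2_ocr: float
    state3_peaks: tuple[float, ...]
    tissue: str = "heart"

    def __post_init__(self) -> None:
        if len(self.adp_doses) != len(self.state3_peaks):
            raise ValueError("one peak per ADP dose required")
        if len(self.state3_peaks) < 1:
            raise ValueError("dataset needs at least one observation")
        if self.state2_ocr < 0 or any(p < 0 for p in self.state3_peaks):
            raise ValueError("observations must be non-negative")

    def points(self, include_state2: bool = True) -> np.ndarray:
        pts = list(self.state3_peaks)
        if include_state2:
            pts.append(self.state2_ocr)
        return np.asarray(pts)


@dataclass
class FitResult:
    """Outcome of the two-stage fit."""

    param_names: tuple[str, ...]
    estimate: np.ndarray
    objective: float
    bounds: tuple[tuple[float, float], ...]
    seed: int
    trace: list = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.estimate)))


@dataclass
class DiagnosticsReport:
    param_names: tuple[str, ...]
    sensitivities: np.ndarray
    sweep_grid: np.ndarray
    sweep_curves: np.ndarray  # (n_params, n_grid) of E/E0
    correlation: np.ndarray | None = None

    def high_correlation_pairs(self, threshold: float = 0.8):
        """Parameter pairs whose |CC| exceeds the weak-dependency threshold."""
        if self.correlation is None:
            return []
        out = []
        n = len(self.param_names)
        for i in range(n):
            for j in range(i + 1, n):
                cc = self.correlation[i, j]
                if abs(cc) > threshold:
                    out.append((self.param_names[i], self.param_names[j], float(cc)))
        return out


def make_model_runner(
    base: TissueParameterSet,
    param_names: Sequence[str],
    substrates: Sequence[str] = SUBSTRATE_COMBOS,
    rtol: float = 1.0e-6,
    atol: float = 1.0e-8,
    dt_out: float = 0.02,
) -> Callable[[np.ndarray], dict[str, "RespiratoryFeatures"]]:
    """Closure mapping a parameter vector to simulated features per substrate.

    Only the named Vmax/Tmax parameters are replaced; everything else stays
    at the base tissue values.  Tolerances are relaxed relative to the
    reporting defaults because the objective only needs feature-level
    accuracy.
    """
    unknown = [p for p in param_names if p not in VMAX_KEYS and p not in TMAX_KEYS]
    if unknown:
        raise KeyError(f"unknown rate parameters: {unknown}")
    schedules = {s: protocol_A(base.tissue, s) for s in substrates}

    def runner(x: np.ndarray):
        ts = base.replace_rates(dict(zip(param_names, np.asarray(x, dtype=float))))
        out = {}
        for s, sched in schedules.items():
            res = run_schedule(ts, sched, rtol=rtol, atol=atol, dt_out=dt_out)
            out[s] = extract_features(res, sched)
        return out

    return runner


def sse_objective(
    simulated: Mapping[str, "RespiratoryFeatures"],
    datasets: Sequence[FeatureDataset],
    include_state2: bool = True,
) -> float:
    """Normalized SSE between simulated and observed features.

    Each dataset is normalized by the maximum of its own observations and
    weighted by 1/N_j, so substrates with different absolute rates and
    numbers of doses contribute comparably.
    """
    total = 0.0
    for ds in datasets:
        feats = simulated[ds.substrate]
        x = ds.points(include_state2)
        sim = list(feats.state3_peaks)
        if include_state2:
            sim.append(feats.state2_ocr)
        X = np.asarray(sim)
        if X.shape != x.shape:
            raise ValueError(
                f"{ds.substrate}: simulated features have {X.shape[0]} points, "
                f"observed {x.shape[0]}"
            )
        scale = float(np.max(x))
        if scale <= 0:
            raise ValueError(f"{ds.substrate}: nonpositive normalization")
        total += float(np.sum(((x - X) / scale) ** 2)) / x.size
    return total


def make_objective(
    base: TissueParameterSet,
    datasets: Sequence[FeatureDataset],
    param_names: Sequence[str],
    include_state2: bool = True,
    runner: Callable | None = None,
    **runner_kwargs,
) -> Callable[[np.ndarray], float]:
    """E(P) as a plain vector function; simulation failures return a large
    finite penalty (logged) so evolutionary search stays totally ordered."""
    if runner is None:
        subs = tuple(ds.substrate for ds in datasets)
        runner = make_model_runner(base, param_names, substrates=subs, **runner_kwargs)

    def objective(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            return PENALTY_BASE * (1.0 + float(np.sum(np.abs(x[x < 0]))))
        try:
            simulated = runner(x)
        except Exception as exc:  # noqa: BLE001 - any solver failure is a penalty
            log.warning("simulation failed at %s: %s", x, exc)
            return PENALTY_BASE
        return sse_objective(simulated, datasets, include_state2)

    return objective


def fit_tissue(
    datasets: Sequence[FeatureDataset],
    base: TissueParameterSet,
    param_names: Sequence[str],
    bounds: Sequence[tuple[float, float]],
    seed: int = 0,
    popsize: int = 8,
    maxiter: int = 12,
    local_refine: bool = True,
    include_state2: bool = True,
    objective: Callable[[np.ndarray], float] | None = None,
    workers: int = 1,
) -> FitResult:
    """Two-stage estimation: global evolutionary search in log10 space over
    the bounds, then local constrained refinement from the best point.

    Reproducible for a fixed seed; returns the best parameter vector seen.
    """
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    for lo, hi in bounds:
        if not (0 < lo < hi):
            raise ValueError(f"bounds must be positive and ordered, got ({lo}, {hi})")
    if objective is None:
        objective = make_objective(base, datasets, param_names, include_state2)

    log_bounds = [(np.log10(lo), np.log10(hi)) for lo, hi in bounds]
    trace: list[tuple[float, float]] = []

    def log_objective(z: np.ndarray) -> float:
        val = objective(10.0**z)
        trace.append((float(val), float(np.min(z))))
        return val

    result = optimize.differential_evolution(
        log_objective,
        log_bounds,
        seed=seed,
        popsize=popsize,
        maxiter=maxiter,
        tol=1e-8,
        polish=False,
        init="sobol",
        updating="deferred",
        workers=workers,
    )
    best_x = 10.0**result.x
    best_E = float(result.fun)

    if local_refine:
        local = optimize.minimize(
            lambda z: objective(10.0**z),
            np.log10(best_x),
            method="Nelder-Mead",
            options={"maxfev": 25 * len(bounds), "xatol": 5e-4, "fatol": 1e-10},
        )
        if local.fun <= best_E:
            best_x = 10.0**local.x
            best_E = float(local.fun)

    best_x = np.clip(best_x, [lo for lo, _ in bounds], [hi for _, hi in bounds])
    return FitResult(
        param_names=tuple(param_names),
        estimate=np.asarray(best_x, dtype=float),
        objective=best_E,
        bounds=bounds,
        seed=seed,
        trace=trace,
    )


def normalized_sensitivity(
    P0: np.ndarray,
    E_fn: Callable[[np.ndarray], float],
    rel_step: float = 0.01,
    E0: float | None = None,
) -> np.ndarray:
    """Normalized sensitivity S_j = [E(1.01 P_j) - E(0.99 P_j)] / (0.02 E0),
    the central-difference form of (P_j/E0) dE/dP_j with a 1% step."""
    P0 = np.asarray(P0, dtype=float)
    if E0 is None:
        E0 = float(E_fn(P0))
    if E0 == 0:
        raise ZeroDivisionError("sensitivity undefined: E0 = 0")
    S = np.empty(P0.size)
    for j in range(P0.size):
        up = P0.copy()
        dn = P0.copy()
        up[j] *= 1.0 + rel_step
        dn[j] *= 1.0 - rel_step
        S[j] = (E_fn(up) - E_fn(dn)) / (2.0 * rel_step * E0)
    return S


def sensitivity_sweep(
    P0: np.ndarray,
    E_fn: Callable[[np.ndarray], float],
    grid: np.ndarray | None = None,
    E0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """E/E0 curves as each parameter is scanned over 0.5-1.5 of its optimum."""
    P0 = np.asarray(P0, dtype=float)
    if grid is None:
        grid = np.linspace(0.5, 1.5, 11)
    grid = np.asarray(grid, dtype=float)
    if E0 is None:
        E0 = float(E_fn(P0))
    if E0 == 0:
        raise ZeroDivisionError("sweep undefined: E0 = 0")
    curves = np.empty((P0.size, grid.size))
    for j in range(P0.size):
        for k, g in enumerate(grid):
            if np.isclose(g, 1.0):
                curves[j, k] = 1.0
                continue
            P = P0.copy()
            P[j] *= g
            curves[j, k] = E_fn(P) / E0
    return grid, curves


def feature_vector(simulated: Mapping[str, "RespiratoryFeatures"],
                   datasets: Sequence[FeatureDataset],
                   include_state2: bool = True) -> np.ndarray:
    """All fitted data points as one flat model-solution vector."""
    vec: list[float] = []
    for ds in datasets:
        feats = simulated[ds.substrate]
        vec.extend(feats.state3_peaks)
        if include_state2:
            vec.append(feats.state2_ocr)
    return np.asarray(vec)


def correlation_matrix(
    P0: np.ndarray,
    runner: Callable[[np.ndarray], Mapping[str, "RespiratoryFeatures"]],
    datasets: Sequence[FeatureDataset],
    rel_step: float = 0.01,
    include_state2: bool = True,
    jacobian: np.ndarray | None = None,
) -> np.ndarray:
    """Parameter correlation matrix CC_ij = HM_ij / sqrt(HM_ii HM_jj).

    The Jacobian JM has one row per fitted data point and one column per
    parameter (1% central differences of the simulated oxygen-consumption
    features); HM is the inverse of the Gauss-Newton information matrix
    JM' JM.  A singular information matrix falls back to the pseudo-inverse
    with a warning.
    """
    P0 = np.asarray(P0, dtype=float)
    if jacobian is None:
        cols = []
        for j in range(P0.size):
            up = P0.copy()
            dn = P0.copy()
            up[j] *= 1.0 + rel_step
            dn[j] *= 1.0 - rel_step
            f_up = feature_vector(runner(up), datasets, include_state2)
            f_dn = feature_vector(runner(dn), datasets, include_state2)
            cols.append((f_up - f_dn) / (2.0 * rel_step * P0[j]))
        jacobian = np.column_stack(cols)
    JM = np.asarray(jacobian, dtype=float)
    info = JM.T @ JM
    try:
        HM = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        log.warning("singular information matrix; using pseudo-inverse")
        HM = np.linalg.pinv(info)
    d = np.sqrt(np.diag(HM))
    d[d == 0] = np.nan
    CC = HM / np.outer(d, d)
    # enforce exact symmetry and unit diagonal against round-off
    CC = 0.5 * (CC + CC.T)
    np.fill_diagonal(CC, 1.0)
    return CC
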