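"""Compartmental ODE system: mass balances, charge balance and integration.

Matrix species obey V_m dC/dt = sum of reaction and transport fluxes (nmol/
min/mg over uL/mg gives mM/min); buffer species obey dC/dt = -J * rho * 1e-3
(protein density rho in mg/mL); intermembrane-space cytochrome c is touched
only by complexes III and IV.  The membrane potential integrates the
charge-weighted fluxes over the membrane capacitance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .fluxes import FLUX_INDEX, FLUX_NAMES, PSI_CHARGE, FluxCatalog, default_catalog
from .params import Compartments, TissueParameterSet
from .states import (
    BUFFER_SPECIES,
    CONSERVED_POOLS,
    IDX,
    IMS_SPECIES,
    MATRIX_SPECIES,
    N_STATES,
    STATE_NAMES,
)
from .thermo import ThermoContext

__all__ = [
    "STOICH",
    "build_stoichiometry",
    "build_rhs",
    "initial_state",
    "integrate",
    "evaluate_all_fluxes",
    "ocr_from_fluxes",
    "IntegrationError",
]

#: species change per forward turnover of each flux (unsigned volumes applied later)
STOICH: dict[str, dict[str, float]] = {
    "PDH": {"PYR_m": -1, "CoA_m": -1, "NAD_m": -1, "ACoA_m": 1, "NADH_m": 1},
    "CITS": {"OXA_m": -1, "ACoA_m": -1, "CIT_m": 1, "CoA_m": 1},
    "ICDH": {"CIT_m": -1, "NAD_m": -1, "AKG_m": 1, "NADH_m": 1},
    "AKGDH": {"AKG_m": -1, "CoA_m": -1, "NAD_m": -1, "SCoA_m": 1, "NADH_m": 1},
    "SCAS": {"SCoA_m": -1, "GDP_m": -1, "Pi_m": -1, "SUC_m": 1, "CoA_m": 1, "GTP_m": 1},
    "NDK": {"GTP_m": -1, "ADP_m": -1, "GDP_m": 1, "ATP_m": 1},
    "FH": {"FUM_m": -1, "MAL_m": 1},
    "MDH": {"MAL_m": -1, "NAD_m": -1, "OXA_m": 1, "NADH_m": 1},
    "GOT": {"ASP_m": -1, "AKG_m": -1, "OXA_m": 1, "GLU_m": 1},
    "CI": {"NADH_m": -1, "UQ_m": -1, "NAD_m": 1, "UQH2_m": 1},
    "CII": {"SUC_m": -1, "UQ_m": -1, "FUM_m": 1, "UQH2_m": 1},
    "CIII": {"UQH2_m": -1, "UQ_m": 1, "CytCox_i": -2, "CytCred_i": 2},
    "CIV": {"CytCred_i": -4, "CytCox_i": 4, "O2_e": -1},
    "CV": {"ADP_m": -1, "Pi_m": -1, "ATP_m": 1},
    "PYRH": {"PYR_e": -1, "PYR_m": 1},
    "GLUH": {"GLU_e": -1, "GLU_m": 1},
    "DCCS": {"SUC_e": -1, "SUC_m": 1, "Pi_m": -1, "Pi_e": 1},
    "DCCM": {"MAL_e": -1, "MAL_m": 1, "Pi_m": -1, "Pi_e": 1},
    "TCC": {"CIT_e": -1, "CIT_m": 1, "MAL_m": -1, "MAL_e": 1},
    "OME": {"AKG_e": -1, "AKG_m": 1, "MAL_m": -1, "MAL_e": 1},
    "GAE": {"GLU_e": -1, "GLU_m": 1, "ASP_m": -1, "ASP_e": 1},
    "ANT": {"ADP_e": -1, "ADP_m": 1, "ATP_m": -1, "ATP_e": 1},
    "PIC": {"Pi_e": -1, "Pi_m": 1},
    "HLEAK": {},
}

_MATRIX = set(MATRIX_SPECIES)
_IMS = set(IMS_SPECIES)
_BUFFER = set(BUFFER_SPECIES)


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the last good time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


def build_stoichiometry(
    compartments: Compartments,
    catalog: FluxCatalog | None = None,
) -> np.ndarray:
    """Volume-scaled stoichiometric matrix mapping fluxes to d(state)/dt."""
    catalog = catalog or default_catalog()
    cap = float(catalog.constants["capacitance_mM_per_mV"])
    S = np.zeros((N_STATES, len(FLUX_NAMES)))
    rho = compartments.protein_density_mg_per_mL
    for flux, species_map in STOICH.items():
        k = FLUX_INDEX[flux]
        for species, coeff in species_map.items():
            i = IDX[species]
            if species in _MATRIX:
                S[i, k] = coeff / compartments.V_m_uL_per_mg
            elif species in _IMS:
                S[i, k] = coeff / compartments.V_ims_uL_per_mg
            elif species in _BUFFER:
                S[i, k] = coeff * rho * 1.0e-3
            else:  # pragma: no cover
                raise KeyError(species)
    for flux, charge in PSI_CHARGE.items():
        S[IDX["dpsi"], FLUX_INDEX[flux]] = charge / (
            compartments.V_m_uL_per_mg * cap
        )
    return S


def build_rhs(
    tissue: TissueParameterSet,
    compartments: Compartments,
    ctx: ThermoContext | None = None,
    catalog: FluxCatalog | None = None,
    rotenone: bool = False,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Right-hand side d(state)/dt for the given tissue and chamber setup."""
    ctx = ctx or ThermoContext()
    catalog = catalog or default_catalog()
    fluxes = catalog.evaluator(tissue.vmax, tissue.tmax, tissue.regulation, ctx)
    S = build_stoichiometry(compartments, catalog)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        J = fluxes(y, rotenone)
        return S @ J

    return rhs


def evaluate_all_fluxes(
    state: np.ndarray | Mapping[str, float],
    tissue: TissueParameterSet,
    ctx: ThermoContext | None = None,
    catalog: FluxCatalog | None = None,
    rotenone: bool = False,
) -> dict[str, float]:
    """Named flux vector (24 entries) at one state."""
    ctx = ctx or ThermoContext()
    catalog = catalog or default_catalog()
    if isinstance(state, Mapping):
        y = np.array([state[name] for name in STATE_NAMES])
    else:
        y = np.asarray(state, dtype=float)
    J = catalog.evaluator(tissue.vmax, tissue.tmax, tissue.regulation, ctx)(y, rotenone)
    return {name: float(J[i]) for i, name in enumerate(FLUX_NAMES)}


def ocr_from_fluxes(J: np.ndarray, catalog: FluxCatalog | None = None) -> np.ndarray:
    """Oxygen consumption rate, nmol O2/min/mg: a fixed stoichiometric factor
    times the complex IV turnover flux (one turnover oxidizes two cytochromes
    c and consumes half an O2)."""
    catalog = catalog or default_catalog()
    factor = float(catalog.constants["ocr_per_civ_turnover"])
    J = np.asarray(J)
    return factor * J[..., FLUX_INDEX["CIV"]]


def initial_state(
    tissue: TissueParameterSet,
    config: dict | None = None,
    overrides: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Initial condition: buffer substrate-free, conserved pools at their
    stated totals, small endogenous matrix metabolites, seeded membrane
    potential."""
    if config is None:
        from .io import load_model_config

        config = load_model_config()
    values: dict[str, float] = {}
    values.update(config["initial_matrix"])
    values.update(config["initial_ims"])
    values.update(config["initial_buffer"])
    values["dpsi"] = float(config["dpsi_initial_mV"])
    if overrides:
        unknown = set(overrides) - set(STATE_NAMES)
        if unknown:
            raise KeyError(f"unknown state names in overrides: {sorted(unknown)}")
        values.update(overrides)
    y0 = np.array([values[name] for name in STATE_NAMES])

    # exact pool closure: adjust the oxidized member of each two-member pool
    for pool, (members, _) in CONSERVED_POOLS.items():
        total = tissue.pools.get(pool)
        if total is None:
            continue
        current = sum(values[m] for m in members)
        if abs(current - total) > 1e-12:
            raise ValueError(
                f"initial condition violates the {pool} pool: {current} != {total}"
            )
    return y0


@dataclass
class Trajectory:
    """Dense solution of one integration segment or a full protocol."""

    t: np.ndarray  # (n,), minutes
    y: np.ndarray  # (N_STATES, n)

    def state_at(self, idx: int) -> np.ndarray:
        return self.y[:, idx]

    def series(self, name: str) -> np.ndarray:
        return self.y[IDX[name], :]


def integrate(
    state0: np.ndarray,
    tissue: TissueParameterSet,
    t_span: tuple[float, float],
    compartments: Compartments,
    ctx: ThermoContext | None = None,
    catalog: FluxCatalog | None = None,
    rotenone: bool = False,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-10,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the system over one event-free interval."""
    rhs = build_rhs(tissue, compartments, ctx, catalog, rotenone)
    sol = solve_ivp(
        rhs, t_span, np.asarray(state0, dtype=float),
        method=method, rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else None
        raise IntegrationError(f"solver failed: {sol.message}", last_time=last)
    return Trajectory(t=sol.t, y=sol.y)
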