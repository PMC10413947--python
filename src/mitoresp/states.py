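"""State-vector layout for the compartmental mitochondrial model.

Concentrations are mM; membrane potential is mV.  Suffixes: ``_m`` matrix,
``_i`` intermembrane space, ``_e`` extra-mitochondrial buffer.  Citrate and
isocitrate are lumped into a single CIT pool (the flux catalog carries no
aconitase step, so the two are always at a fixed interconversion).
"""

from __future__ import annotations

import numpy as np

MATRIX_SPECIES = (
    "PYR_m", "CIT_m", "AKG_m", "SUC_m", "FUM_m", "MAL_m", "OXA_m",
    "GLU_m", "ASP_m", "ACoA_m", "SCoA_m", "CoA_m",
    "NAD_m", "NADH_m", "UQ_m", "UQH2_m",
    "ADP_m", "ATP_m", "GDP_m", "GTP_m", "Pi_m",
)

IMS_SPECIES = ("CytCred_i", "CytCox_i")

BUFFER_SPECIES = (
    "PYR_e", "GLU_e", "AKG_e", "SUC_e", "MAL_e", "CIT_e", "ASP_e",
    "ADP_e", "ATP_e", "Pi_e", "O2_e",
)

STATE_NAMES: tuple[str, ...] = MATRIX_SPECIES + IMS_SPECIES + BUFFER_SPECIES + ("dpsi",)

N_STATES = len(STATE_NAMES)

IDX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

#: conserved pools checked during integration: name -> (members, total mM)
CONSERVED_POOLS: dict[str, tuple[tuple[str, ...], float]] = {
    "pyridine": (("NAD_m", "NADH_m"), 3.0),
    "ubiquinone": (("UQ_m", "UQH2_m"), 1.5),
    "cytochrome_c": (("CytCred_i", "CytCox_i"), 1.0),
    "adenine_matrix": (("ADP_m", "ATP_m"), 10.0),
    "coenzyme_a": (("SCoA_m", "ACoA_m", "CoA_m"), 1.0),
    "guanine_matrix": (("GDP_m", "GTP_m"), 1.0),
}


def state_to_dict(y: np.ndarray) -> dict[str, float]:
    """Map a raw state array to a name -> value dict."""
    return {name: float(y[i]) for name, i in IDX.items()}


def dict_to_state(values: dict[str, float]) -> np.ndarray:
    """Build a state array from a complete name -> value dict."""
    missing = set(STATE_NAMES) - set(values)
    if missing:
        raise KeyError(f"missing state values: {sorted(missing)}")
    y = np.empty(N_STATES)
    for name, i in IDX.items():
        y[i] = values[name]
    return y


def pool_totals(y: np.ndarray) -> dict[str, float]:
    """Current value of each conserved pool (mM, within its compartment)."""
    return {
        pool: float(sum(y[IDX[s]] for s in members))
        for pool, (members, _) in CONSERVED_POOLS.items()
    }
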