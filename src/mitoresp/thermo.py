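"""Thermodynamic context and apparent equilibrium constants.

Reactions are referenced to their transformed Gibbs free energy at pH 7
(:math:`\\Delta_r G'^0`), and the apparent equilibrium constant at the working
matrix pH is obtained by scaling the pH-7 value with a power of 10 per proton
produced or consumed.  Membrane-potential coupling for charge-translocating
steps is handled separately (see :func:`charge_coupled_keq`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "ThermoContext",
    "apparent_keq",
    "proton_pump_cost",
    "charge_coupled_keq",
]

#: Ideal gas constant, J/mol/K.
GAS_CONSTANT = 8.314
#: Faraday constant, C/mol (J/mol per volt).
FARADAY = 96485.0


@dataclass(frozen=True)
class ThermoContext:
    """Fixed thermodynamic conditions of an experiment.

    Attributes
    ----------
    temperature:
        Absolute temperature in kelvin (default 310.15 K, i.e. 37 degC).
    pH_matrix:
        Mitochondrial matrix pH (default 7.6).
    pH_external:
        Buffer / intermembrane-space pH (default 7.15).
    """

    temperature: float = 310.15
    pH_matrix: float = 7.6
    pH_external: float = 7.15
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError("temperature must be positive")
        for name in ("pH_matrix", "pH_external"):
            v = getattr(self, name)
            if not (0.0 < v < 14.0):
                raise ValueError(f"{name} must lie in (0, 14), got {v}")

    @property
    def RT(self) -> float:
        """R*T in J/mol."""
        return self.gas_constant * self.temperature

    @property
    def delta_pH(self) -> float:
        """pH_matrix - pH_external (alkaline matrix gives a positive value)."""
        return self.pH_matrix - self.pH_external


def apparent_keq(
    delta_rG0: float,
    n_protons: int,
    pH: float,
    ctx: ThermoContext | None = None,
) -> float:
    """Apparent equilibrium constant at a specified pH.

    Parameters
    ----------
    delta_rG0:
        Transformed Gibbs free energy of the reaction at pH 7, kJ/mol.
    n_protons:
        Signed proton count: positive for a proton-producing reaction,
        negative for a proton-consuming one, zero for neither.  The pH-7
        constant exp(-dG/RT) is multiplied by ``10**(|nH| (pH-7))`` for a
        producing reaction and ``10**(|nH| (7-pH))`` for a consuming one.
    pH:
        The pH at which the constant is evaluated (usually the matrix pH).
    ctx:
        Thermodynamic context supplying R and T (defaults used if None).
    """
    if ctx is None:
        ctx = ThermoContext()
    if not math.isfinite(delta_rG0):
        raise ValueError(f"non-finite delta_rG0: {delta_rG0!r}")
    keq0 = math.exp(-delta_rG0 * 1000.0 / ctx.RT)
    n = abs(int(n_protons))
    if n_protons > 0:
        factor = 10.0 ** (n * (pH - 7.0))
    elif n_protons < 0:
        factor = 10.0 ** (n * (7.0 - pH))
    else:
        factor = 1.0
    return keq0 * factor


def proton_pump_cost(delta_psi_mV: float, ctx: ThermoContext) -> float:
    """Electrochemical cost (J/mol) of moving one proton matrix -> outside.

    The cost has an electrical part F*dPsi (matrix negative, so export is
    uphill for positive dPsi) and a chemical part RT ln(10) (pH_m - pH_e)
    (the alkaline matrix makes proton export additionally uphill).
    """
    return FARADAY * delta_psi_mV * 1e-3 + ctx.RT * math.log(10.0) * ctx.delta_pH


def charge_coupled_keq(
    delta_rG0: float,
    n_protons: int,
    n_charge: float,
    delta_psi_mV: float,
    ctx: ThermoContext,
    pH: float | None = None,
) -> float:
    """Apparent K'eq of a reaction that pumps ``n_charge`` protons outward.

    ``n_charge > 0`` means the forward reaction exports that many proton
    charges per turnover (ETC complexes); ``n_charge < 0`` means the forward
    reaction is driven by proton influx (ATP synthase).  The flux computed
    with this constant vanishes exactly when the chemical driving force
    balances the electrochemical proton-motive cost.
    """
    if pH is None:
        pH = ctx.pH_matrix
    keq_chem = apparent_keq(delta_rG0, n_protons, pH, ctx)
    u = proton_pump_cost(delta_psi_mV, ctx)
    return keq_chem * math.exp(-n_charge * u / ctx.RT)
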