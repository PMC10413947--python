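"""Tissue parameter sets and compartment geometry."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .fluxes import RegulationParams

__all__ = ["VMAX_KEYS", "TMAX_KEYS", "TISSUES", "Compartments", "TissueParameterSet"]

VMAX_KEYS = (
    "PDH", "CITS", "ICDH", "AKGDH", "SCAS", "NDK", "FH", "MDH", "GOT",
    "CI", "CII", "CIII", "CIV", "CV",
)
TMAX_KEYS = ("PYRH", "GLUH", "DCCS", "DCCM", "TCC", "OME", "GAE", "ANT", "PIC", "HLEAK")

TISSUES = ("heart", "cortex", "om")


@dataclass(frozen=True)
class Compartments:
    """Region volumes and mitochondrial protein density.

    The buffer volume cancels out of the concentration balances (fluxes are
    per mg protein and the protein density is per mL of buffer), but it is
    carried for bookkeeping and manifests.
    """

    V_e_mL: float = 2.0
    V_m_uL_per_mg: float = 1.0
    V_ims_fraction: float = 0.1
    protein_density_mg_per_mL: float = 0.05

    def __post_init__(self) -> None:
        for f in ("V_e_mL", "V_m_uL_per_mg", "V_ims_fraction", "protein_density_mg_per_mL"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be positive")

    @property
    def V_ims_uL_per_mg(self) -> float:
        return self.V_ims_fraction * self.V_m_uL_per_mg


@dataclass(frozen=True)
class TissueParameterSet:
    """The 24 extrinsic maximal rates plus regulation and conserved pools
    for one tissue.  Rates are nmol/min/mg mitochondrial protein at 37 degC."""

    tissue: str
    vmax: Mapping[str, float]
    tmax: Mapping[str, float]
    regulation: RegulationParams
    pools: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.vmax) != set(VMAX_KEYS):
            raise ValueError(
                f"vmax keys must be exactly {sorted(VMAX_KEYS)}; "
                f"offenders: {sorted(set(self.vmax) ^ set(VMAX_KEYS))}"
            )
        if set(self.tmax) != set(TMAX_KEYS):
            raise ValueError(
                f"tmax keys must be exactly {sorted(TMAX_KEYS)}; "
                f"offenders: {sorted(set(self.tmax) ^ set(TMAX_KEYS))}"
            )
        for k, v in {**dict(self.vmax), **dict(self.tmax)}.items():
            if v < 0:
                raise ValueError(f"negative maximal rate for {k}")

    def replace_rates(self, updates: Mapping[str, float]) -> "TissueParameterSet":
        """Return a copy with some Vmax/Tmax values replaced (fitting helper)."""
        vmax = dict(self.vmax)
        tmax = dict(self.tmax)
        for k, v in updates.items():
            if k in vmax:
                vmax[k] = float(v)
            elif k in tmax:
                tmax[k] = float(v)
            else:
                raise KeyError(f"unknown rate parameter {k!r}")
        return TissueParameterSet(self.tissue, vmax, tmax, self.regulation, self.pools)

    def scale_rate(self, key: str, factor: float) -> "TissueParameterSet":
        base = dict(self.vmax).get(key, dict(self.tmax).get(key))
        return self.replace_rates({key: base * factor})
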