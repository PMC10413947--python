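"""Generic rate laws: multisubstrate Michaelis-Menten and carrier mechanisms.

The reaction law implements a generalized random-ordered rapid-equilibrium
mechanism: the net rate is proportional to the displacement of the
mass-action ratio from the apparent equilibrium constant, saturating in every
substrate and product.  Carriers come in three mechanism classes (uniporter,
symporter, antiporter) with a shared 'one filled carrier at a time'
denominator.  Electrogenic or proton-coupled carriers take an equilibrium
bias factor ``theta`` multiplying the forward (external-side) term so that
the flux is zero exactly at the electrochemical equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "ReactionSpec",
    "TransporterSpec",
    "reaction_core",
    "reaction_flux",
    "uniporter_flux",
    "symporter_flux",
    "antiporter_flux",
]


@dataclass(frozen=True)
class ReactionSpec:
    """Stoichiometry, binding constants and thermodynamics of one reaction.

    ``substrates`` / ``products`` are sequences of ``(species, coeff, K)``
    with integer stoichiometric coefficients >= 1 and binding constants in mM.
    ``delta_rG0`` is the transformed Gibbs energy at pH 7 in kJ/mol;
    ``n_protons`` the signed proton count (+ producing / - consuming);
    ``vmax_key`` names the extrinsic V_maxf parameter the reaction reads.
    """

    name: str
    substrates: tuple[tuple[str, int, float], ...]
    products: tuple[tuple[str, int, float], ...]
    delta_rG0: float
    n_protons: int = 0
    vmax_key: str = ""
    #: protons translocated out of the matrix per forward turnover (ETC pumps);
    #: negative = driven by proton influx (ATP synthase)
    n_charge: float = 0.0

    def __post_init__(self) -> None:
        for side in (self.substrates, self.products):
            for species, coeff, k in side:
                if coeff < 1 or int(coeff) != coeff:
                    raise ValueError(
                        f"{self.name}: stoichiometric coefficient for {species} "
                        f"must be a positive integer, got {coeff}"
                    )
                if not k > 0:
                    raise ValueError(
                        f"{self.name}: binding constant for {species} must be "
                        f"positive, got {k}"
                    )


@dataclass(frozen=True)
class TransporterSpec:
    """Mechanism class, binding constants and charge coupling of one carrier."""

    name: str
    mechanism: str  # uniporter | symporter | antiporter
    species_A: str
    species_B: str | None = None
    K_Ae: float = 1.0
    K_Am: float = 1.0
    K_Be: float = 1.0
    K_Bm: float = 1.0
    tmax_key: str = ""
    #: net positive charge moved into the matrix per forward turnover
    charge: float = 0.0
    #: protons cotransported into the matrix per forward turnover
    n_protons_in: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("uniporter", "symporter", "antiporter"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "uniporter" and self.species_B is not None:
            raise ValueError(f"{self.name}: uniporter carries exactly one species")
        if self.mechanism != "uniporter" and self.species_B is None:
            raise ValueError(f"{self.name}: {self.mechanism} needs species_B")
        for k in (self.K_Ae, self.K_Am, self.K_Be, self.K_Bm):
            if not k > 0:
                raise ValueError(f"{self.name}: binding constants must be positive")


def _check_nonneg(*concs: float) -> None:
    for c in concs:
        if c < 0:
            raise ValueError(f"negative concentration: {c}")


def reaction_core(
    subs: Sequence[tuple[float, int, float]],
    prods: Sequence[tuple[float, int, float]],
    vmax: float,
    keq: float,
) -> float:
    """Scalar core of the generalized reaction law.

    ``subs`` / ``prods`` are sequences of ``(concentration, coeff, K)``.
    numerator = (V_maxf / prod K_Si^ai) (prod C_Si^ai - prod C_Pj^bj / K'eq);
    denominator = prod_i (1 + C_Si^ai / K_Si^ai) * prod_j (1 + C_Pj^bj / K_Pj^bj).
    """
    fwd = 1.0
    kprod = 1.0
    denom = 1.0
    for c, coeff, k in subs:
        ca = c**coeff
        ka = k**coeff
        fwd *= ca
        kprod *= ka
        denom *= 1.0 + ca / ka
    rev = 1.0
    for c, coeff, k in prods:
        cb = c**coeff
        rev *= cb
        denom *= 1.0 + cb / k**coeff
    return (vmax / kprod) * (fwd - rev / keq) / denom


def reaction_flux(
    spec: ReactionSpec,
    concentrations: Mapping[str, float],
    vmax: float,
    keq: float,
) -> float:
    """Net flux (nmol/min/mg) of a multisubstrate reaction (see reaction_core)."""
    subs = []
    for species, coeff, k in spec.substrates:
        c = concentrations[species]
        _check_nonneg(c)
        subs.append((c, coeff, k))
    prods = []
    for species, coeff, k in spec.products:
        c = concentrations[species]
        _check_nonneg(c)
        prods.append((c, coeff, k))
    return reaction_core(subs, prods, vmax, keq)


def uniporter_flux(
    spec: TransporterSpec,
    C_Ae: float,
    C_Am: float,
    tmax: float,
    theta: float = 1.0,
) -> float:
    """Facilitated-diffusion carrier flux, positive into the matrix.

    ``theta`` biases the equilibrium point (proton-coupled carriers): the
    flux is zero iff C_Am = theta * C_Ae.
    """
    _check_nonneg(C_Ae, C_Am)
    num = (theta * C_Ae - C_Am) / spec.K_Ae
    denom = 1.0 + C_Ae / spec.K_Ae + C_Am / spec.K_Am
    return tmax * num / denom


def symporter_flux(
    spec: TransporterSpec,
    C_Ae: float,
    C_Be: float,
    C_Am: float,
    C_Bm: float,
    tmax: float,
    theta: float = 1.0,
) -> float:
    """Cotransporter A_e + B_e <-> A_m + B_m; zero iff C_Am*C_Bm = theta*C_Ae*C_Be."""
    _check_nonneg(C_Ae, C_Be, C_Am, C_Bm)
    num = (theta * C_Ae * C_Be - C_Am * C_Bm) / (spec.K_Ae * spec.K_Be)
    denom = (
        1.0
        + C_Ae / spec.K_Ae
        + C_Be / spec.K_Be
        + C_Am / spec.K_Am
        + C_Bm / spec.K_Bm
        + C_Ae * C_Be / (spec.K_Ae * spec.K_Be)
        + C_Am * C_Bm / (spec.K_Am * spec.K_Bm)
    )
    return tmax * num / denom


def antiporter_flux(
    spec: TransporterSpec,
    C_Ae: float,
    C_Bm: float,
    C_Am: float,
    C_Be: float,
    tmax: float,
    theta: float = 1.0,
    K_Ae: float | None = None,
    K_Am: float | None = None,
) -> float:
    """Exchanger A_e + B_m <-> A_m + B_e; zero iff C_Am*C_Be = theta*C_Ae*C_Bm.

    ``K_Ae`` / ``K_Am`` override the spec's A-side binding constants; the
    regulated dicarboxylate carriers use this to substitute an apparent
    binding constant into every A term.

    The electrochemical bias ``theta`` divides the reverse term (the whole
    potential dependence is assigned to the reverse translocation step), so
    the forward mode keeps its Michaelis saturation while the equilibrium
    point is shifted to C_Am*C_Be = theta*C_Ae*C_Bm.
    """
    _check_nonneg(C_Ae, C_Bm, C_Am, C_Be)
    kae = spec.K_Ae if K_Ae is None else K_Ae
    kam = spec.K_Am if K_Am is None else K_Am
    num = (C_Ae * C_Bm - C_Am * C_Be / theta) / (kae * spec.K_Bm)
    denom = (
        1.0
        + C_Ae / kae
        + C_Be / spec.K_Be
        + C_Am / kam
        + C_Bm / spec.K_Bm
        + C_Ae * C_Bm / (kae * spec.K_Bm)
        + C_Am * C_Be / (kam * spec.K_Be)
    )
    return tmax * num / denom
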