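"""Concrete flux catalog: 14 reactions and 10 carriers of the inner membrane.

TCA-cycle dehydrogenases, the electron-transport complexes, ATP synthase, the
metabolite and phosphate carriers, the adenine nucleotide translocase and the
proton leak are each expressed through the generic thermodynamically
constrained laws of :mod:`mitoresp.ratelaws`.  Membrane-potential-coupled
steps (CI, CIII, CIV, CV, ANT, GAE, H+ leak) carry an explicit per-turnover
charge ledger; their apparent equilibrium constants include the
electrochemical proton cost so every flux vanishes exactly at zero net
driving force including the membrane-potential term.

Succinate-pathway regulation: matrix malate competitively inhibits the
succinate/phosphate carrier (DCCS), matrix succinate competitively inhibits
the malate/phosphate carrier (DCCM), and succinate dehydrogenase is inhibited
by matrix oxaloacetate and stimulated by matrix malate, all through apparent
succinate binding constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping

import numpy as np

from .ratelaws import (
    ReactionSpec,
    TransporterSpec,
    antiporter_flux,
    reaction_core,
    uniporter_flux,
)
from .states import IDX
from .thermo import FARADAY, ThermoContext, apparent_keq

__all__ = [
    "FLUX_NAMES",
    "PSI_CHARGE",
    "RegulationParams",
    "FluxCatalog",
    "dccs_flux",
    "dccm_flux",
    "sdh_flux",
    "hleak_flux",
    "civ_flux",
    "default_catalog",
]

#: Canonical flux ordering; names match the Vmax/Tmax parameter keys.
FLUX_NAMES: tuple[str, ...] = (
    "PDH", "CITS", "ICDH", "AKGDH", "SCAS", "NDK", "FH", "MDH", "GOT",
    "CI", "CII", "CIII", "CIV", "CV",
    "PYRH", "GLUH", "DCCS", "DCCM", "TCC", "OME", "GAE", "ANT", "PIC", "HLEAK",
)

FLUX_INDEX = {name: i for i, name in enumerate(FLUX_NAMES)}

#: contribution of each flux to d(dPsi)/dt, in elementary charges moved
#: out of the matrix per forward turnover (positive charges exported raise
#: the membrane potential).
PSI_CHARGE: dict[str, float] = {
    "CI": 4.0, "CIII": 2.0, "CIV": 8.0,
    "CV": -3.0, "GAE": -1.0, "ANT": -1.0, "HLEAK": -1.0,
}


@dataclass(frozen=True)
class RegulationParams:
    """Regulatory binding constants of the succinate pathway, mM."""

    K_MAL_dccs: float
    K_SUC_dccm: float
    K_OXA_sdh: float
    K_MAL_sdh: float

    def __post_init__(self) -> None:
        for f in ("K_MAL_dccs", "K_SUC_dccm", "K_OXA_sdh", "K_MAL_sdh"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# Regulated flux operations (public, scalar signatures)
# ---------------------------------------------------------------------------

def dccs_flux(
    C_SUCe: float,
    C_SUCm: float,
    C_Pie: float,
    C_Pim: float,
    C_MALm: float,
    params: RegulationParams,
    tmax: float = 1.0,
    K_SUC: float = 1.0,
    K_Pi: float = 1.5,
) -> float:
    """Succinate/phosphate antiporter with malate inhibition.

    The apparent succinate binding constant K'_SUC = K_SUC (1 + MAL_m/K_MAL)
    replaces K_SUC in all four succinate terms; positive flux imports
    succinate and exports matrix phosphate.
    """
    for c in (C_SUCe, C_SUCm, C_Pie, C_Pim, C_MALm):
        if c < 0:
            raise ValueError("negative concentration")
    k_suc_app = K_SUC * (1.0 + C_MALm / params.K_MAL_dccs)
    spec = TransporterSpec(
        "DCCS", "antiporter", "SUC", "Pi",
        K_Ae=k_suc_app, K_Am=k_suc_app, K_Be=K_Pi, K_Bm=K_Pi,
    )
    return antiporter_flux(spec, C_SUCe, C_Pim, C_SUCm, C_Pie, tmax)


def dccm_flux(
    C_MALe: float,
    C_MALm: float,
    C_Pie: float,
    C_Pim: float,
    C_SUCm: float,
    params: RegulationParams,
    tmax: float = 1.0,
    K_MAL: float = 0.7,
    K_Pi: float = 1.5,
) -> float:
    """Malate/phosphate antiporter with succinate inhibition.

    K'_MAL = K_MAL (1 + SUC_m/K_SUC) in all malate terms.  Negative flux is
    the carrier's reverse mode: malate efflux with phosphate influx.
    """
    for c in (C_MALe, C_MALm, C_Pie, C_Pim, C_SUCm):
        if c < 0:
            raise ValueError("negative concentration")
    k_mal_app = K_MAL * (1.0 + C_SUCm / params.K_SUC_dccm)
    spec = TransporterSpec(
        "DCCM", "antiporter", "MAL", "Pi",
        K_Ae=k_mal_app, K_Am=k_mal_app, K_Be=K_Pi, K_Bm=K_Pi,
    )
    return antiporter_flux(spec, C_MALe, C_Pim, C_MALm, C_Pie, tmax)


def sdh_flux(
    C_SUCm: float,
    C_FUMm: float,
    C_UQm: float,
    C_UQH2m: float,
    C_OXAm: float,
    C_MALm: float,
    params: RegulationParams,
    keq_sdh: float,
    vmax: float = 1.0,
    K_SUC: float = 0.5,
    K_FUM: float = 0.3,
    K_UQ: float = 0.3,
    K_UQH2: float = 0.3,
) -> float:
    """Succinate dehydrogenase (complex II) with OXA inhibition / MAL stimulation.

    K''_SUC = K_SUC (1 + OXA_m/K_OXA) / (1 + MAL_m/K_MAL) replaces the
    intrinsic succinate binding constant.  Succinate and fumarate compete for
    the dicarboxylate site and the two quinone species for the quinone site,
    so the denominator is the two-bracket shared-site form

        (1 + SUC/K'' + FUM/K_FUM)(1 + UQ/K_UQ + UQH2/K_UQH2).
    """
    for c in (C_SUCm, C_FUMm, C_UQm, C_UQH2m, C_OXAm, C_MALm):
        if c < 0:
            raise ValueError("negative concentration")
    k_suc_app = (
        K_SUC * (1.0 + C_OXAm / params.K_OXA_sdh) / (1.0 + C_MALm / params.K_MAL_sdh)
    )
    num = (vmax / (k_suc_app * K_UQ)) * (
        C_SUCm * C_UQm - C_FUMm * C_UQH2m / keq_sdh
    )
    denom = (1.0 + C_SUCm / k_suc_app + C_FUMm / K_FUM) * (
        1.0 + C_UQm / K_UQ + C_UQH2m / K_UQH2
    )
    return num / denom


def hleak_flux(
    delta_psi_mV: float,
    tmax: float,
    alpha: float,
    ctx: ThermoContext,
    x_ref: float = 0.0,
) -> float:
    """Proton leak across the inner membrane, positive into the matrix.

    Exponential conductance in the proton-motive force: zero at zero pmf and
    strongly supralinear at physiological potentials, as measured leak
    kinetics are.  ``alpha`` sets the steepness and ``x_ref`` (a reference
    pmf in RT units) the potential around which the conductance turns on.
    """
    u = FARADAY * delta_psi_mV * 1e-3 + ctx.RT * math.log(10.0) * ctx.delta_pH
    x = u / ctx.RT
    scale = math.exp(-alpha * x_ref)
    return tmax * (math.exp(alpha * (x - x_ref)) - scale)


def civ_flux(
    C_CytCred: float,
    C_CytCox: float,
    C_O2: float,
    delta_psi_mV: float,
    vmax: float,
    K_CytC: float,
    K_O2: float,
    keq_chem: float,
    ctx: ThermoContext,
    o2_ref: float = 1.0,
) -> float:
    """Cytochrome c oxidase; one turnover = one O2 reduced (4 cytochromes c).

    The turnover convention makes the complex IV flux identical to the
    oxygen consumption rate, the quantity the respirometer measures.  The
    law is first-order in reduced and oxidized cytochrome c (electrons are
    delivered one at a time, so turnover saturates in single-site binding)
    with Michaelis saturation in oxygen and eight charges exported per
    turnover.  The quarter-power driving term puts the zero-flux point
    exactly at the four-electron thermodynamic equilibrium
    (CytCox/CytCred)^4 = K'eq * O2.
    """
    if min(C_CytCred, C_CytCox, C_O2) < 0:
        raise ValueError("negative concentration")
    u = FARADAY * delta_psi_mV * 1e-3 + ctx.RT * math.log(10.0) * ctx.delta_pH
    kapp = keq_chem * math.exp(-8.0 * u / ctx.RT)
    x = C_CytCred / K_CytC
    y = C_CytCox / K_CytC
    q = (C_O2 / o2_ref) ** 0.25
    num = x * q - y / kapp**0.25
    denom = 1.0 + x + y
    return vmax * (num / denom) * (C_O2 / (C_O2 + K_O2))


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

def _rxn_from_dict(name: str, d: Mapping) -> ReactionSpec:
    return ReactionSpec(
        name=name,
        substrates=tuple((s, int(a), float(k)) for s, a, k in d["substrates"]),
        products=tuple((s, int(b), float(k)) for s, b, k in d["products"]),
        delta_rG0=float(d["dG0"]),
        n_protons=int(d.get("nH", 0)),
        vmax_key=d.get("vmax_key", name),
        n_charge=float(d.get("charge", 0.0)),
    )


class FluxCatalog:
    """The 24 named flux functions, addressable by name, built from the
    intrinsic kinetic-constants catalog."""

    def __init__(self, config: Mapping):
        self._config = config
        self.reactions: dict[str, ReactionSpec] = {}
        for name, d in config["reactions"].items():
            if name == "CIV":
                continue
            self.reactions[name] = _rxn_from_dict(name, d)
        self.civ_params = dict(config["reactions"]["CIV"])
        self.transporters: dict[str, Mapping] = dict(config["transporters"])
        self.constants = dict(config["constants"])
        self.co2_product = {
            name: bool(d.get("co2_product", False))
            for name, d in config["reactions"].items()
        }

    @classmethod
    def from_json(cls, path=None) -> "FluxCatalog":
        if path is None:
            text = resources.files("mitoresp.data").joinpath("kinetics.json").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        return cls(json.loads(text))

    def transporter_spec(self, name: str) -> TransporterSpec:
        d = self.transporters[name]
        return TransporterSpec(
            name=name,
            mechanism=d["mechanism"] if d["mechanism"] != "leak" else "uniporter",
            species_A=d.get("species_A", "H"),
            species_B=d.get("species_B"),
            K_Ae=float(d.get("K_Ae", 1.0)),
            K_Am=float(d.get("K_Am", 1.0)),
            K_Be=float(d.get("K_Be", 1.0)),
            K_Bm=float(d.get("K_Bm", 1.0)),
            tmax_key=d.get("tmax_key", name),
            charge=float(d.get("charge", 0.0)),
        )

    # -- fast evaluator -----------------------------------------------------

    def evaluator(
        self,
        vmax: Mapping[str, float],
        tmax: Mapping[str, float],
        regulation: RegulationParams,
        ctx: ThermoContext,
    ) -> Callable[[np.ndarray, bool], np.ndarray]:
        """Build a closure mapping a state array to the 24-entry flux vector.

        State values are clipped at zero before rate evaluation (stiff-solver
        transients can undershoot slightly); the rotenone flag zeroes complex
        I's maximal rate and leaves everything else untouched.
        """
        RT = ctx.RT
        ln10_dpH = math.log(10.0) * ctx.delta_pH
        theta_H = 10.0 ** ctx.delta_pH  # proton-symport bias, external->matrix
        F = FARADAY
        co2 = float(self.constants["co2_mM"])
        alpha = float(self.transporters["HLEAK"]["alpha"])
        leak_x_ref = float(self.transporters["HLEAK"].get("x_ref", 0.0))
        o2_ref = float(self.constants["o2_ref_mM"])

        irreversible = {
            name
            for name, d in self._config["reactions"].items()
            if d.get("irreversible")
        }
        # reaction tables: (flux_idx, vmax, subs(idx,coeff,K), prods, keq_chem,
        # n_charge, one_way)
        rxn_rows = []
        for name, spec in self.reactions.items():
            keq = apparent_keq(spec.delta_rG0, spec.n_protons, ctx.pH_matrix, ctx)
            # exp(-dG0/RT) refers to the 1 M standard state; concentrations are
            # mM, so the constant is rescaled by the molecularity difference
            delta_n = sum(b for _, b, _ in spec.products) - sum(
                a for _, a, _ in spec.substrates
            )
            if self.co2_product.get(name):
                delta_n += 1
                keq = keq / co2  # fixed CO2 folded into the equilibrium constant
            keq = keq * 1000.0**delta_n
            rxn_rows.append(
                (
                    FLUX_INDEX[name],
                    float(vmax[name]),
                    tuple((IDX[s], a, k) for s, a, k in spec.substrates),
                    tuple((IDX[s], b, k) for s, b, k in spec.products),
                    keq,
                    spec.n_charge,
                    name in irreversible,
                )
            )

        civ = self.civ_params
        civ_vmax = float(vmax["CIV"])
        civ_keq = apparent_keq(float(civ["dG0"]), int(civ["nH"]), ctx.pH_matrix, ctx)
        K_cytc = float(civ["K_CytC"])
        K_O2 = float(civ["K_O2"])

        tr = {name: self.transporter_spec(name) for name in self.transporters}
        reg = regulation
        t_dccs, t_dccm = float(tmax["DCCS"]), float(tmax["DCCM"])
        t_pyrh, t_gluh, t_pic = (float(tmax[k]) for k in ("PYRH", "GLUH", "PIC"))
        t_tcc, t_ome, t_gae, t_ant = (
            float(tmax[k]) for k in ("TCC", "OME", "GAE", "ANT")
        )
        t_leak = float(tmax["HLEAK"])
        i_sdh = FLUX_INDEX["CII"]
        sdh = self.reactions["CII"]
        sdh_keq = apparent_keq(sdh.delta_rG0, sdh.n_protons, ctx.pH_matrix, ctx)
        sdh_Ks = {s: k for s, _, k in sdh.substrates} | {s: k for s, _, k in sdh.products}
        v_sdh = float(vmax["CII"])
        ix = IDX
        n_flux = len(FLUX_NAMES)

        i_ci = FLUX_INDEX["CI"]
        i_dpsi = ix["dpsi"]
        isfinite = math.isfinite
        exp = math.exp

        # scalar index shortcuts for the inlined carrier laws
        iSUCe, iSUCm, iPie, iPim, iMALe, iMALm = (
            ix[s] for s in ("SUC_e", "SUC_m", "Pi_e", "Pi_m", "MAL_e", "MAL_m")
        )
        iCITe, iCITm, iAKGe, iAKGm = (ix[s] for s in ("CIT_e", "CIT_m", "AKG_e", "AKG_m"))
        iGLUe, iGLUm, iASPe, iASPm = (ix[s] for s in ("GLU_e", "GLU_m", "ASP_e", "ASP_m"))
        iADPe, iADPm, iATPe, iATPm = (ix[s] for s in ("ADP_e", "ADP_m", "ATP_e", "ATP_m"))
        iPYRe, iPYRm = ix["PYR_e"], ix["PYR_m"]
        iCred, iCox, iO2 = ix["CytCred_i"], ix["CytCox_i"], ix["O2_e"]
        iSUCm2, iFUMm, iUQm, iUQH2m, iOXAm = (
            ix[s] for s in ("SUC_m", "FUM_m", "UQ_m", "UQH2_m", "OXA_m")
        )
        kS_suc, kS_fum = sdh_Ks["SUC_m"], sdh_Ks["FUM_m"]
        kS_uq, kS_uqh2 = sdh_Ks["UQ_m"], sdh_Ks["UQH2_m"]
        k_oxa, k_mal_sdh = reg.K_OXA_sdh, reg.K_MAL_sdh
        k_mal_dccs, k_suc_dccm = reg.K_MAL_dccs, reg.K_SUC_dccm
        dccs_kpi, dccm_kmal, dccm_kpi = (
            tr["DCCS"].K_Be, tr["DCCM"].K_Ae, tr["DCCM"].K_Be,
        )
        dccs_ksuc = tr["DCCS"].K_Ae
        kp_pyr_e, kp_pyr_m = tr["PYRH"].K_Ae, tr["PYRH"].K_Am
        kp_glu_e, kp_glu_m = tr["GLUH"].K_Ae, tr["GLUH"].K_Am
        kp_pi_e, kp_pi_m = tr["PIC"].K_Ae, tr["PIC"].K_Am
        tcc_kc, tcc_km = tr["TCC"].K_Ae, tr["TCC"].K_Be
        ome_ka, ome_km = tr["OME"].K_Ae, tr["OME"].K_Be
        gae_kg, gae_ka = tr["GAE"].K_Ae, tr["GAE"].K_Be
        ant_kae, ant_kam = tr["ANT"].K_Ae, tr["ANT"].K_Am
        ant_kbe, ant_kbm = tr["ANT"].K_Be, tr["ANT"].K_Bm
        civ_ko2_q = 1.0 / o2_ref
        leak_scale0 = exp(-alpha * leak_x_ref)

        def _anti(ae, bm, am, be, kae, kbe, kam, kbm, t, theta):
            num = (ae * bm - am * be / theta) / (kae * kbm)
            den = (1.0 + ae / kae + be / kbe + am / kam + bm / kbm
                   + ae * bm / (kae * kbm) + am * be / (kam * kbe))
            return t * num / den

        def fluxes(y: np.ndarray, rotenone: bool = False) -> np.ndarray:
            c = [v if v > 0.0 else 0.0 for v in y.tolist()]
            dpsi = y[i_dpsi] if isinstance(y, list) else float(y[i_dpsi])
            x_psi = F * dpsi * 1e-3 / RT
            u_over_RT = x_psi + ln10_dpH
            J = [0.0] * n_flux

            for fidx, vm, subs, prods, keq, n_charge, one_way in rxn_rows:
                if rotenone and fidx == i_ci:
                    continue
                if fidx == i_sdh:
                    continue  # handled with regulation below
                if n_charge:
                    keq = keq * exp(-n_charge * u_over_RT)
                flux = reaction_core(
                    [(c[i], a, k) for i, a, k in subs],
                    [(c[i], b, k) for i, b, k in prods],
                    vm,
                    keq,
                )
                # decarboxylating dehydrogenase complexes do not run backward
                J[fidx] = flux if (flux > 0.0 or not one_way) else 0.0

            # SDH / complex II with OXA inhibition and MAL stimulation (shared
            # dicarboxylate and quinone sites)
            kpp = kS_suc * (1.0 + c[iOXAm] / k_oxa) / (1.0 + c[iMALm] / k_mal_sdh)
            J[i_sdh] = (v_sdh / (kpp * kS_uq)) * (
                c[iSUCm2] * c[iUQm] - c[iFUMm] * c[iUQH2m] / sdh_keq
            ) / (
                (1.0 + c[iSUCm2] / kpp + c[iFUMm] / kS_fum)
                * (1.0 + c[iUQm] / kS_uq + c[iUQH2m] / kS_uqh2)
            )

            # complex IV (per-O2 turnover; first order in each cytc species)
            kapp = civ_keq * exp(-8.0 * u_over_RT)
            xr = c[iCred] / K_cytc
            yo = c[iCox] / K_cytc
            o2 = c[iO2]
            J[FLUX_INDEX["CIV"]] = (
                civ_vmax
                * (xr * (o2 * civ_ko2_q) ** 0.25 - yo / kapp**0.25)
                / (1.0 + xr + yo)
                * (o2 / (o2 + K_O2))
            )

            # proton-coupled uniporters (equilibrium biased by the pH gradient)
            J[FLUX_INDEX["PYRH"]] = t_pyrh * (theta_H * c[iPYRe] - c[iPYRm]) / (
                kp_pyr_e * (1.0 + c[iPYRe] / kp_pyr_e + c[iPYRm] / kp_pyr_m)
            )
            J[FLUX_INDEX["GLUH"]] = t_gluh * (theta_H * c[iGLUe] - c[iGLUm]) / (
                kp_glu_e * (1.0 + c[iGLUe] / kp_glu_e + c[iGLUm] / kp_glu_m)
            )
            J[FLUX_INDEX["PIC"]] = t_pic * (theta_H * c[iPie] - c[iPim]) / (
                kp_pi_e * (1.0 + c[iPie] / kp_pi_e + c[iPim] / kp_pi_m)
            )

            # regulated dicarboxylate carriers
            kps = dccs_ksuc * (1.0 + c[iMALm] / k_mal_dccs)
            J[FLUX_INDEX["DCCS"]] = _anti(
                c[iSUCe], c[iPim], c[iSUCm], c[iPie],
                kps, dccs_kpi, kps, dccs_kpi, t_dccs, 1.0,
            )
            kpm = dccm_kmal * (1.0 + c[iSUCm] / k_suc_dccm)
            J[FLUX_INDEX["DCCM"]] = _anti(
                c[iMALe], c[iPim], c[iMALm], c[iPie],
                kpm, dccm_kpi, kpm, dccm_kpi, t_dccm, 1.0,
            )

            # neutral exchangers
            J[FLUX_INDEX["TCC"]] = _anti(
                c[iCITe], c[iMALm], c[iCITm], c[iMALe],
                tcc_kc, tcc_km, tcc_kc, tcc_km, t_tcc, 1.0,
            )
            J[FLUX_INDEX["OME"]] = _anti(
                c[iAKGe], c[iMALm], c[iAKGm], c[iMALe],
                ome_ka, ome_km, ome_ka, ome_km, t_ome, 1.0,
            )

            # electrogenic exchangers: the reverse term carries the potential
            theta_psi = exp(x_psi)
            J[FLUX_INDEX["GAE"]] = _anti(
                c[iGLUe], c[iASPm], c[iGLUm], c[iASPe],
                gae_kg, gae_ka, gae_kg, gae_ka, t_gae, theta_psi * theta_H,
            )
            J[FLUX_INDEX["ANT"]] = _anti(
                c[iADPe], c[iATPm], c[iADPm], c[iATPe],
                ant_kae, ant_kbe, ant_kam, ant_kbm, t_ant, theta_psi,
            )

            # proton leak (supralinear in the proton-motive force)
            J[FLUX_INDEX["HLEAK"]] = t_leak * (
                exp(alpha * (u_over_RT - leak_x_ref)) - leak_scale0
            )

            total = 0.0
            for v in J:
                total += v
            if not isfinite(total):
                bad = [FLUX_NAMES[i] for i, v in enumerate(J) if not isfinite(v)]
                raise FloatingPointError(f"non-finite flux(es): {bad}")
            return np.asarray(J)

        return fluxes


def default_catalog() -> FluxCatalog:
    """The catalog shipped with the package."""
    return FluxCatalog.from_json()
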