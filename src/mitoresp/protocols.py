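"""In-silico respirometry: event schedules, simulation and derived observables.

Two closed-chamber protocols are encoded.  Protocol A (used for fitting):
substrate addition followed by six sequential ADP doses (25, 50, 75, 100,
150, 250 uM).  Protocol B (validation): substrate addition followed by a
single ADP dose (200 uM heart, 100 uM kidney).  Additions are instantaneous
jumps in buffer concentrations (microlitre additions into a millilitre
chamber) implemented as integration restarts; rotenone is a flag that zeroes
complex I from its event time onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluxes import FLUX_NAMES, FluxCatalog, default_catalog
from .model import initial_state, integrate, ocr_from_fluxes
from .params import Compartments, TissueParameterSet
from .states import IDX
from .thermo import ThermoContext

__all__ = [
    "SUBSTRATE_COMBOS",
    "Event",
    "EventSchedule",
    "SimulationResult",
    "RespiratoryFeatures",
    "protocol_A",
    "protocol_B",
    "run_schedule",
    "simulate_protocol",
    "extract_features",
    "redox_ratios",
    "leak_scan",
]

SUBSTRATE_COMBOS = ("PM", "GM", "AM", "SUC", "SUC+ROT")

# Rotenone is in the chamber before the mitochondria: complex I binds it
# within seconds, so the block is active from the start of the recording.
ROT_TIME_MIN = 0.0


@dataclass(frozen=True)
class Event:
    time: float  # min
    kind: str  # add_substrate | add_ADP | add_rotenone
    payload: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EventSchedule:
    tissue: str
    substrate: str
    protocol: str
    protein_density_mg_per_mL: float
    events: tuple[Event, ...]
    t_end: float

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if self.events and self.t_end <= self.events[-1].time:
            raise ValueError("t_end must exceed the last event time")

    @property
    def adp_times(self) -> list[float]:
        return [e.time for e in self.events if e.kind == "add_ADP"]

    @property
    def adp_doses(self) -> list[float]:
        return [e.payload["ADP_e"] for e in self.events if e.kind == "add_ADP"]


def _schedule(tissue, substrate, protocol, doses, config) -> EventSchedule:
    if substrate not in SUBSTRATE_COMBOS:
        raise ValueError(f"unknown substrate combo {substrate!r}; choose from {SUBSTRATE_COMBOS}")
    proto = config["protocol"]
    t_sub = float(proto["substrate_time_min"])
    spacing = float(proto["adp_spacing_min"])
    first_delay = float(proto.get("first_adp_delay_min", spacing))
    rho = float(config["protein_density_mg_per_mL"][protocol][tissue])
    events: list[Event] = []
    if substrate == "SUC+ROT":
        events.append(Event(ROT_TIME_MIN, "add_rotenone", {"ROT_uM": 0.5}))
    events.append(Event(t_sub, "add_substrate", dict(proto["substrates"][substrate])))
    t = t_sub + first_delay
    for i, dose in enumerate(doses):
        if i:
            t += spacing
        events.append(Event(t, "add_ADP", {"ADP_e": float(dose)}))
    t_end = t + float(proto["tail_min"])
    return EventSchedule(tissue, substrate, protocol, rho, tuple(events), t_end)


def protocol_A(tissue: str, substrate: str, config: dict | None = None) -> EventSchedule:
    """Sequential-ADP protocol: 0.05 mg/mL heart (0.2 mg/mL kidney) protein,
    one substrate addition, then ADP doses 25, 50, 75, 100, 150, 250 uM."""
    if config is None:
        from .io import load_model_config

        config = load_model_config()
    doses = config["protocol"]["adp_doses_A_mM"]
    return _schedule(tissue, substrate, "A", doses, config)


def protocol_B(tissue: str, substrate: str, config: dict | None = None) -> EventSchedule:
    """Single-ADP validation protocol: 0.1 mg/mL heart (0.2 mg/mL kidney)
    protein, one substrate addition, one ADP dose (200 uM heart, 100 uM kidney)."""
    if config is None:
        from .io import load_model_config

        config = load_model_config()
    dose = config["protocol"]["adp_dose_B_mM"][tissue]
    return _schedule(tissue, substrate, "B", [dose], config)


@dataclass
class SimulationResult:
    """Trajectory plus flux traces and the derived observables."""

    schedule: EventSchedule
    t: np.ndarray
    y: np.ndarray  # (N_STATES, n)
    fluxes: np.ndarray  # (n_flux, n)
    ocr: np.ndarray
    dpsi: np.ndarray
    nadh_ratio: np.ndarray
    uqh2_ratio: np.ndarray
    cytc_ratio: np.ndarray

    def state_series(self, name: str) -> np.ndarray:
        return self.y[IDX[name], :]

    def flux_series(self, name: str) -> np.ndarray:
        return self.fluxes[FLUX_NAMES.index(name), :]


@dataclass(frozen=True)
class RespiratoryFeatures:
    """State-2 mean OCR, per-dose state-3 peak OCRs, and the control index."""

    substrate: str
    adp_doses: tuple[float, ...]
    state2_ocr: float
    state3_peaks: tuple[float, ...]

    @property
    def rci(self) -> float:
        if self.state2_ocr <= 0:
            raise ZeroDivisionError("RCI undefined: nonpositive state-2 OCR")
        return max(self.state3_peaks) / self.state2_ocr


def redox_ratios(state: np.ndarray | dict) -> tuple[float, float, float]:
    """(NADH, UQH2, reduced cytochrome c) as fractions of their pools."""
    if isinstance(state, dict):
        get = state.__getitem__
    else:
        get = lambda n: float(state[IDX[n]])  # noqa: E731
    nadh = get("NADH_m") / (get("NADH_m") + get("NAD_m"))
    uqh2 = get("UQH2_m") / (get("UQH2_m") + get("UQ_m"))
    cytc = get("CytCred_i") / (get("CytCred_i") + get("CytCox_i"))
    return nadh, uqh2, cytc


def run_schedule(
    tissue: TissueParameterSet,
    schedule: EventSchedule,
    ctx: ThermoContext | None = None,
    catalog: FluxCatalog | None = None,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-10,
    dt_out: float = 0.01,
    leak_scale: float = 1.0,
    y0: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate a full event schedule and assemble observables.

    ``leak_scale`` multiplies the maximal H+ leak rate (pathology scans).
    """
    ctx = ctx or ThermoContext()
    catalog = catalog or default_catalog()
    if leak_scale != 1.0:
        tissue = tissue.scale_rate("HLEAK", leak_scale)
    comp = Compartments(protein_density_mg_per_mL=schedule.protein_density_mg_per_mL)
    if y0 is None:
        y0 = initial_state(tissue)
    y = np.asarray(y0, dtype=float).copy()

    times = [0.0] + [e.time for e in schedule.events] + [schedule.t_end]
    rotenone = False
    seg_t: list[np.ndarray] = []
    seg_y: list[np.ndarray] = []
    evaluator = catalog.evaluator(tissue.vmax, tissue.tmax, tissue.regulation, ctx)

    for k in range(len(times) - 1):
        t0, t1 = times[k], times[k + 1]
        if t1 <= t0:  # instantaneous event at the start of the recording
            ev = schedule.events[k]
            if ev.kind == "add_rotenone":
                rotenone = True
            else:
                for species, dose in ev.payload.items():
                    y[IDX[species]] += dose
            continue
        n_pts = max(int(round((t1 - t0) / dt_out)), 2) + 1
        t_eval = np.linspace(t0, t1, n_pts)
        traj = integrate(
            y, tissue, (t0, t1), comp, ctx, catalog,
            rotenone=rotenone, rtol=rtol, atol=atol, t_eval=t_eval,
        )
        seg_t.append(traj.t)
        seg_y.append(traj.y)
        y = traj.y[:, -1].copy()
        if k < len(schedule.events):
            ev = schedule.events[k]
            if ev.kind == "add_rotenone":
                rotenone = True
            else:
                for species, dose in ev.payload.items():
                    y[IDX[species]] += dose

    t = np.concatenate(seg_t)
    ys = np.concatenate(seg_y, axis=1)

    # flux traces; rotenone applies from its event time onward
    rot_time = next(
        (e.time for e in schedule.events if e.kind == "add_rotenone"), np.inf
    )
    J = np.empty((len(FLUX_NAMES), t.size))
    for i in range(t.size):
        J[:, i] = evaluator(ys[:, i], t[i] >= rot_time)

    ocr = ocr_from_fluxes(J.T, catalog)
    nadh, uqh2, cytc = (np.empty(t.size) for _ in range(3))
    for i in range(t.size):
        nadh[i], uqh2[i], cytc[i] = redox_ratios(ys[:, i])
    return SimulationResult(
        schedule=schedule, t=t, y=ys, fluxes=J, ocr=ocr,
        dpsi=ys[IDX["dpsi"], :], nadh_ratio=nadh, uqh2_ratio=uqh2, cytc_ratio=cytc,
    )


def simulate_protocol(
    tissue: TissueParameterSet,
    substrate: str,
    protocol: str = "A",
    **kwargs,
) -> SimulationResult:
    """Convenience wrapper: build the schedule and run it."""
    sched = protocol_A(tissue.tissue, substrate) if protocol == "A" else protocol_B(
        tissue.tissue, substrate
    )
    return run_schedule(tissue, sched, **kwargs)


def extract_features(
    result: SimulationResult,
    schedule: EventSchedule | None = None,
    state2_window: float | None = None,
) -> RespiratoryFeatures:
    """State-2 mean over a window before the first ADP dose and the per-dose
    peak OCR in each inter-event interval."""
    schedule = schedule or result.schedule
    if state2_window is None:
        from .io import load_model_config

        state2_window = float(load_model_config()["protocol"]["state2_window_min"])
    adp_times = schedule.adp_times
    if not adp_times:
        raise ValueError("schedule has no ADP events")
    t = result.t
    if t[-1] < adp_times[-1]:
        raise ValueError("simulation does not cover all scheduled events")
    w0 = adp_times[0] - state2_window
    mask2 = (t >= w0) & (t < adp_times[0])
    if not mask2.any():
        raise ValueError("empty state-2 window")
    state2 = float(np.mean(result.ocr[mask2]))

    bounds = adp_times + [schedule.t_end]
    peaks = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mask = (t > a) & (t <= b)
        if not mask.any():
            raise ValueError(f"empty peak window ({a}, {b}]")
        peaks.append(float(np.max(result.ocr[mask])))
    return RespiratoryFeatures(
        substrate=schedule.substrate,
        adp_doses=tuple(schedule.adp_doses),
        state2_ocr=state2,
        state3_peaks=tuple(peaks),
    )


def leak_scan(
    tissue: TissueParameterSet,
    substrate: str,
    scales_percent=(100, 300, 500, 700, 900),
    ctx: ThermoContext | None = None,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-10,
) -> list[dict]:
    """Protocol-B pathology scan over the maximal H+ leak activity.

    Returns one record per scale with respiratory features and the state-2 /
    state-3 redox ratios and membrane potential.
    """
    sched = protocol_B(tissue.tissue, substrate)
    records = []
    adp_t = sched.adp_times[0]
    for scale in scales_percent:
        res = run_schedule(
            tissue, sched, ctx=ctx, rtol=rtol, atol=atol, leak_scale=scale / 100.0
        )
        feats = extract_features(res, sched)
        i2 = int(np.searchsorted(res.t, adp_t) - 1)  # end of state 2
        ipk = int(np.argmax(np.where((res.t > adp_t), res.ocr, -np.inf)))
        records.append(
            {
                "leak_percent": float(scale),
                "state2_ocr": feats.state2_ocr,
                "state3_peak": max(feats.state3_peaks),
                "rci": feats.rci,
                "state2_dpsi": float(res.dpsi[i2]),
                "state3_dpsi": float(res.dpsi[ipk]),
                "state2_nadh": float(res.nadh_ratio[i2]),
                "state3_nadh": float(res.nadh_ratio[ipk]),
                "state2_uqh2": float(res.uqh2_ratio[i2]),
                "state3_uqh2": float(res.uqh2_ratio[ipk]),
                "state2_cytc": float(res.cytc_ratio[i2]),
                "state3_cytc": float(res.cytc_ratio[ipk]),
            }
        )
    return records
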