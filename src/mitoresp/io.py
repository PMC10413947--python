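"""Readers and writers for parameter tables, run configuration and manifests.

The tissue parameter table mirrors the published layout: values are printed
in units of 1e5 nmol/min/mg and scaled on load, except the proton-leak row
which is printed unscaled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

from .fluxes import FluxCatalog, RegulationParams, default_catalog
from .params import TISSUES, TMAX_KEYS, VMAX_KEYS, Compartments, TissueParameterSet

__all__ = [
    "RunConfig",
    "load_model_config",
    "load_tissue_parameters",
    "write_tissue_parameters",
    "load_kinetic_catalog",
    "manifest",
]

RATE_SCALE = 1.0e5
UNSCALED_ROWS = {"Tmaxf_HLEAK"}


@lru_cache(maxsize=1)
def load_model_config() -> dict:
    """Pools, regulation constants, initial conditions and protocol defaults."""
    text = resources.files("mitoresp.data").joinpath("model_config.json").read_text()
    return json.loads(text)


def load_kinetic_catalog(path: str | Path | None = None) -> FluxCatalog:
    """Intrinsic kinetic-constants catalog (packaged default or external file)."""
    return FluxCatalog.from_json(path)


def _row_key(parameter: str) -> str:
    # "Vmaxf_PDH" -> "PDH"
    return parameter.split("_", 1)[1]


def load_tissue_parameters(
    source: str | Path = "heart",
    config: dict | None = None,
) -> TissueParameterSet:
    """Load a tissue parameter set by builtin name or from a CSV path.

    The CSV must contain exactly the 24 ``Vmaxf_*`` / ``Tmaxf_*`` rows; all
    values are multiplied by 1e5 except the H+ leak row, which is stored in
    plain nmol/min/mg.
    """
    config = config or load_model_config()
    if str(source) in TISSUES:
        tissue = str(source)
        with resources.as_file(
            resources.files("mitoresp.data").joinpath("tissue_params.csv")
        ) as p:
            table = pd.read_csv(p)
        column = tissue
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"unknown tissue {source!r}: not one of {TISSUES} and not a file"
            )
        table = pd.read_csv(path)
        data_cols = [c for c in table.columns if c != "parameter"]
        if len(data_cols) != 1:
            raise ValueError("external parameter table must have one value column")
        column = data_cols[0]
        tissue = column if column in TISSUES else "heart"

    expected = {f"Vmaxf_{k}" for k in VMAX_KEYS} | {f"Tmaxf_{k}" for k in TMAX_KEYS}
    got = set(table["parameter"])
    if got != expected:
        raise ValueError(
            "parameter table schema error; "
            f"missing={sorted(expected - got)} extra={sorted(got - expected)}"
        )

    vmax: dict[str, float] = {}
    tmax: dict[str, float] = {}
    for _, row in table.iterrows():
        name = row["parameter"]
        value = float(row[column])
        if name not in UNSCALED_ROWS:
            value *= RATE_SCALE
        key = _row_key(name)
        (vmax if name.startswith("Vmaxf_") else tmax)[key] = value

    reg = RegulationParams(**config["regulation"][tissue])
    return TissueParameterSet(tissue, vmax, tmax, reg, dict(config["pools"]))


def write_tissue_parameters(ts: TissueParameterSet, path: str | Path) -> None:
    """Write a parameter set back in the printed-units CSV layout."""
    rows = []
    for k in VMAX_KEYS:
        rows.append((f"Vmaxf_{k}", ts.vmax[k] / RATE_SCALE))
    for k in TMAX_KEYS:
        name = f"Tmaxf_{k}"
        scale = 1.0 if name in UNSCALED_ROWS else RATE_SCALE
        rows.append((name, ts.tmax[k] / scale))
    pd.DataFrame(rows, columns=["parameter", ts.tissue]).to_csv(path, index=False)


def default_compartments(tissue: str, protocol: str, config: dict | None = None) -> Compartments:
    config = config or load_model_config()
    comp = config["compartments"]
    rho = config["protein_density_mg_per_mL"][protocol][tissue]
    return Compartments(
        V_e_mL=float(comp["V_e_mL"]),
        V_m_uL_per_mg=float(comp["V_m_uL_per_mg"]),
        V_ims_fraction=float(comp["V_ims_fraction_of_Vm"]),
        protein_density_mg_per_mL=float(rho),
    )


@dataclass
class RunConfig:
    """Serializable description of one simulation run."""

    tissue: str = "heart"
    substrate: str = "PM"
    protocol: str = "A"
    rtol: float = 1.0e-8
    atol: float = 1.0e-10
    leak_scale: float = 1.0
    seed: int = 0
    out_dir: str = "."
    event_overrides: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def save_checkpoint(path: str | Path, t: float, state, tissue: str = "",
                    rotenone: bool = False) -> None:
    """Write an integration checkpoint (time, named state, flags) as JSON."""
    from .states import STATE_NAMES

    values = {name: float(v) for name, v in zip(STATE_NAMES, state)}
    Path(path).write_text(
        json.dumps({"t_min": float(t), "tissue": tissue, "rotenone": bool(rotenone),
                    "state": values}, indent=2, sort_keys=True)
    )


def load_checkpoint(path: str | Path):
    """Read a checkpoint back; returns (t, state array, tissue, rotenone)."""
    import numpy as np

    from .states import STATE_NAMES

    d = json.loads(Path(path).read_text())
    missing = set(STATE_NAMES) - set(d["state"])
    if missing:
        raise ValueError(f"checkpoint missing states: {sorted(missing)}")
    y = np.array([d["state"][name] for name in STATE_NAMES])
    return float(d["t_min"]), y, d.get("tissue", ""), bool(d.get("rotenone", False))


def manifest(config: RunConfig, extra: dict | None = None) -> dict:
    """Reproducibility manifest: config, package version, data hashes."""
    import mitoresp

    hashes = {}
    for name in ("kinetics.json", "model_config.json", "tissue_params.csv"):
        data = resources.files("mitoresp.data").joinpath(name).read_bytes()
        hashes[name] = hashlib.sha256(data).hexdigest()
    out = {
        "config": asdict(config),
        "version": getattr(mitoresp, "__version__", "0"),
        "data_sha256": hashes,
    }
    if extra:
        out.update(extra)
    return out
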