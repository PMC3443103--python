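"""Plain-text serialization: TSV tables and JSON parameter sets.

Survival curves travel as TSV with columns ``time_s``, ``survival``, ``sd``,
``n_total``; trajectories as ``bead_id``, ``time_s``, ``x_um``; arrests as
``bead_id``, ``start_s``, ``d_app_s``, ``d_true_s``, ``shear_per_s``,
``censored``.  Bond laws, Bell regressions and force-level triples use small
JSON objects.  Geometry / tether configuration is read from JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dimer_sim import ForceLevels
from .hydrodynamics import ChamberGeometry, TetherModel
from .kinetics import BellLaw, BondLaw, SurvivalCurve
from .observation import ArrestEvent, ArrestSet

__all__ = [
    "read_survival",
    "write_survival",
    "read_bond_law",
    "write_bond_law",
    "read_bell_law",
    "write_bell_law",
    "read_force_levels",
    "write_force_levels",
    "read_arrests",
    "write_arrests",
    "read_trajectory_table",
    "write_trajectory_table",
    "load_config",
]


def write_survival(curve: SurvivalCurve, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": curve.times,
            "survival": curve.survival,
            "sd": curve.sd if curve.sd is not None else np.nan,
            "n_total": curve.n_total if curve.n_total is not None else np.nan,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> SurvivalCurve:
    df = pd.read_csv(path, sep="\t")
    sd = df["sd"].to_numpy(float) if "sd" in df and df["sd"].notna().all() else None
    n_total = None
    if "n_total" in df and df["n_total"].notna().any():
        n_total = float(df["n_total"].iloc[0])
    return SurvivalCurve(
        times=df["time_s"].to_numpy(float),
        survival=df["survival"].to_numpy(float),
        sd=sd,
        n_total=n_total,
    )


def write_bond_law(law: BondLaw, path: str | Path) -> None:
    obj = {"k0": law.initial_off_rate, "a": law.strengthening_rate}
    if law.force is not None:
        obj["force_pN"] = law.force
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_bond_law(path: str | Path) -> BondLaw:
    obj = json.loads(Path(path).read_text())
    return BondLaw(
        initial_off_rate=float(obj["k0"]),
        strengthening_rate=float(obj.get("a", 0.0)),
        force=obj.get("force_pN"),
    )


def write_bell_law(bell: BellLaw, path: str | Path) -> None:
    obj = {"k_at_zero_force": bell.zero_force_value, "slope_per_pN": bell.slope}
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_bell_law(path: str | Path) -> BellLaw:
    obj = json.loads(Path(path).read_text())
    return BellLaw(
        zero_force_value=float(obj["k_at_zero_force"]),
        slope=float(obj["slope_per_pN"]),
    )


def _law_to_obj(law: BondLaw) -> dict:
    return {"k0": law.initial_off_rate, "a": law.strengthening_rate}


def _law_from_obj(obj: dict) -> BondLaw:
    return BondLaw(float(obj["k0"]), float(obj.get("a", 0.0)), force=obj.get("force_pN"))


def write_force_levels(levels: ForceLevels, path: str | Path) -> None:
    obj = {
        "full": _law_to_obj(levels.full),
        "half": _law_to_obj(levels.half),
        "unloaded": _law_to_obj(levels.unloaded),
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_force_levels(path: str | Path) -> ForceLevels:
    obj = json.loads(Path(path).read_text())
    return ForceLevels(
        full=_law_from_obj(obj["full"]),
        half=_law_from_obj(obj["half"]),
        unloaded=_law_from_obj(obj["unloaded"]),
    )


def write_arrests(arrests: ArrestSet, path: str | Path, bead_id: str = "") -> None:
    df = pd.DataFrame(
        {
            "bead_id": bead_id,
            "start_s": [e.start_time for e in arrests.events],
            "d_app_s": [e.apparent_duration for e in arrests.events],
            "d_true_s": [e.corrected_duration for e in arrests.events],
            "shear_per_s": [e.shear_rate for e in arrests.events],
            "censored": [int(e.censored) for e in arrests.events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_arrests(path: str | Path, total_path_length: float = 1.0) -> ArrestSet:
    df = pd.read_csv(path, sep="\t")
    events = [
        ArrestEvent(
            start_time=float(row.start_s),
            apparent_duration=float(row.d_app_s),
            corrected_duration=None if pd.isna(row.d_true_s) else float(row.d_true_s),
            shear_rate=None if pd.isna(row.shear_per_s) else float(row.shear_per_s),
            censored=bool(row.censored),
        )
        for row in df.itertuples()
    ]
    return ArrestSet(events=events, total_path_length=total_path_length)


def write_trajectory_table(trajectories, path: str | Path) -> None:
    frames = [
        pd.DataFrame({"bead_id": tr.bead_id, "time_s": tr.times, "x_um": tr.x})
        for tr in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_trajectory_table(path: str | Path):
    from .observation import Trajectory

    df = pd.read_csv(path, sep="\t")
    return [
        Trajectory(
            bead_id=str(bead),
            times=sub["time_s"].to_numpy(float),
            x=sub["x_um"].to_numpy(float),
        )
        for bead, sub in df.groupby("bead_id", sort=False)
    ]


def load_config(path: str | Path) -> dict:
    """Read a JSON or YAML configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def geometry_from_config(cfg: dict) -> ChamberGeometry:
    kwargs = {}
    if "bead_radius_nm" in cfg:
        kwargs["bead_radius"] = float(cfg["bead_radius_nm"])
    if "viscosity_Pa_s" in cfg:
        kwargs["viscosity"] = float(cfg["viscosity_Pa_s"])
    return ChamberGeometry(**kwargs)


def tether_from_config(cfg: dict) -> TetherModel:
    kwargs = {}
    if "tether_length_nm" in cfg:
        kwargs["length"] = float(cfg["tether_length_nm"])
    if "n_links" in cfg:
        kwargs["n_links"] = int(cfg["n_links"])
    if "link_length_nm" in cfg:
        kwargs["link_length"] = float(cfg["link_length_nm"])
    return TetherModel(**kwargs)
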