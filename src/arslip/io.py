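"""Plain-text dataset formats and (de)serialization.

A dataset bundle is a directory of comma-separated tables with unit-bearing
header comments plus a JSON metadata file:

    trajectory.csv : t, x, z [, y]            (s, m)
    footfalls.csv  : leg, t_down, t_up, x_foot, y_foot
    leg_tracks.csv : t, leg, y_body, stance   (optional)
    metadata.json  : fly_id, mass_kg, R_real_m, frame_rate_hz, provenance

Times are seconds, positions metres, angles radians.  Numeric round trips
are lossless (shortest round-trip float formatting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import CoMTrajectory
from .gait import LEGS, FootfallSequence, LegTracks

__all__ = ["DatasetBundle", "SchemaError", "read_dataset", "write_dataset"]


class SchemaError(ValueError):
    """A table does not conform to the documented schema."""


@dataclass
class DatasetBundle:
    """In-memory dataset: CoM trajectory, footfalls, optional leg tracks,
    and the fitting metadata (fly id, mass, measured leg length, frame
    rate) with provenance (seed, generator version or "imported")."""

    com: CoMTrajectory
    footfalls: FootfallSequence
    leg_tracks: LegTracks | None
    metadata: dict
    provenance: dict


_UNITS_HEADER = {
    "trajectory.csv": "# t [s], x [m], z [m]" ,
    "footfalls.csv": "# leg, t_down [s], t_up [s], x_foot [m], y_foot [m]",
    "leg_tracks.csv": "# t [s], leg, y_body [m], stance [0/1]",
}


def _write_csv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment + "\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    # round_trip parser: numeric content must survive write/read losslessly
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_dataset(bundle: DatasetBundle, path: str | Path) -> None:
    """Write a bundle to a directory of CSV/JSON files (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    traj = pd.DataFrame({"t": bundle.com.t, "x": bundle.com.x,
                         "z": bundle.com.z})
    _write_csv(traj, path / "trajectory.csv", _UNITS_HEADER["trajectory.csv"])

    rows = []
    for leg, iv in bundle.footfalls.intervals.items():
        for (td, tu), (fx, fy) in zip(iv, bundle.footfalls.footholds[leg]):
            rows.append({"leg": leg, "t_down": td, "t_up": tu,
                         "x_foot": fx, "y_foot": fy})
    ff = pd.DataFrame(rows).sort_values(["t_down", "leg"], ignore_index=True)
    _write_csv(ff, path / "footfalls.csv", _UNITS_HEADER["footfalls.csv"])

    if bundle.leg_tracks is not None:
        lt_rows = []
        for leg in bundle.leg_tracks.y:
            lt_rows.append(pd.DataFrame({
                "t": bundle.leg_tracks.t, "leg": leg,
                "y_body": bundle.leg_tracks.y[leg],
                "stance": bundle.leg_tracks.stance[leg].astype(int)}))
        lt = pd.concat(lt_rows, ignore_index=True)
        _write_csv(lt, path / "leg_tracks.csv",
                   _UNITS_HEADER["leg_tracks.csv"])

    meta = dict(bundle.metadata)
    meta["provenance"] = bundle.provenance
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=float)


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def read_dataset(path: str | Path) -> DatasetBundle:
    """Read a bundle directory, validating schemas.

    Raises :class:`SchemaError` naming the offending row for missing
    columns, non-monotone time, or unknown leg labels.
    """
    path = Path(path)
    traj = _read_csv(path / "trajectory.csv")
    _require_columns(traj, ["t", "x", "z"], "trajectory.csv")
    t = traj["t"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise SchemaError(
            f"trajectory.csv: time not strictly increasing at row "
            f"{bad[0] + 1} (t = {t[bad[0] + 1]!r})")
    com = CoMTrajectory(t=t, x=traj["x"].to_numpy(float),
                        z=traj["z"].to_numpy(float))

    ff = _read_csv(path / "footfalls.csv")
    _require_columns(ff, ["leg", "t_down", "t_up", "x_foot", "y_foot"],
                     "footfalls.csv")
    unknown = ~ff["leg"].isin(LEGS)
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0])
        raise SchemaError(f"footfalls.csv: unknown leg label "
                          f"{ff['leg'].iloc[row]!r} at row {row}")
    intervals: dict[str, np.ndarray] = {}
    footholds: dict[str, np.ndarray] = {}
    for leg, grp in ff.groupby("leg"):
        grp = grp.sort_values("t_down")
        intervals[leg] = grp[["t_down", "t_up"]].to_numpy(float)
        footholds[leg] = grp[["x_foot", "y_foot"]].to_numpy(float)
    footfalls = FootfallSequence(intervals=intervals, footholds=footholds,
                                 span=(float(t[0]), float(t[-1])))

    leg_tracks = None
    lt_path = path / "leg_tracks.csv"
    if lt_path.exists():
        lt = _read_csv(lt_path)
        _require_columns(lt, ["t", "leg", "y_body", "stance"],
                         "leg_tracks.csv")
        unknown = ~lt["leg"].isin(LEGS)
        if unknown.any():
            row = int(np.flatnonzero(unknown)[0])
            raise SchemaError(f"leg_tracks.csv: unknown leg label "
                              f"{lt['leg'].iloc[row]!r} at row {row}")
        y, stance = {}, {}
        t_lt = None
        for leg, grp in lt.groupby("leg"):
            if t_lt is None:
                t_lt = grp["t"].to_numpy(float)
            y[leg] = grp["y_body"].to_numpy(float)
            stance[leg] = grp["stance"].to_numpy(int).astype(bool)
        leg_tracks = LegTracks(t=t_lt, y=y, stance=stance)

    with open(path / "metadata.json") as fh:
        meta = json.load(fh)
    provenance = meta.pop("provenance", {"source": "imported"})
    return DatasetBundle(com=com, footfalls=footfalls, leg_tracks=leg_tracks,
                         metadata=meta, provenance=provenance)


def bundle_from_synthetic(ds) -> DatasetBundle:
    """Wrap a :class:`~arslip.synthetic.SyntheticDataset` as a bundle."""
    cfg = ds.config
    return DatasetBundle(
        com=ds.com, footfalls=ds.footfalls, leg_tracks=ds.leg_tracks,
        metadata={"fly_id": cfg.fly_id, "mass_kg": cfg.mass,
                  "R_real_m": cfg.R_real, "frame_rate_hz": cfg.frame_rate},
        provenance={"source": "synthetic", "seed": cfg.seed})
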