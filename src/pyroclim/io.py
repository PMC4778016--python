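"""On-disk formats: CSV proxy series, site-burn CSV, NetCDF grids.

Series travel as CSV with columns ``time,value`` (optional ``units``
and ``bp_flag``; rows flagged BP are converted to calendar years as
AD = 1950 − BP on read).  Site-burn matrices travel as long-format CSV
with columns ``year,site,burned,recording``.  Gridded fields are
NetCDF with coordinate variables ``lat``, ``lon``, ``time``.  All CSV
writers prepend ``#``-comment provenance headers (tool version, config
hash) which the readers skip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .errors import FormatError
from .fields import GriddedField
from .lfy import SiteBurnMatrix
from .series import ProxySeries

__all__ = [
    "read_series", "write_series",
    "read_site_burn", "write_site_burn",
    "read_field", "write_field",
]

_NC_ENGINE = "scipy"


def _provenance(extra: str = "") -> str:
    lines = [f"# pyroclim {__version__}"]
    if extra:
        lines.append(f"# {extra}")
    return "\n".join(lines) + "\n"


def read_series(path: str | Path, label: str | None = None) -> ProxySeries:
    """Read a proxy series CSV; sort by time, convert BP-flagged rows."""
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in ("time", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    time = pd.to_numeric(df["time"], errors="coerce")
    value = pd.to_numeric(df["value"], errors="coerce")
    if time.isna().any() or value.isna().any():
        raise FormatError(f"{path}: non-numeric time or value entries")
    time = time.to_numpy(dtype=float)
    if "bp_flag" in df.columns:
        bp = df["bp_flag"].astype(bool).to_numpy()
        time = np.where(bp, 1950.0 - time, time)
    order = np.argsort(time)
    time = time[order]
    if len(np.unique(time)) != len(time):
        raise FormatError(f"{path}: duplicate timestamps")
    resolution = float(df["resolution"].iloc[0]) if "resolution" in df.columns else 1.0
    return ProxySeries(time=time, value=value.to_numpy(dtype=float)[order],
                       resolution=resolution,
                       label=label if label is not None else Path(path).stem)


def write_series(series: ProxySeries, path: str | Path, provenance: str = "") -> None:
    df = pd.DataFrame({"time": series.time, "value": series.value,
                       "resolution": series.resolution})
    with open(path, "w") as fh:
        fh.write(_provenance(provenance))
        df.to_csv(fh, index=False, float_format="%.17g")


def read_site_burn(path: str | Path) -> SiteBurnMatrix:
    """Read a long-format site-burn CSV into a year × site matrix."""
    df = pd.read_csv(path, comment="#")
    for col in ("year", "site", "burned", "recording"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    years = np.sort(df["year"].unique())
    sites = sorted(df["site"].astype(str).unique())
    yi = {y: i for i, y in enumerate(years)}
    si = {s: j for j, s in enumerate(sites)}
    burned = np.zeros((len(years), len(sites)), dtype=bool)
    recording = np.zeros_like(burned)
    for row in df.itertuples(index=False):
        i, j = yi[row.year], si[str(row.site)]
        burned[i, j] = bool(row.burned)
        recording[i, j] = bool(row.recording)
    return SiteBurnMatrix(years=years.astype(int), sites=sites,
                          burned=burned, recording=recording)


def write_site_burn(matrix: SiteBurnMatrix, path: str | Path,
                    provenance: str = "") -> None:
    ny, ns = matrix.burned.shape
    df = pd.DataFrame({
        "year": np.repeat(matrix.years, ns),
        "site": matrix.sites * ny,
        "burned": matrix.burned.ravel().astype(int),
        "recording": matrix.recording.ravel().astype(int),
    })
    with open(path, "w") as fh:
        fh.write(_provenance(provenance))
        df.to_csv(fh, index=False)


def read_field(path: str | Path, var: str | None = None) -> GriddedField:
    """Read a NetCDF grid, normalising lon to [−180, 180) and lat ascending."""
    try:
        ds = xr.open_dataset(path, engine=_NC_ENGINE)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot open {path} as NetCDF: {exc}") from exc
    with ds:
        return GriddedField.from_xarray(ds.load(), var=var)


def write_field(field: GriddedField, path: str | Path, name: str = "field") -> None:
    field.to_xarray(name=name).to_netcdf(path, engine=_NC_ENGINE)
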