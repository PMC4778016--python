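"""Gridded lat/lon/time field container.

Thin dataclass around a (time, lat, lon) array with the conventions the
teleconnection statistics expect: latitudes ascending, longitudes in
[−180, 180), time either monthly (datetime64[M], first of month) or
annual.  Conversion to and from :class:`xarray.Dataset` handles NetCDF
I/O and convention normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xarray as xr

from .errors import FormatError, InvalidInputError

__all__ = ["GriddedField"]


@dataclass(frozen=True)
class GriddedField:
    lat: np.ndarray
    lon: np.ndarray
    time: np.ndarray  # datetime64[M] timestamps
    values: np.ndarray  # (time, lat, lon)
    units: str = ""
    frequency: str = "monthly"  # or "annual"

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        time = np.asarray(self.time, dtype="datetime64[M]")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(time), len(lat), len(lon)):
            raise InvalidInputError("values must have shape (time, lat, lon)")
        for name, coord in (("lat", lat), ("lon", lon)):
            if len(np.unique(coord)) != len(coord):
                raise InvalidInputError(f"duplicate {name} coordinates")
        if len(time) > 1 and not np.all(np.diff(time.astype("int64")) > 0):
            raise InvalidInputError("time must be strictly increasing")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "values", values)

    @property
    def years(self) -> np.ndarray:
        return self.time.astype("datetime64[Y]").astype(int) + 1970

    @property
    def months(self) -> np.ndarray:
        return self.time.astype(int) % 12 + 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, **kw) -> "GriddedField":
        return replace(self, values=values, **kw)

    # --- xarray bridge -------------------------------------------------

    def to_xarray(self, name: str = "field") -> xr.Dataset:
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.time.astype("datetime64[ns]"),
                    "lat": self.lat, "lon": self.lon},
            name=name,
            attrs={"units": self.units, "frequency": self.frequency},
        )
        return da.to_dataset()

    @classmethod
    def from_xarray(cls, ds: xr.Dataset, var: str | None = None) -> "GriddedField":
        """Build from a dataset, normalising coordinate conventions.

        Longitudes on [0, 360) are wrapped to [−180, 180) and the grid is
        re-sorted; descending latitudes are flipped to ascending.
        """
        for coord in ("lat", "lon", "time"):
            if coord not in ds.coords:
                raise FormatError(f"missing coordinate variable {coord!r}")
        if var is None:
            data_vars = [v for v in ds.data_vars if set(ds[v].dims) >= {"time", "lat", "lon"}]
            if not data_vars:
                raise FormatError("no (time, lat, lon) data variable found")
            var = data_vars[0]
        da = ds[var].transpose("time", "lat", "lon")
        lon = da["lon"].values.astype(float)
        if np.any(lon >= 180.0):
            da = da.assign_coords(lon=((lon + 180.0) % 360.0) - 180.0).sortby("lon")
        if len(da["lat"]) > 1 and da["lat"].values[0] > da["lat"].values[-1]:
            da = da.sortby("lat")
        time = pd.DatetimeIndex(da["time"].values).to_numpy().astype("datetime64[M]")
        return cls(lat=da["lat"].values, lon=da["lon"].values, time=time,
                   values=da.values, units=str(da.attrs.get("units", "")),
                   frequency=str(da.attrs.get("frequency", "monthly")))
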