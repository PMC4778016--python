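"""Proxy time series container and the conditioning chain.

The analyses operate on scalar proxy series — annually burned area,
reconstructed summer temperature, SST, ice-rafted debris, sediment
charcoal — that arrive at heterogeneous resolutions and in incompatible
units.  Everything downstream (regime detection, compositing,
correlation) assumes a common conditioning chain:

* variance-stabilising transforms for burned-area data (``log1p`` /
  ``sqrt``),
* per-site standardisation to z-scores so each site gets equal weight,
* binning to a constant coarse resolution (20 yr core resampling,
  200 yr composites),
* multi-site compositing (mean of standardised, binned site series),
* linear detrending before regime detection,
* a 100-yr moving cumulative burned-area filter at 10-yr shifts that
  turns annual fire records into decadally resolved activity series.

Time is calendar year AD throughout; series given in cal yr BP are
converted on read (AD = 1950 − BP).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError

__all__ = [
    "ProxySeries",
    "BinnedComposite",
    "transform_fire",
    "standardize",
    "bin_series",
    "composite",
    "detrend_linear",
    "moving_cumulative",
    "charcoal_prepare",
    "CharcoalConfig",
]


@dataclass(frozen=True)
class ProxySeries:
    """A timestamped scalar proxy series.

    Parameters
    ----------
    time
        Strictly increasing calendar years (AD).
    value
        Proxy values, same length as ``time``.  Units depend on the proxy
        (ha, °C, z-score, influx).
    resolution
        Nominal years per step (1 for annual, 200 for binned composites).
    label
        Free-text identifier; transforms append their name to it.
    """

    time: np.ndarray
    value: np.ndarray
    resolution: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise InvalidInputError("time and value must be 1-D")
        if len(t) != len(v):
            raise InvalidInputError("time and value must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("time must be strictly increasing")
        if not self.resolution > 0:
            raise InvalidParameterError("resolution must be > 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)

    def __len__(self) -> int:
        return len(self.time)

    def with_values(self, value: np.ndarray, label: str | None = None) -> "ProxySeries":
        return replace(self, value=np.asarray(value, dtype=float),
                       label=self.label if label is None else label)


@dataclass(frozen=True)
class BinnedComposite:
    """Multi-site composite on a common bin grid.

    ``value[i]`` is the mean of standardised site values falling in
    ``[bin_start[i], bin_start[i] + bin_width)``; ``n_sites_per_bin[i]``
    counts the sites contributing there (bins with zero sites are dropped).
    """

    bin_start: np.ndarray
    bin_width: float
    value: np.ndarray
    n_sites_per_bin: np.ndarray

    def to_series(self, label: str = "composite") -> ProxySeries:
        return ProxySeries(time=self.bin_start, value=self.value,
                           resolution=self.bin_width, label=label)


def transform_fire(series: ProxySeries, method: str = "log1p") -> ProxySeries:
    """Variance-stabilising transform for burned-area data.

    ``log1p`` maps x to ln(1+x), ``sqrt`` to √x; both keep zero years at
    zero and pull in the heavy right tail of annual burned areas so the
    Pearson-correlation machinery sees roughly normal inputs.
    """
    if method not in ("log1p", "sqrt"):
        raise InvalidParameterError(f"unknown transform {method!r}")
    v = series.value
    if np.any(v < 0):
        raise InvalidInputError("fire data must be non-negative")
    out = np.log1p(v) if method == "log1p" else np.sqrt(v)
    return series.with_values(out, label=f"{series.label}|{method}")


def standardize(series: ProxySeries) -> ProxySeries:
    """Z-score a series (sample sd, ddof=1).

    Raises :class:`DegenerateInputError` on constant input.
    """
    v = series.value
    if len(v) < 2:
        raise DegenerateInputError("need at least 2 points to standardize")
    sd = np.std(v, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot standardize a constant series")
    return series.with_values((v - np.mean(v)) / sd, label=f"{series.label}|z")


def _bin_edges(t: np.ndarray, width: float, origin: float | None) -> np.ndarray:
    start = t[0] if origin is None else origin
    n_bins = int(np.floor((t[-1] - start) / width)) + 1
    return start + width * np.arange(n_bins + 1)


def bin_series(series: ProxySeries, bin_width: float, aggregator: str = "mean",
               origin: float | None = None) -> ProxySeries:
    """Aggregate into contiguous left-closed right-open bins.

    Bins are anchored at the earliest observation (or an explicit
    ``origin``); empty bins yield NaN.  Output timestamps are bin starts
    and the output resolution equals ``bin_width``.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    if aggregator not in ("mean", "sum"):
        raise InvalidParameterError(f"unknown aggregator {aggregator!r}")
    edges = _bin_edges(series.time, bin_width, origin)
    idx = np.digitize(series.time, edges) - 1
    n_bins = len(edges) - 1
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            vals = series.value[sel]
            out[b] = np.sum(vals) if aggregator == "sum" else np.mean(vals)
    return ProxySeries(time=edges[:-1], value=out, resolution=bin_width,
                       label=f"{series.label}|bin{bin_width:g}")


def composite(series_list: Sequence[ProxySeries], bin_width: float) -> BinnedComposite:
    """Standardise each site, bin to a shared grid, average per bin.

    The bin grid is anchored at the earliest time across all sites so
    every site lands on identical edges.  Each bin averages only the
    sites with data there; bins with no sites at all are dropped.
    """
    if len(series_list) == 0:
        raise InvalidParameterError("need at least one series")
    origin = min(s.time[0] for s in series_list)
    end = max(s.time[-1] for s in series_list)
    n_bins = int(np.floor((end - origin) / bin_width)) + 1
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins, dtype=int)
    for s in series_list:
        zb = bin_series(standardize(s), bin_width, "mean", origin=origin)
        offset = int(round((zb.time[0] - origin) / bin_width))
        for i, v in enumerate(zb.value):
            if np.isfinite(v):
                acc[offset + i] += v
                cnt[offset + i] += 1
    keep = cnt > 0
    if not np.any(keep):
        raise DegenerateInputError("composite is empty: no bin has site data")
    starts = origin + bin_width * np.arange(n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(keep, acc / np.maximum(cnt, 1), np.nan)
    return BinnedComposite(bin_start=starts[keep], bin_width=float(bin_width),
                           value=mean[keep], n_sites_per_bin=cnt[keep])


def detrend_linear(series: ProxySeries) -> ProxySeries:
    """Subtract the OLS long-term linear trend.

    Residuals have zero mean and zero covariance with time; applied to
    temperature/SST/IRD reconstructions before regime detection so a
    secular trend is not mistaken for a staircase of regimes.
    """
    if len(series) < 3:
        raise DegenerateInputError("need at least 3 points to detrend")
    t = series.time
    coeffs = np.polyfit(t, series.value, 1)
    resid = series.value - np.polyval(coeffs, t)
    return series.with_values(resid, label=f"{series.label}|detrended")


def moving_cumulative(series: ProxySeries, window: int = 100, step: int = 10) -> ProxySeries:
    """Cumulative burned area over a moving window.

    Sums ``window`` consecutive annual values, advancing the window by
    ``step`` years; the default 100-yr window at 10-yr shifts turns an
    annual burned-area record into a smoothed decadal activity series
    suitable for regime detection.  Output timestamps are window starts.
    """
    if window <= 0 or step <= 0:
        raise InvalidParameterError("window and step must be positive")
    n = len(series)
    if window > n:
        raise InvalidParameterError(f"window {window} exceeds series length {n}")
    if abs(series.resolution - 1.0) > 1e-9:
        raise InvalidInputError("moving_cumulative expects an annual series")
    starts = np.arange(0, n - window + 1, step)
    csum = np.concatenate([[0.0], np.cumsum(series.value)])
    sums = csum[starts + window] - csum[starts]
    return ProxySeries(time=series.time[starts], value=sums, resolution=float(step),
                       label=f"{series.label}|cum{window}s{step}")


@dataclass(frozen=True)
class CharcoalConfig:
    """Settings for the charcoal conditioning chain.

    ``boxcox_lambda=None`` fits λ per site by maximum likelihood; the
    shift added before the power transform is ``shift_frac`` times the
    site maximum, so zero-count samples stay admissible.
    """

    bin_width: float = 200.0
    boxcox_lambda: float | None = None
    shift_frac: float = 0.01
    deposition_rates: tuple | None = None  # one vector per site, cm/yr × conc → influx


def charcoal_prepare(series_list: Sequence[ProxySeries],
                     config: CharcoalConfig | None = None) -> BinnedComposite:
    """Charcoal conditioning: influx conversion, Box-Cox, z-score, composite.

    Per site: optionally multiply concentrations by a deposition-rate
    vector to get influx, apply a shifted Box-Cox power transform
    (stabilises the strongly right-skewed charcoal counts), standardise,
    then composite all sites on a common coarse grid (default 200 yr).
    """
    cfg = config or CharcoalConfig()
    prepared = []
    for k, s in enumerate(series_list):
        v = s.value.copy()
        if cfg.deposition_rates is not None:
            rate = np.asarray(cfg.deposition_rates[k], dtype=float)
            if len(rate) != len(v):
                raise InvalidInputError("deposition rate vector length mismatch")
            v = v * rate
        shift = cfg.shift_frac * np.max(v) if np.max(v) > 0 else cfg.shift_frac
        shifted = v + shift
        if np.any(shifted <= 0):
            raise InvalidInputError("non-positive values after shift")
        if np.ptp(shifted) == 0:
            raise DegenerateInputError("constant charcoal record cannot be standardized")
        if cfg.boxcox_lambda is None:
            transformed, _ = stats.boxcox(shifted)
        else:
            lam = cfg.boxcox_lambda
            transformed = np.log(shifted) if lam == 0 else (shifted ** lam - 1) / lam
        prepared.append(s.with_values(transformed, label=f"{s.label}|boxcox"))
    return composite(prepared, cfg.bin_width)
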