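"""Teleconnection statistics between a scalar index and gridded fields.

Implements the map-scale statistics used to link a fire-activity index
to ocean/atmosphere state: per-cell Pearson correlation with
autocorrelation-adjusted significance, Monte-Carlo field significance,
moving-window correlation stability, and superposed epoch analysis
(SEA) of fields around event years.

Serial correlation inflates the nominal sample size of a correlation
between two annual series; following the standard adjustment, the
effective sample size is

    n_eff = n (1 − r₁ᵃ r₁ᵇ) / (1 + r₁ᵃ r₁ᵇ),

with r₁ the lag-1 autocorrelations of the two series, and the t-test
for each cell uses n_eff − 2 degrees of freedom.  Field significance —
the probability that the observed fraction of locally significant
cells could arise by chance given the spatial correlation of the field
— is evaluated by permuting the index's years and recomputing the
whole map n_perm times, which preserves the field's spatial structure
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError, InvalidParameterError
from .fields import GriddedField
from .series import ProxySeries

__all__ = [
    "CorrelationMap",
    "SEAResult",
    "seasonal_index",
    "effective_n",
    "lag1_autocorr",
    "correlation_map",
    "moving_correlation",
    "sea",
]


@dataclass(frozen=True)
class CorrelationMap:
    """Per-cell correlation with adjusted significance and map-level summary."""

    lat: np.ndarray
    lon: np.ndarray
    r: np.ndarray          # (lat, lon)
    p_adj: np.ndarray      # autocorrelation-adjusted two-sided p per cell
    n_eff: np.ndarray
    p_field: float
    frac_significant: float
    months: tuple
    alpha: float
    n_overlap: int


@dataclass(frozen=True)
class SEAResult:
    """Composite anomalies around event years, one layer per month."""

    lat: np.ndarray
    lon: np.ndarray
    months: tuple
    composite_anom: np.ndarray  # (month, lat, lon)
    p: np.ndarray               # two-sided bootstrap p, same shape
    event_years: np.ndarray
    n_boot: int


def seasonal_index(field: GriddedField, months: Sequence[int]) -> GriddedField:
    """Average a monthly field over the listed months, per year.

    Years missing any requested month are dropped.  The result is an
    annual field timestamped at January of each year.
    """
    months = tuple(int(m) for m in months)
    if not months or any(m < 1 or m > 12 for m in months):
        raise InvalidParameterError("months must be a non-empty subset of 1..12")
    if field.frequency == "annual":
        return field
    yrs = field.years
    mos = field.months
    out_years, out_vals = [], []
    for y in np.unique(yrs):
        sel = (yrs == y) & np.isin(mos, months)
        if sel.sum() == len(set(months)):
            out_years.append(y)
            out_vals.append(field.values[sel].mean(axis=0))
    if not out_years:
        raise InvalidInputError("no year has all requested months")
    time = np.array([np.datetime64(f"{y:04d}-01", "M") for y in out_years])
    return GriddedField(lat=field.lat, lon=field.lon, time=time,
                        values=np.stack(out_vals), units=field.units,
                        frequency="annual")


def effective_n(n: int, r1_a: float, r1_b: float) -> float:
    """Autocorrelation-adjusted effective sample size.

    n_eff = n (1 − r₁ᵃ r₁ᵇ)/(1 + r₁ᵃ r₁ᵇ), capped at n and floored at 3.
    """
    if abs(r1_a) >= 1 or abs(r1_b) >= 1:
        raise InvalidParameterError("lag-1 autocorrelations must lie in (-1, 1)")
    prod = r1_a * r1_b
    n_eff = n * (1.0 - prod) / (1.0 + prod)
    return float(np.clip(n_eff, 3.0, n))


def lag1_autocorr(x: np.ndarray) -> float:
    """Pearson correlation between x_t and x_{t−1}."""
    x = np.asarray(x, dtype=float)
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _rows_lag1(rows: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation of each row of a 2-D array."""
    a = rows[:, :-1]
    b = rows[:, 1:]
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((am ** 2).sum(axis=1) * (bm ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (am * bm).sum(axis=1) / denom, 0.0)
    return np.clip(r, -0.999999, 0.999999)


def _p_from_r(r: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-value for Pearson r at df = n_eff − 2."""
    df = np.maximum(n_eff - 2.0, 1.0)
    r2 = np.clip(r * r, 0.0, 1.0 - 1e-15)
    t = np.abs(r) * np.sqrt(df / (1.0 - r2))
    return 2.0 * stats.t.sf(t, df)


def correlation_map(index: ProxySeries, field: GriddedField,
                    months: Sequence[int] = (4, 5), alpha: float = 0.1,
                    n_perm: int = 1000, seed: int = 0) -> CorrelationMap:
    """Pearson correlation of an annual index with every grid cell.

    The monthly field is first averaged over ``months`` per year, then
    correlated with the index over the overlapping years.  Per-cell
    significance uses the effective sample size; ``p_field`` is the
    fraction of ``n_perm`` random permutations of the index whose map
    shows at least the observed fraction of significant cells, the
    adjustment included.
    """
    annual = seasonal_index(field, months)
    yrs_f = annual.years
    yrs_i = index.time.astype(int)
    common, ia, ib = np.intersect1d(yrs_i, yrs_f, return_indices=True)
    n = len(common)
    if n < 10:
        raise InvalidInputError(f"need ≥10 overlapping years, found {n}")
    x = index.value[ia]
    Y = annual.values[ib].reshape(n, -1)   # (n, cells)
    ncell = Y.shape[1]
    valid = ~np.any(np.isnan(Y), axis=0)
    Yv = np.where(np.isnan(Y), 0.0, Y)

    xc = x - x.mean()
    Yc = Yv - Yv.mean(axis=0, keepdims=True)
    sxx = float(np.sum(xc ** 2))
    syy = np.sum(Yc ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_flat = np.where((syy > 0) & (sxx > 0) & valid,
                          (xc @ Yc) / np.sqrt(sxx * syy), np.nan)

    r1_x = lag1_autocorr(x)
    r1_cells = _rows_lag1(Yv.T)
    prod = np.clip(r1_x * r1_cells, -0.999999, 0.999999)
    neff_flat = np.clip(n * (1.0 - prod) / (1.0 + prod), 3.0, n)
    p_flat = np.where(np.isfinite(r_flat), _p_from_r(np.nan_to_num(r_flat), neff_flat), np.nan)
    n_valid = int(np.sum(np.isfinite(p_flat)))
    frac_sig = float(np.nansum(p_flat <= alpha) / n_valid)

    # Monte-Carlo field significance: permute the index's years, redo the map
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Xp = xc[perms]                                    # (n_perm, n) — already centred
    Rp = (Xp @ Yc) / np.sqrt(sxx * np.where(syy > 0, syy, np.inf))
    r1_p = _rows_lag1(Xp)
    prod_p = np.clip(r1_p[:, None] * r1_cells[None, :], -0.999999, 0.999999)
    neff_p = np.clip(n * (1.0 - prod_p) / (1.0 + prod_p), 3.0, n)
    Pp = _p_from_r(Rp, neff_p)
    Pp = np.where(np.isfinite(p_flat)[None, :], Pp, np.nan)
    frac_p = np.nansum(Pp <= alpha, axis=1) / n_valid
    p_field = float(np.mean(frac_p >= frac_sig))

    shape = (len(annual.lat), len(annual.lon))
    return CorrelationMap(lat=annual.lat, lon=annual.lon,
                          r=r_flat.reshape(shape), p_adj=p_flat.reshape(shape),
                          n_eff=neff_flat.reshape(shape), p_field=p_field,
                          frac_significant=frac_sig, months=tuple(months),
                          alpha=alpha, n_overlap=n)


def moving_correlation(index: ProxySeries, series: ProxySeries,
                       window: int = 31, step: int = 1) -> ProxySeries:
    """Sliding-window Pearson correlation between two annual series.

    Windows with a constant member yield NaN; timestamps are window
    centres.  Used to check that a teleconnection is temporally stable
    rather than driven by one sub-period.
    """
    common, ia, ib = np.intersect1d(index.time, series.time, return_indices=True)
    n = len(common)
    if window > n:
        raise InvalidParameterError(f"window {window} exceeds overlap {n}")
    x = index.value[ia]
    y = series.value[ib]
    starts = np.arange(0, n - window + 1, step)
    rs = np.empty(len(starts))
    for k, s in enumerate(starts):
        xw, yw = x[s:s + window], y[s:s + window]
        if xw.std() == 0 or yw.std() == 0:
            rs[k] = np.nan
        else:
            rs[k] = np.corrcoef(xw, yw)[0, 1]
    centres = common[starts + (window - 1) // 2]
    return ProxySeries(time=centres.astype(float), value=rs, resolution=float(step),
                       label=f"movcorr({window})")


def sea(field: GriddedField, event_years: Sequence[int],
        months: Sequence[int] = (4, 5), n_boot: int = 1000,
        seed: int = 0) -> SEAResult:
    """Superposed epoch analysis of a monthly field around event years.

    For each requested month, the composite anomaly is the mean over
    event years of (cell value − cell climatology over all years).
    Significance per cell is the two-sided fraction of ``n_boot``
    random draws of the same number of years (without replacement, all
    years eligible) whose composite magnitude reaches the observed one.
    """
    months = tuple(int(m) for m in months)
    events = np.asarray(sorted(set(int(y) for y in event_years)))
    if len(events) < 2:
        raise InvalidParameterError("need at least 2 event years")
    yrs_all = np.unique(field.years)
    missing = np.setdiff1d(events, yrs_all)
    if missing.size:
        raise InvalidInputError(f"event years outside field span: {missing.tolist()}")
    rng = np.random.default_rng(seed)

    comp_layers, p_layers = [], []
    for m in months:
        if field.frequency == "annual":
            sel_years = field.years
            vals = field.values
        else:
            sel = field.months == m
            sel_years = field.years[sel]
            vals = field.values[sel]
        present = np.isin(events, sel_years)
        if not np.all(present):
            raise InvalidInputError(f"month {m} missing for some event years")
        clim = vals.mean(axis=0)
        anom = vals - clim
        ev_idx = np.searchsorted(sel_years, events)
        obs = anom[ev_idx].mean(axis=0)
        k = len(events)
        ny = len(sel_years)
        draws = np.array([rng.choice(ny, size=k, replace=False) for _ in range(n_boot)])
        null = anom[draws].mean(axis=1)           # (n_boot, lat, lon)
        p = (np.abs(null) >= np.abs(obs)[None]).mean(axis=0)
        comp_layers.append(obs)
        p_layers.append(p)

    return SEAResult(lat=field.lat, lon=field.lon, months=months,
                     composite_anom=np.stack(comp_layers), p=np.stack(p_layers),
                     event_years=events, n_boot=n_boot)
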