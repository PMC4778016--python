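"""Seeded synthetic inputs with the statistical structure the analyses assume.

Real inputs to the pipeline — multi-century fire-scar networks, lake
charcoal records, gridded SST / geopotential-height fields — cannot be
shipped, so every downstream stage is exercised on generated data that
reproduces the relevant structure:

* stationary AR(1) red noise, optionally with step changes in the mean
  (regime-detector inputs),
* binomial site-burning with probability-inflated large fire years
  (LFY-detector inputs),
* gridded monthly fields with a spatially localised linear coupling to
  an index series (teleconnection-map inputs).

Each generator takes one integer seed and is bit-reproducible; spatial
covariance of real SST fields, sedimentation-rate structure and
tree-ring biology are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .fields import GriddedField
from .lfy import SiteBurnMatrix
from .series import ProxySeries

__all__ = [
    "SegmentSpec",
    "TeleconnectionSpec",
    "gen_ar1_series",
    "gen_regime_series",
    "gen_site_burn_matrix",
    "gen_teleconnected_field",
]


@dataclass(frozen=True)
class SegmentSpec:
    """A contiguous run of years sharing one mean level."""

    start_index: int
    length: int
    mean: float

    def __post_init__(self) -> None:
        if self.start_index < 0 or self.length < 1:
            raise InvalidParameterError("start_index ≥ 0 and length ≥ 1 required")


@dataclass(frozen=True)
class TeleconnectionSpec:
    """A rectangular block of grid cells linearly coupled to an index.

    Inside the block each cell is ``coupling·z(index) + ε``,
    ε ~ N(0, noise_sd²); outside, pure noise.  With a unit-variance
    index the expected in-block correlation is
    coupling / sqrt(coupling² + noise_sd²).
    """

    block_lat_range: tuple[int, int]  # half-open index interval
    block_lon_range: tuple[int, int]
    coupling: float
    noise_sd: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.coupling <= 1.0:
            raise InvalidParameterError("|coupling| must be ≤ 1")
        if not self.noise_sd > 0:
            raise InvalidParameterError("noise_sd must be > 0")


def _ar1(n: int, ar1: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    # innovations scaled so the marginal (stationary) sd equals `sd`;
    # x_0 drawn from the stationary distribution to avoid burn-in.
    innov_sd = sd * np.sqrt(1.0 - ar1 * ar1)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = ar1 * x[i - 1] + eps[i - 1]
    return x


def gen_ar1_series(n: int, mean: float = 0.0, ar1: float = 0.0, sd: float = 1.0,
                   seed: int = 0, start_year: int = 0) -> ProxySeries:
    """Stationary AR(1) red noise with marginal standard deviation ``sd``."""
    if n < 2:
        raise InvalidParameterError("n must be ≥ 2")
    if not abs(ar1) < 1:
        raise InvalidParameterError("|ar1| must be < 1 for stationarity")
    if not sd > 0:
        raise InvalidParameterError("sd must be > 0")
    rng = np.random.default_rng(seed)
    x = mean + _ar1(n, ar1, sd, rng)
    return ProxySeries(time=np.arange(start_year, start_year + n, dtype=float),
                       value=x, resolution=1.0, label=f"ar1({ar1:g})")


def gen_regime_series(segments: Sequence[SegmentSpec], ar1: float = 0.0,
                      sd: float = 1.0, seed: int = 0,
                      start_year: int = 0) -> ProxySeries:
    """AR(1) noise superposed on a piecewise-constant mean.

    Segments must tile ``0..n-1`` contiguously without gaps or overlap.
    With ``sd → 0`` the output degenerates to the exact step function.
    """
    segs = sorted(segments, key=lambda s: s.start_index)
    if len(segs) == 0:
        raise InvalidParameterError("need at least one segment")
    pos = 0
    for s in segs:
        if s.start_index != pos:
            raise InvalidParameterError("segments must be contiguous and non-overlapping")
        pos += s.length
    n = pos
    mean = np.concatenate([np.full(s.length, s.mean) for s in segs])
    if sd == 0:
        noise = np.zeros(n)
    else:
        noise = _ar1(n, ar1, sd, np.random.default_rng(seed)) if abs(ar1) < 1 else None
        if noise is None:
            raise InvalidParameterError("|ar1| must be < 1")
    return ProxySeries(time=np.arange(start_year, start_year + n, dtype=float),
                       value=mean + noise, resolution=1.0, label="regime-series")


def gen_site_burn_matrix(n_years: int, n_sites: int, base_p: float,
                         lfy_years: Sequence[int] = (), lfy_p: float = 0.0,
                         seed: int = 0, start_year: int = 0) -> SiteBurnMatrix:
    """Binomial site-burning with probability-inflated large fire years.

    Every site-year is an independent Bernoulli draw: probability
    ``lfy_p`` in planted LFY years (given as indices into the year
    axis), ``base_p`` otherwise.  All sites are marked recording.
    """
    for p in (base_p, lfy_p):
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError("probabilities must lie in [0, 1]")
    if lfy_years and not 0.0 <= base_p <= lfy_p:
        raise InvalidParameterError("need base_p ≤ lfy_p when planting LFYs")
    lfy_idx = np.asarray(list(lfy_years), dtype=int)
    if lfy_idx.size and (lfy_idx.min() < 0 or lfy_idx.max() >= n_years):
        raise InvalidParameterError("lfy_years out of range")
    rng = np.random.default_rng(seed)
    p_year = np.full(n_years, base_p)
    p_year[lfy_idx] = lfy_p
    burned = rng.random((n_years, n_sites)) < p_year[:, None]
    return SiteBurnMatrix(
        years=np.arange(start_year, start_year + n_years, dtype=int),
        sites=[f"site{j:02d}" for j in range(n_sites)],
        burned=burned,
        recording=np.ones((n_years, n_sites), dtype=bool),
    )


def gen_teleconnected_field(index: ProxySeries, grid_shape: tuple[int, int],
                            spec: TeleconnectionSpec, seed: int = 0,
                            monthly: bool = False) -> GriddedField:
    """Gridded field with a rectangular block coupled to ``index``.

    The index is standardised internally, so in-block cells have slope
    ``coupling`` against a unit-variance signal plus independent
    N(0, noise_sd²) noise; all other cells are pure noise.  By default
    one time step per index point on an annual axis; with
    ``monthly=True`` the same yearly coupled value is laid down for all
    12 months (the seasonal averaging downstream recovers it).
    """
    nlat, nlon = grid_shape
    (la0, la1), (lo0, lo1) = spec.block_lat_range, spec.block_lon_range
    if not (0 <= la0 < la1 <= nlat and 0 <= lo0 < lo1 <= nlon):
        raise InvalidParameterError("teleconnection block outside grid bounds")
    n = len(index)
    rng = np.random.default_rng(seed)
    z = (index.value - index.value.mean()) / index.value.std(ddof=1)
    years = index.time.astype(int)
    nt = n * 12 if monthly else n
    vals = rng.normal(0.0, spec.noise_sd, size=(nt, nlat, nlon))
    signal = np.repeat(z, 12) if monthly else z
    vals[:, la0:la1, lo0:lo1] += spec.coupling * signal[:, None, None]
    lat = np.linspace(-90.0 + 90.0 / nlat, 90.0 - 90.0 / nlat, nlat)
    lon = np.linspace(-180.0 + 180.0 / nlon, 180.0 - 180.0 / nlon, nlon)
    if monthly:
        time = np.array([np.datetime64(f"{y:04d}-{m:02d}", "M")
                         for y in years for m in range(1, 13)])
    else:
        time = np.array([np.datetime64(f"{y:04d}-01", "M") for y in years])
    return GriddedField(lat=lat, lon=lon, time=time, values=vals,
                        units="synthetic", frequency="monthly" if monthly else "annual")
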