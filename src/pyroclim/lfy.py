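"""Large fire year (LFY) detection from a multi-site fire record.

A regional fire-history network records, for every year and site,
whether the site burned and whether it was recording (alive trees with
scar-sensitive surfaces present).  Treating site-burning in a year as a
binomial process with N recording areas and per-area burn probability
p, a year in which X areas burned is anomalous when the upper-tail
probability P[count ≥ X | N, p] is small.  Years are flagged as LFYs
when that tail probability falls below ``alpha`` *and* the fraction of
recording sites burned exceeds a synchronicity threshold
(``min_fraction``) — large years must be both statistically surprising
and spatially synchronous.  The overall fit of the binomial model is
assessed with a Pearson chi-square test of the observed yearly
burn-count frequencies against binomial expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "SiteBurnMatrix",
    "BinomialFireModel",
    "LFYResult",
    "binomial_pmf",
    "estimate_p",
    "detect_lfy",
    "chi_square_contingency",
    "chi_square_fit",
]


@dataclass(frozen=True)
class SiteBurnMatrix:
    """Per-year, per-site burned/recording indicators.

    ``burned[i, j]`` is True when site j burned in year ``years[i]``;
    a site can only burn while recording (``burned ⇒ recording``).
    """

    years: np.ndarray
    sites: list[str]
    burned: np.ndarray
    recording: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        burned = np.asarray(self.burned, dtype=bool)
        recording = np.asarray(self.recording, dtype=bool)
        if burned.shape != (len(years), len(self.sites)) or burned.shape != recording.shape:
            raise InvalidParameterError("matrix dimensions must match years × sites")
        if np.any(burned & ~recording):
            raise InvalidParameterError("a site cannot burn while not recording")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "burned", burned)
        object.__setattr__(self, "recording", recording)

    @property
    def n_burned(self) -> np.ndarray:
        """X per year: number of recording sites that burned."""
        return self.burned.sum(axis=1)

    @property
    def n_recording(self) -> np.ndarray:
        """N per year: number of recording sites."""
        return self.recording.sum(axis=1)

    def restrict(self, year_min: int, year_max: int) -> "SiteBurnMatrix":
        """Sub-matrix for ``year_min ≤ year ≤ year_max`` (period-specific p)."""
        sel = (self.years >= year_min) & (self.years <= year_max)
        return SiteBurnMatrix(self.years[sel], self.sites,
                              self.burned[sel], self.recording[sel])


@dataclass(frozen=True)
class BinomialFireModel:
    """Binomial burn model: p = probability of an area burning in any year."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError("p must lie in [0, 1]")

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True)
class LFYResult:
    """Per-year LFY diagnostics plus the global chi-square model check."""

    years: np.ndarray
    X: np.ndarray
    N: np.ndarray
    fraction_burned: np.ndarray
    tail_prob: np.ndarray
    is_lfy: np.ndarray
    chi_square_stat: float
    chi_square_p: float
    alpha: float
    min_fraction: float
    model: BinomialFireModel

    @property
    def lfy_years(self) -> np.ndarray:
        return self.years[self.is_lfy]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years, "X": self.X, "N": self.N,
            "fraction_burned": self.fraction_burned,
            "tail_prob": self.tail_prob, "is_lfy": self.is_lfy,
        })


def binomial_pmf(N: int, X, p: float):
    """P[count = X] for a Binomial(N, p), evaluated in log space.

    Stable for N up to at least 10⁴; ``X`` may be a scalar or array.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError("p must lie in [0, 1]")
    Xa = np.asarray(X)
    if np.any(Xa < 0) or np.any(Xa > N):
        raise InvalidParameterError("X must satisfy 0 ≤ X ≤ N")
    out = stats.binom.pmf(Xa, N, p)
    return float(out) if np.isscalar(X) else out


def estimate_p(matrix: SiteBurnMatrix) -> BinomialFireModel:
    """Pooled estimate: burned site-years over recording site-years."""
    n_rec = int(matrix.recording.sum())
    if n_rec == 0:
        raise DegenerateInputError("no recording site-years")
    return BinomialFireModel(p=float(matrix.burned.sum()) / n_rec)


def detect_lfy(matrix: SiteBurnMatrix, alpha: float = 0.05,
               min_fraction: float = 0.0,
               model: BinomialFireModel | None = None) -> LFYResult:
    """Flag years whose burn count is binomially anomalous and synchronous.

    For each year with N > 0 recording sites the upper-tail probability
    P[count ≥ X] under Binomial(N, p) is computed; a year is an LFY when
    ``tail_prob ≤ alpha`` and ``fraction_burned ≥ min_fraction``.  Years
    with no recording sites are dropped, not treated as zero-burn years.
    ``model`` defaults to :func:`estimate_p` on the matrix.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    if len(matrix.years) == 0:
        raise DegenerateInputError("empty site-burn matrix")
    p_estimated = model is None
    model = model or estimate_p(matrix)
    keep = matrix.n_recording > 0
    years = matrix.years[keep]
    X = matrix.n_burned[keep]
    N = matrix.n_recording[keep]
    frac = X / N
    # sf(X-1) = P[count ≥ X]; vectorised over years with varying N
    tail = stats.binom.sf(X - 1, N, model.p)
    flags = (tail <= alpha) & (frac >= min_fraction)
    try:
        chi_stat, chi_p = chi_square_fit(matrix, model, p_estimated=p_estimated)
    except DegenerateInputError:
        # too few count classes for a goodness-of-fit verdict
        chi_stat, chi_p = float("nan"), float("nan")
    return LFYResult(years=years, X=X, N=N, fraction_burned=frac,
                     tail_prob=tail, is_lfy=flags,
                     chi_square_stat=chi_stat, chi_square_p=chi_p,
                     alpha=alpha, min_fraction=min_fraction, model=model)


def chi_square_contingency(observed: np.ndarray, expected_probs: np.ndarray,
                           p_estimated: bool = True) -> tuple[float, float]:
    """Pearson chi-square of burn-count class frequencies vs expectation.

    ``observed[k]`` counts years whose burn count fell in class k;
    ``expected_probs`` are the matching binomial class probabilities
    (must sum to 1).  Trailing classes are pooled until every expected
    count is ≥ 5 (Cochran's rule); degrees of freedom are
    classes − 1 − 1 when p was estimated from the data.
    """
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape:
        raise InvalidParameterError("observed and expected_probs lengths differ")
    if abs(probs.sum() - 1.0) > 1e-8:
        raise InvalidParameterError("expected_probs must sum to 1")
    n = obs.sum()
    exp = n * probs
    # pool trailing classes until expected ≥ 5 everywhere
    while len(exp) > 2 and exp[-1] < 5:
        exp = np.concatenate([exp[:-2], [exp[-2] + exp[-1]]])
        obs = np.concatenate([obs[:-2], [obs[-2] + obs[-1]]])
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = len(obs) - 1 - (1 if p_estimated else 0)
    if df < 1:
        raise DegenerateInputError("not enough classes after pooling")
    return stat, float(stats.chi2.sf(stat, df))


def chi_square_fit(matrix: SiteBurnMatrix,
                   model: BinomialFireModel | None = None,
                   p_estimated: bool | None = None) -> tuple[float, float]:
    """Chi-square goodness of fit of yearly burn counts to the binomial model.

    Builds the observed count-class table over years (classes X = 0..max N)
    and the expected class probabilities, averaging the binomial pmf over
    the per-year number of recording sites when N varies.
    """
    if p_estimated is None:
        p_estimated = model is None
    model = model or estimate_p(matrix)
    keep = matrix.n_recording > 0
    X = matrix.n_burned[keep]
    N = matrix.n_recording[keep]
    if len(X) == 0:
        raise DegenerateInputError("no recording years")
    n_max = int(N.max())
    observed = np.bincount(X, minlength=n_max + 1).astype(float)
    ks = np.arange(n_max + 1)
    probs = np.zeros(n_max + 1)
    for n_rec in np.unique(N):
        w = np.mean(N == n_rec)
        pmf = stats.binom.pmf(ks, n_rec, model.p)
        probs += w * np.where(ks <= n_rec, pmf, 0.0)
    probs /= probs.sum()
    return chi_square_contingency(observed, probs, p_estimated=p_estimated)
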