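"""Per-stratum rate-of-change estimation.

The central quantity is the AROCM (Average Rate Of Change in Methylation):
the least-squares slope of standardized mean methylation on chronological
age within one stratum (a dog breed, or a species x tissue combination).
Because the response is standardized to unit population SD, the slope
decomposes exactly as

    AROCM = Cor(Methyl, Age) / (SD(R) * L)

where R = Age / L is relative age and L the stratum's maximum lifespan.
All moments here use the population convention (divisor n).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateStratumError

__all__ = [
    "AgeInterval",
    "StratumView",
    "StratumStats",
    "scale_values",
    "relative_ages",
    "pearson",
    "spearman",
    "ols_line",
    "estimate_arocm",
    "split_young_old",
]


@dataclass(frozen=True)
class AgeInterval:
    """Half-open relative-age interval [lower, upper) within [0, 1]."""

    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError(
                f"invalid relative-age interval [{self.lower}, {self.upper})"
            )

    def contains(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return (r >= self.lower) & (r < self.upper)


@dataclass
class StratumView:
    """One stratum's samples restricted to a relative-age interval.

    ``methyl`` is the per-sample mean beta over the chosen CpG set;
    ``scaled`` is its standardization to mean 0 / population SD 1 within
    the retained samples (NaN when n < 2 or methyl is constant).
    """

    stratum_id: str
    ages: np.ndarray
    rel_ages: np.ndarray
    methyl: np.ndarray
    scaled: np.ndarray
    L: float
    interval: AgeInterval
    species: str | None = None
    tissue: str | None = None
    gestation: float = 0.0
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(len(self.ages))

    @property
    def effective_lifespan(self) -> float:
        """Lifespan entering the relative-age denominator: L + GT."""
        return self.L + self.gestation


def scale_values(v) -> np.ndarray:
    """Standardize a vector to mean 0 and population SD 1 (divisor n)."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise DegenerateStratumError("too_few_samples")
    if np.all(v == v[0]):
        raise DegenerateStratumError("constant_vector")
    sd = v.std()
    if not np.isfinite(sd):
        raise DegenerateStratumError("constant_vector")
    return (v - v.mean()) / sd


def relative_ages(ages, L: float, gestation: float = 0.0) -> np.ndarray:
    """Relative age R = (Age + GT) / (L + GT).

    Gestation time (GT, years) shifts the origin so that prenatal samples
    with small negative chronological ages map into [0, 1).
    """
    ages = np.asarray(ages, dtype=float)
    if L <= 0:
        raise ValueError("maximum lifespan must be positive")
    if gestation < 0:
        raise ValueError("gestation time must be non-negative")
    r = (ages + gestation) / (L + gestation)
    if np.any(r < 0):
        bad = ages[r < 0]
        raise ValueError(
            f"negative relative age for age(s) {bad.tolist()}; "
            "prenatal samples need a gestation time"
        )
    return r


def pearson(x, y) -> float:
    """Pearson correlation (divisor-invariant, population moments used)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateStratumError("constant_vector")
    sx, sy = x.std(), y.std()
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Returns NaN (with a warning) when either vector is constant, where the
    rank correlation is undefined.
    """
    from scipy import stats as sps
    import warnings

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("spearman undefined for a constant vector; returning NaN")
        return float("nan")
    return pearson(sps.rankdata(x), sps.rankdata(y))


def ols_line(x, y) -> tuple[float, float]:
    """Simple least-squares fit y = b0 + b1 x; returns (b0, b1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]):
        raise DegenerateStratumError("constant_ages")
    vx = x.var()
    b1 = ((x - x.mean()) * (y - y.mean())).mean() / vx
    b0 = y.mean() - b1 * x.mean()
    return float(b0), float(b1)


@dataclass
class StratumStats:
    """Estimated rate-of-change quantities for one stratum.

    ``arocm`` is the OLS slope of ScaledM on age (per year);
    the exact decomposition arocm = cor / (sd_R * (L + GT)) holds up to
    floating-point rounding, as does sd_A = sd_R * (L + GT).
    """

    stratum_id: str
    n: int
    interval: AgeInterval
    cor_methyl_age: float
    sd_R: float
    sd_A: float
    sd_M: float
    arocm: float
    intercept: float
    r_squared: float
    L: float
    resid_sd: float
    gestation: float = 0.0
    species: str | None = None
    tissue: str | None = None

    def replace(self, **kw) -> "StratumStats":
        return dataclasses.replace(self, **kw)


def estimate_arocm(view: StratumView) -> StratumStats:
    """Fit ScaledM ~ Age within one stratum and decompose the slope.

    Raises :class:`DegenerateStratumError` (with a reason code) for strata
    where the slope is undefined: fewer than two samples, constant ages,
    or constant methylation.
    """
    if view.n < 2:
        raise DegenerateStratumError("too_few_samples", view.stratum_id)
    ages = np.asarray(view.ages, dtype=float)
    methyl = np.asarray(view.methyl, dtype=float)
    if np.all(ages == ages[0]):
        raise DegenerateStratumError("constant_ages", view.stratum_id)
    if np.all(methyl == methyl[0]):
        raise DegenerateStratumError("constant_methyl", view.stratum_id)

    scaled = view.scaled
    if scaled is None or np.any(~np.isfinite(scaled)):
        scaled = scale_values(methyl)

    b0, b1 = ols_line(ages, scaled)
    cor = pearson(methyl, ages)
    resid = scaled - (b0 + b1 * ages)
    return StratumStats(
        stratum_id=view.stratum_id,
        n=view.n,
        interval=view.interval,
        cor_methyl_age=cor,
        sd_R=float(np.asarray(view.rel_ages, dtype=float).std()),
        sd_A=float(ages.std()),
        sd_M=float(methyl.std()),
        arocm=b1,
        intercept=b0,
        r_squared=cor * cor,
        L=view.L,
        resid_sd=float(resid.std()),
        gestation=view.gestation,
        species=view.species,
        tissue=view.tissue,
    )


def _subview(view: StratumView, mask: np.ndarray, interval: AgeInterval,
             rescale: bool) -> StratumView:
    methyl = np.asarray(view.methyl, dtype=float)[mask]
    if rescale and methyl.size >= 2 and methyl.std() > 0:
        scaled = scale_values(methyl)
    elif rescale:
        scaled = np.full(methyl.shape, np.nan)
    else:
        scaled = np.asarray(view.scaled, dtype=float)[mask]
    return StratumView(
        stratum_id=view.stratum_id,
        ages=np.asarray(view.ages, dtype=float)[mask],
        rel_ages=np.asarray(view.rel_ages, dtype=float)[mask],
        methyl=methyl,
        scaled=scaled,
        L=view.L,
        interval=interval,
        species=view.species,
        tissue=view.tissue,
        gestation=view.gestation,
        sample_ids=[s for s, keep in zip(view.sample_ids, mask) if keep],
    )


def split_young_old(view: StratumView, cutoff: float = 0.1,
                    rescale: bool = True) -> tuple[StratumView, StratumView]:
    """Partition a stratum at relative age ``cutoff`` (boundary goes old).

    With ``rescale=True`` (the default) each side is re-standardized within
    itself, matching the situation where young and old animals are analyzed
    as separate strata.  With ``rescale=False`` both sides keep the parent
    stratum's scaling, which preserves the theoretical proportionality
    between young and old slopes of a common life-course curve.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    r = np.asarray(view.rel_ages, dtype=float)
    young_mask = r < cutoff
    lo, up = view.interval.lower, view.interval.upper
    young_iv = AgeInterval(lo, min(cutoff, up)) if lo < cutoff else view.interval
    old_iv = AgeInterval(max(cutoff, lo), up) if up > cutoff else view.interval
    young = _subview(view, young_mask, young_iv, rescale)
    old = _subview(view, ~young_mask, old_iv, rescale)
    return young, old
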