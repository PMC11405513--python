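"""Cross-stratum analyses.

Species-level aggregation (median across tissue strata), correlations of
rate metrics with maximum lifespan on several scales, lifespan-group trend
testing (Mann-Kendall), multivariate lifespan/weight/tissue regressions,
and the SD(R)-stratified sanity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .core import pearson, spearman
from .errors import ArocmError
from .datasets import stats_to_frame

__all__ = [
    "CorrelationResult",
    "TrendResult",
    "aggregate_by_species",
    "lifespan_correlations",
    "assign_lifespan_group",
    "mann_kendall_trend",
    "fit_lifespan_models",
    "stratified_by_sdr",
    "LIFESPAN_GROUP_LABELS",
]

logger = logging.getLogger(__name__)

LIFESPAN_GROUP_LABELS = ("<10", "10-19", "20-24", "25-39", ">=40")
_GROUP_EDGES = (10.0, 20.0, 25.0, 40.0)

_METRIC_COLUMNS = ["arocm", "cor_methyl_age", "adj_arocm", "adj_cor",
                   "sd_R", "r_squared"]


def aggregate_by_species(stats_list, traits: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Median per species across its tissue strata, one row per species.

    Lifespans are taken as the median of the per-stratum values (identical
    when traits are keyed by species).  When a ``traits`` table with an
    ``adult_weight`` column is supplied, weights are joined in.
    """
    frame = stats_to_frame(stats_list)
    if frame.empty:
        return pd.DataFrame(columns=["species", "L"])
    metrics = [c for c in _METRIC_COLUMNS if c in frame.columns]
    agg = frame.groupby("species")[metrics + ["L"]].median()
    agg.insert(0, "n_strata", frame.groupby("species").size())
    if traits is not None and "adult_weight" in traits.columns:
        agg = agg.join(traits["adult_weight"], how="left")
    return agg.reset_index()


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def _t_test_p(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t approximation (df = n - 2)."""
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def lifespan_correlations(table: pd.DataFrame, metric: str, mode: str,
                          a: float = 1.0) -> CorrelationResult:
    """Correlation between a rate metric and maximum lifespan.

    Modes: ``pearson-raw`` (metric vs L), ``pearson-log-log`` (natural logs
    of both, strata with non-positive metric dropped), ``pearson-vs-inverse-L``
    and ``spearman-vs-inverse-L`` (metric vs a / L, where ``a`` is the
    proportionality constant c_p from the proposition report, 1 when
    unadjusted).  p-values are two-sided t-tests; Spearman uses the same t
    approximation applied to rho.
    """
    if metric not in table.columns or "L" not in table.columns:
        raise ArocmError(f"table needs columns {metric!r} and 'L'")
    sub = table[[metric, "L"]].dropna()
    x = sub[metric].to_numpy(dtype=float)
    L = sub["L"].to_numpy(dtype=float)
    if mode == "pearson-raw":
        y = L
    elif mode == "pearson-log-log":
        keep = (x > 0) & (L > 0)
        if keep.sum() < len(x):
            logger.info("log-log correlation: dropped %d non-positive value(s)",
                        int(len(x) - keep.sum()))
        x, L = x[keep], L[keep]
        x, y = np.log(x), np.log(L)
    elif mode in ("pearson-vs-inverse-L", "spearman-vs-inverse-L"):
        y = a / L
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(x)
    if n < 3:
        raise ArocmError(f"need >= 3 complete pairs, got {n}")
    r = spearman(x, y) if mode.startswith("spearman") else pearson(x, y)
    return CorrelationResult(r=r, p=_t_test_p(r, n), n=n)


def assign_lifespan_group(L: float) -> str:
    """One of five ordered lifespan groups; boundaries go to the upper group."""
    if L <= 0:
        raise ValueError("lifespan must be positive")
    for label, edge in zip(LIFESPAN_GROUP_LABELS, _GROUP_EDGES):
        if L < edge:
            return label
    return LIFESPAN_GROUP_LABELS[-1]


@dataclass
class TrendResult:
    s: int
    var_s: float
    z: float
    p: float
    n: int
    group_labels: tuple | None = None


def mann_kendall_trend(values, groups=None) -> TrendResult:
    """Mann-Kendall test for a monotone trend.

    ``values`` are taken in the given order (e.g. ordered by lifespan
    group).  When ``groups`` (ordinal labels, one per value) is supplied,
    only pairs from different groups contribute to S — within-group order
    carries no information — and the variance receives the tie correction
    for both tied values and tied group ranks.  A continuity-corrected
    normal approximation yields the two-sided p; an all-tied input returns
    S = 0, p = 1.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ArocmError("Mann-Kendall test needs n >= 3")
    if groups is None:
        t = np.arange(n, dtype=float)
        labels = None
    else:
        groups = list(groups)
        if len(groups) != n:
            raise ArocmError("groups must match values in length")
        seen: dict = {}
        for g in groups:
            seen.setdefault(g, len(seen))
        t = np.array([seen[g] for g in groups], dtype=float)
        labels = tuple(seen)

    dx = np.sign(x[:, None] - x[None, :])
    dt = np.sign(t[:, None] - t[None, :])
    s = int(np.triu(dt * dx, k=1).sum())

    def tie_sizes(v):
        _, counts = np.unique(v, return_counts=True)
        return counts[counts > 1].astype(float)

    tx, tt = tie_sizes(x), tie_sizes(t)
    v0 = n * (n - 1) * (2 * n + 5)
    vx = float((tx * (tx - 1) * (2 * tx + 5)).sum())
    vt = float((tt * (tt - 1) * (2 * tt + 5)).sum())
    var_s = (v0 - vx - vt) / 18.0
    if n > 2:
        var_s += (
            (tx * (tx - 1) * (tx - 2)).sum() * (tt * (tt - 1) * (tt - 2)).sum()
        ) / (9.0 * n * (n - 1) * (n - 2))
    var_s += ((tx * (tx - 1)).sum() * (tt * (tt - 1)).sum()) / (2.0 * n * (n - 1))

    if s == 0 or var_s <= 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / math.sqrt(var_s)
    else:
        z = (s + 1) / math.sqrt(var_s)
    p = 1.0 if z == 0.0 else float(2.0 * sps.norm.sf(abs(z)))
    return TrendResult(s=s, var_s=float(var_s), z=float(z), p=p, n=n,
                       group_labels=labels)


_MODEL_TISSUES = {
    "M3": ("Brain",),
    "M4": ("Brain", "Blood", "Skin", "Liver", "Muscle", "Tail"),
}


def fit_lifespan_models(table: pd.DataFrame, model_id: str) -> pd.DataFrame:
    """OLS regressions relating log rate, log lifespan and log weight.

    * M1: log(L) ~ log(AROCM) + log(Weight)
    * M2: log(AROCM) ~ log(L) + log(Weight)
    * M3: M2 + Brain indicator
    * M4: M2 + Brain/Blood/Skin/Liver/Muscle/Tail indicators

    ``table`` needs columns ``arocm``, ``L``, ``adult_weight`` and, for
    M3/M4, ``tissue``.  Rows where any log argument is non-positive are
    dropped.  Returns a coefficient table with columns Estimate, Std. error,
    t-value, Pr(>|t|).
    """
    if model_id not in ("M1", "M2", "M3", "M4"):
        raise ValueError("model_id must be one of M1..M4")
    needed = ["arocm", "L", "adult_weight"]
    if model_id in _MODEL_TISSUES:
        needed.append("tissue")
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ArocmError(f"table is missing column(s): {missing}")
    sub = table[needed].dropna()
    sub = sub[(sub["arocm"] > 0) & (sub["L"] > 0) & (sub["adult_weight"] > 0)]
    n = len(sub)

    log_a = np.log(sub["arocm"].to_numpy(dtype=float))
    log_l = np.log(sub["L"].to_numpy(dtype=float))
    log_w = np.log(sub["adult_weight"].to_numpy(dtype=float))
    if model_id == "M1":
        y = log_l
        X = pd.DataFrame({"log(AROCM)": log_a, "log(AverageWeight)": log_w})
    else:
        y = log_a
        X = pd.DataFrame({"log(Lifespan)": log_l, "log(AverageWeight)": log_w})
        for tis in _MODEL_TISSUES.get(model_id, ()):
            X[tis] = (sub["tissue"].str.lower() == tis.lower()).astype(float).to_numpy()
    if n < X.shape[1] + 2:
        raise ArocmError(f"{model_id}: {n} usable rows are too few for "
                         f"{X.shape[1] + 1} coefficients")
    X = sm.add_constant(X)
    try:
        fit = sm.OLS(y, X).fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover - collinear input
        raise ArocmError(f"{model_id}: singular design matrix") from exc
    out = pd.DataFrame({
        "Estimate": fit.params,
        "Std. error": fit.bse,
        "t-value": fit.tvalues,
        "Pr(>|t|)": fit.pvalues,
    })
    out.index.name = "Covariate"
    return out.rename(index={"const": "(Intercept)"}).reset_index()


def stratified_by_sdr(stats_list, bins=((0.2, 0.4), (0.4, 0.6))
                      ) -> dict[tuple, CorrelationResult]:
    """Unadjusted AROCM vs 1/L correlation within each open SD(R) bin.

    Restricting to strata of comparable SD(R) is the conventional guard
    against the sampling-window confounder; bins with fewer than 3 strata
    are skipped (logged).
    """
    for i, (lo, hi) in enumerate(bins):
        if lo >= hi:
            raise ValueError(f"bin {i} is empty: ({lo}, {hi})")
    frame = stats_to_frame(stats_list)
    results: dict[tuple, CorrelationResult] = {}
    for lo, hi in bins:
        sub = frame[(frame["sd_R"] > lo) & (frame["sd_R"] < hi)]
        if len(sub) < 3:
            logger.info("SD(R) bin (%g, %g): %d strata; skipped", lo, hi, len(sub))
            continue
        results[(lo, hi)] = lifespan_correlations(
            sub, "arocm", "pearson-vs-inverse-L")
    return results
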