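"""SD(R)-power adjustment of rate-of-change estimates.

Heterogeneous relative-age sampling windows make SD(R) vary across strata,
which confounds both the slope (AROCM) and the age correlation.  The
adjustment trades the confounder between the two with a power p in [0, 1]:

    Adj.Cor   = Cor(Methyl, Age) / SD(R)^p
    Adj.AROCM = AROCM * SD(R)^(1-p)

so that Adj.AROCM = Adj.Cor / L holds identically for every p.  The power
is selected by minimizing a robust dispersion objective (quartile
coefficient of dispersion) of the adjusted correlations across strata; the
propositions below then predict the strength of the inverse relation
between the adjusted rate and lifespan on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import StratumStats, pearson
from .errors import ArocmError

__all__ = [
    "AdjustedStats",
    "PropositionReport",
    "PowerSelection",
    "adjust_stats",
    "qcod",
    "select_adjustment_power",
    "proposition_checks",
]

DEFAULT_POWER_GRID = np.round(np.arange(0, 1.0001, 0.005), 10)


@dataclass
class AdjustedStats(StratumStats):
    """StratumStats augmented with power-adjusted quantities.

    Natural logs are NaN when the corresponding argument is non-positive.
    """

    p: float = 1.0
    adj_cor: float = float("nan")
    adj_arocm: float = float("nan")
    log_adj_cor: float = float("nan")
    log_adj_arocm: float = float("nan")
    log_L: float = float("nan")


def _safe_log(x: float) -> float:
    return math.log(x) if x > 0 else float("nan")


def adjust_stats(stats: StratumStats, p: float) -> AdjustedStats:
    """Apply the SD(R)^p adjustment to one stratum's estimates."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("adjustment power p must lie in [0, 1]")
    if stats.sd_R <= 0:
        raise ArocmError(
            f"stratum {stats.stratum_id!r} has SD(R) = {stats.sd_R}; "
            "adjustment undefined"
        )
    adj_cor = stats.cor_methyl_age / stats.sd_R ** p
    adj_arocm = stats.arocm * stats.sd_R ** (1.0 - p)
    return AdjustedStats(
        **stats.__dict__,
        p=p,
        adj_cor=adj_cor,
        adj_arocm=adj_arocm,
        log_adj_cor=_safe_log(adj_cor),
        log_adj_arocm=_safe_log(adj_arocm),
        log_L=_safe_log(stats.L),
    )


def qcod(values) -> float:
    """Quartile coefficient of dispersion (Q3 - Q1) / (Q3 + Q1).

    Quartiles use linear interpolation between order statistics (the common
    "type 7" rule).  Undefined when Q1 + Q3 <= 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    denom = q1 + q3
    if denom <= 0:
        raise ArocmError(f"QCOD undefined: Q1 + Q3 = {denom} <= 0")
    return float((q3 - q1) / denom)


def _coefvar(values: np.ndarray) -> float:
    return float(values.std() / values.mean())


@dataclass
class PowerSelection:
    """Result of the grid search for the adjustment power."""

    p_optimal: float
    profile: pd.DataFrame  # columns: p, objective
    objective: str
    degenerate: bool
    n_used: int
    n_excluded: int


def select_adjustment_power(
    stats_list,
    grid=None,
    objective: str = "qcod",
    on_log: bool = False,
) -> PowerSelection:
    """Pick the power p minimizing the dispersion of Adj.Cor across strata.

    Strata with non-positive age correlation are excluded (counted).  The
    default objective is the QCOD of the raw adjusted correlations; pass
    ``on_log=True`` for the dispersion of their natural logs, or
    ``objective="cv"`` for the coefficient of variation.  Ties resolve to
    the smallest p.  A flat profile (SD(R) constant across strata, where
    the adjustment cannot discriminate) sets ``degenerate=True``.
    """
    if grid is None:
        grid = DEFAULT_POWER_GRID
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("power grid must lie within [0, 1]")
    if objective not in ("qcod", "cv"):
        raise ValueError("objective must be 'qcod' or 'cv'")

    usable = [s for s in stats_list if s.cor_methyl_age > 0 and s.sd_R > 0]
    n_excluded = len(list(stats_list)) - len(usable)
    if len(usable) < 3:
        raise ArocmError(
            f"power selection needs >= 3 strata with positive age correlation; "
            f"got {len(usable)}"
        )
    cors = np.array([s.cor_methyl_age for s in usable])
    sd_r = np.array([s.sd_R for s in usable])

    values = np.empty_like(grid)
    for i, p in enumerate(grid):
        adj = cors / sd_r ** p
        arg = np.log(adj) if on_log else adj
        try:
            values[i] = qcod(arg) if objective == "qcod" else _coefvar(arg)
        except ArocmError:
            # log-scale QCOD is undefined where the quartiles straddle zero
            values[i] = np.inf
    if not np.any(np.isfinite(values)):
        raise ArocmError("dispersion objective undefined on the whole grid")

    best = int(np.argmin(values))  # argmin takes the first (smallest p) on ties
    degenerate = bool(np.ptp(values) < 1e-12)
    profile = pd.DataFrame({"p": grid, "objective": values})
    return PowerSelection(
        p_optimal=float(grid[best]),
        profile=profile,
        objective=objective + ("_log" if on_log else ""),
        degenerate=degenerate,
        n_used=len(usable),
        n_excluded=n_excluded,
    )


@dataclass
class PropositionReport:
    """Cross-stratum moments connecting the adjusted rate to lifespan.

    Under condition C1 — zero correlation between log lifespan and log
    adjusted correlation — the observed Cor(log L, log Adj.AROCM) equals
    -1 / sqrt(1 + Var(log Adj.Cor) / Var(log L)) exactly; when the variance
    ratio vanishes the correlation reaches -1 and Adj.AROCM ~ c_p / L with
    c_p = exp(mean log Adj.Cor).
    """

    S: int
    n_excluded: int
    var_log_adj_cor: float
    var_log_L: float
    ratio_p: float
    ratio_cv: float
    predicted_cor: float
    observed_cor: float
    c_p: float
    c1_cor: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def proposition_checks(adjusted_list) -> PropositionReport:
    """Compute the cross-stratum report for a list of adjusted strata.

    Strata whose adjusted correlation (or lifespan) is non-positive are
    excluded — the log scale does not apply to them — and counted.
    All cross-stratum variances use the population convention (divisor S).
    """
    usable = [s for s in adjusted_list if s.adj_cor > 0 and s.L > 0]
    n_excluded = len(list(adjusted_list)) - len(usable)
    if len(usable) < 3:
        raise ArocmError(
            f"proposition checks need >= 3 strata with positive Adj.Cor; "
            f"got {len(usable)}"
        )
    log_L = np.array([s.log_L for s in usable])
    log_adj_cor = np.array([s.log_adj_cor for s in usable])
    log_adj_roc = np.array([s.log_adj_arocm for s in usable])
    adj_cor = np.array([s.adj_cor for s in usable])
    lifespans = np.array([s.L for s in usable])

    var_c = float(log_adj_cor.var())
    var_l = float(log_L.var())
    ratio = var_c / var_l
    ratio_cv = _coefvar(adj_cor) ** 2 / _coefvar(lifespans) ** 2
    return PropositionReport(
        S=len(usable),
        n_excluded=n_excluded,
        var_log_adj_cor=var_c,
        var_log_L=var_l,
        ratio_p=ratio,
        ratio_cv=ratio_cv,
        predicted_cor=-1.0 / math.sqrt(1.0 + ratio),
        observed_cor=pearson(log_L, log_adj_roc),
        c_p=float(np.exp(log_adj_cor.mean())),
        # a constant Adj.Cor is trivially uncorrelated with lifespan
        c1_cor=0.0 if var_c == 0.0 else pearson(log_L, log_adj_cor),
    )
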