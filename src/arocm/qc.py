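"""Stratum exclusion rules.

Reliable slope estimates need enough samples, a wide enough spread of
relative ages, and (for the single-tissue dog mode) a decent linear fit.
Mammal mode additionally screens extreme slopes with a derived-interval
check: a primary AROCM outside (-1, 10) is declared an outlier only when
the AROCMs recomputed on wider nested age intervals of the same stratum
are themselves well-behaved — otherwise the extreme value may be a real
property of the stratum and is kept but flagged for review.

All rules are pure functions of (view, stats, config); every violated rule
is reported, never just the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import AgeInterval, StratumStats, StratumView, estimate_arocm, scale_values
from .errors import DegenerateStratumError

__all__ = ["FilterConfig", "FilterDecision", "apply_filters",
           "derived_interval_check"]

logger = logging.getLogger(__name__)

# rule codes
SMALL_N = "small_n"
LOW_SD_R = "low_sd_r"
POOR_FIT = "poor_fit"
AROCM_OUTLIER = "arocm_outlier"
RANGE_UNVERIFIABLE = "range_unverifiable"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for stratum exclusion.

    Dog mode: SD(R) >= 0.1 and fit R^2 >= 0.2, no slope-range rule.
    Mammal mode: SD(R) >= 0.06 and AROCM within the open range (-1, 10),
    backed by the derived-interval outlier check.
    """

    mode: str = "mammal"
    min_n: int = 3
    min_sd_r: float = 0.06
    arocm_range: tuple[float, float] | None = (-1.0, 10.0)
    min_r2: float | None = None
    derived_bounds: tuple[float, ...] = (0.1, 0.2, 0.3)

    def __post_init__(self):
        if self.mode not in ("dog", "mammal"):
            raise ValueError("mode must be 'dog' or 'mammal'")
        if self.min_n < 1 or self.min_sd_r <= 0:
            raise ValueError("thresholds must be positive")
        if self.arocm_range is not None and self.arocm_range[0] >= self.arocm_range[1]:
            raise ValueError("arocm_range lower bound must be below upper bound")

    @classmethod
    def dog(cls, **kw) -> "FilterConfig":
        kw.setdefault("min_sd_r", 0.1)
        kw.setdefault("min_r2", 0.2)
        kw.setdefault("arocm_range", None)
        return cls(mode="dog", **kw)

    @classmethod
    def mammal(cls, **kw) -> "FilterConfig":
        return cls(mode="mammal", **kw)


@dataclass
class FilterDecision:
    """Outcome for one stratum: kept iff no rule fired.

    ``review`` flags strata kept despite an extreme slope because the
    derived-interval check could not confirm an outlier.
    """

    stratum_id: str
    kept: bool
    reasons: list[str] = field(default_factory=list)
    review: list[str] = field(default_factory=list)
    derived_arocms: dict = field(default_factory=dict)


def derived_interval_check(view: StratumView, stats: StratumStats,
                           config: FilterConfig):
    """Re-estimate the AROCM on nested intervals [0, b) of the same stratum.

    ``view`` must cover the stratum's full relative-age range.  Returns
    ``(is_outlier, derived)`` where ``derived`` maps each upper bound b to
    the re-estimated slope.  ``is_outlier`` is True when every estimable
    derived slope lies inside the configured range, None (abstention) when
    any derived interval has too few samples to estimate.
    """
    lo, hi = config.arocm_range if config.arocm_range else (-1.0, 10.0)
    derived: dict[float, float] = {}
    abstained = False
    bounds = [b for b in config.derived_bounds
              if abs(b - stats.interval.upper) > 1e-12]
    for b in bounds:
        interval = AgeInterval(0.0, b)
        mask = interval.contains(view.rel_ages)
        if mask.sum() < config.min_n:
            abstained = True
            logger.info("stratum %s: derived interval [0, %g) has %d samples; "
                        "check abstains", view.stratum_id, b, int(mask.sum()))
            continue
        methyl = np.asarray(view.methyl, dtype=float)[mask]
        sub = StratumView(
            stratum_id=view.stratum_id,
            ages=np.asarray(view.ages, dtype=float)[mask],
            rel_ages=np.asarray(view.rel_ages, dtype=float)[mask],
            methyl=methyl,
            scaled=np.full(methyl.shape, np.nan),
            L=view.L, interval=interval, species=view.species,
            tissue=view.tissue, gestation=view.gestation,
        )
        try:
            sub.scaled = scale_values(methyl)
            derived[b] = estimate_arocm(sub).arocm
        except DegenerateStratumError:
            abstained = True
    if abstained or not derived:
        return None, derived
    is_outlier = all(lo < v < hi for v in derived.values())
    return is_outlier, derived


def apply_filters(views, stats_list, config: FilterConfig,
                  full_views=None) -> list[FilterDecision]:
    """Classify every stratum against all rules of the given mode.

    ``full_views`` optionally maps stratum_id to a full-age-range view used
    by the derived-interval check; by default the primary views themselves
    are used (appropriate when the primary interval is the full range).
    """
    if full_views is None:
        full_views = {}
    view_by_id = {v.stratum_id: v for v in views}
    decisions: list[FilterDecision] = []
    for stats in stats_list:
        reasons: list[str] = []
        review: list[str] = []
        derived: dict = {}
        if stats.n < config.min_n:
            reasons.append(SMALL_N)
        if stats.sd_R < config.min_sd_r:
            reasons.append(LOW_SD_R)
        if config.min_r2 is not None and stats.r_squared < config.min_r2:
            reasons.append(POOR_FIT)
        if config.arocm_range is not None:
            lo, hi = config.arocm_range
            if not (lo < stats.arocm < hi):
                full = full_views.get(stats.stratum_id,
                                      view_by_id.get(stats.stratum_id))
                if full is None:
                    reasons.append(RANGE_UNVERIFIABLE)
                else:
                    is_outlier, derived = derived_interval_check(
                        full, stats, config)
                    if is_outlier is None:
                        reasons.append(RANGE_UNVERIFIABLE)
                    elif is_outlier:
                        reasons.append(AROCM_OUTLIER)
                    else:
                        review.append(AROCM_OUTLIER)
        decisions.append(FilterDecision(
            stratum_id=stats.stratum_id,
            kept=not reasons,
            reasons=reasons,
            review=review,
            derived_arocms=derived,
        ))
    return decisions
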