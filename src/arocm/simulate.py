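"""Synthetic multi-stratum methylation studies with known truth.

The generator emulates the statistical structure of a comparative
methylation study: many strata (species x tissue) with log-uniform maximum
lifespans, uneven relative-age sampling windows (the mechanism behind
heterogeneous SD(R)), and CpG groups whose mean methylation follows the
piecewise log-linear life-course model

    signal(R) = gamma0 + gamma1 * g(R)

on the beta scale through a per-probe baseline and loading:

    beta_ij = clip(baseline_j + k_j * signal(R_i) + s_i + e_ij, 0, 1).

Two probe groups are emitted: a low-baseline, positive-loading group
("BivProm2-like": bivalent promoter CpGs bound by PRC2, which gain
methylation with age) and a high-baseline, negative-loading group
("Quies1-like": quiescent-state CpGs that lose methylation), so that
strata with negative age correlation exist.  Windows and gamma1 are drawn
independently of lifespan, so the condition C1 (no correlation between log
lifespan and log adjusted age correlation) holds by design up to sampling
noise.

Truth per stratum (lifespan, gamma, window, realized SD(R), mean probe
loading, derivative-based young/old rates) is recorded for recovery
testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AgeInterval, ols_line
from .datasets import StudyBundle, ProbeSet, build_strata, select_state_cpgs
from .errors import ArocmError
from .lifecourse import loglinear_transform

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_study",
           "recover_estimates", "recovery_report", "write_synthetic"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate a mammal-scale study.

    Windows [a, b] of relative age are drawn per stratum (uniform start and
    width); samples are uniform within the window, so realized SD(R) is
    approximately (b - a) / sqrt(12).  ``young_fraction``, when set, forces
    that fraction of samples below the knot (oversampling the young side of
    the window), which several life-course analyses need.
    """

    n_strata: int = 50
    n_per_stratum: int = 200
    lifespan_range: tuple[float, float] = (2.0, 60.0)   # years, log-uniform
    window_start: tuple[float, float] = (0.02, 0.05)    # relative age
    window_width: tuple[float, float] = (0.4, 0.9)
    young_fraction: float | None = None
    gamma1_range: tuple[float, float] = (0.5, 1.5)
    gamma0: float = 0.0
    transform: str = "g"
    knot: float = 0.1
    n_probes: int = 20                                  # per probe group
    bivprom_baseline: float = 0.10
    bivprom_loading: float = 0.05
    quies_baseline: float = 0.90
    quies_loading: float = -0.05
    baseline_jitter_sd: float = 0.02
    loading_jitter: float = 0.25                        # relative, uniform
    probe_noise_sd: float = 0.02
    sample_noise_sd: float = 0.0
    include_negative_group: bool = True
    tissue: str = "blood"

    def __post_init__(self):
        if self.n_strata < 1 or self.n_per_stratum < 2:
            raise ValueError("need at least 1 stratum and 2 samples each")
        for sd in (self.probe_noise_sd, self.sample_noise_sd,
                   self.baseline_jitter_sd):
            if sd < 0:
                raise ValueError("noise SDs must be non-negative")
        a_lo, a_hi = self.window_start
        w_lo, w_hi = self.window_width
        if not (0.0 < a_lo <= a_hi and 0.0 < w_lo <= w_hi
                and a_hi + w_hi <= 1.0):
            raise ValueError("window start/width must define windows within (0, 1]")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticTruth:
    """Per-stratum generator parameters, reproducible from (config, seed)."""

    config: SyntheticConfig
    seed: int
    frame: pd.DataFrame  # one row per stratum
    clip_rate: float


def _draw_window(cfg: SyntheticConfig, rng: np.random.Generator
                 ) -> tuple[float, float]:
    a = rng.uniform(*cfg.window_start)
    w = rng.uniform(*cfg.window_width)
    return a, min(a + w, 1.0 - 1e-9)


def _draw_rel_ages(cfg: SyntheticConfig, a: float, b: float, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    if cfg.young_fraction is None or a >= cfg.knot or b <= cfg.knot:
        return rng.uniform(a, b, size=n)
    n_young = int(round(cfg.young_fraction * n))
    young = rng.uniform(a, cfg.knot, size=n_young)
    old = rng.uniform(cfg.knot, b, size=n - n_young)
    return np.concatenate([young, old])


def simulate_study(config: SyntheticConfig, seed: int = 0
                   ) -> tuple[StudyBundle, SyntheticTruth]:
    """Generate a study bundle plus its ground truth.

    The bundle passes :func:`arocm.datasets.load_study`-level validation and
    round-trips through the CSV writers.  A clipping rate above 10% (betas
    pushed outside [0, 1] by noise) raises a warning, since clipping bends
    the generative trajectories.
    """
    rng = np.random.default_rng(seed)
    cfg = config

    groups = [("BivProm2", "+", cfg.bivprom_baseline, cfg.bivprom_loading)]
    if cfg.include_negative_group:
        groups.append(("Quies1", "-", cfg.quies_baseline, cfg.quies_loading))

    probe_rows = []
    probe_params = []  # (probe_id, group_index, baseline_j, k_j)
    pid = 0
    for gi, (state, prc2, base, load) in enumerate(groups):
        for _ in range(cfg.n_probes):
            pid += 1
            probe_id = f"cg{pid:06d}"
            baseline_j = base + rng.normal(0.0, cfg.baseline_jitter_sd)
            k_j = load * (1.0 + rng.uniform(-cfg.loading_jitter,
                                            cfg.loading_jitter))
            probe_rows.append({"probe_id": probe_id, "chromatin_state": state,
                               "prc2_bound": prc2})
            probe_params.append((probe_id, gi, baseline_j, k_j))

    sample_rows = []
    beta_rows = []
    truth_rows = []
    trait_rows = []
    n_clipped = 0
    n_total = 0

    log_lo, log_hi = np.log(cfg.lifespan_range[0]), np.log(cfg.lifespan_range[1])
    for s in range(cfg.n_strata):
        species = f"species_{s + 1:03d}"
        stratum_id = f"{species}__{cfg.tissue}"
        L = float(np.exp(rng.uniform(log_lo, log_hi)))
        a, b = _draw_window(cfg, rng)
        gamma1 = float(rng.uniform(*cfg.gamma1_range))
        n = cfg.n_per_stratum
        R = np.sort(_draw_rel_ages(cfg, a, b, n, rng))
        ages = R * L
        T, _ = loglinear_transform(R, cfg.transform, cfg.knot)
        signal = cfg.gamma0 + gamma1 * T

        sample_eff = (rng.normal(0.0, cfg.sample_noise_sd, size=n)
                      if cfg.sample_noise_sd > 0 else np.zeros(n))
        k_means = {}
        block = {}
        for probe_id, gi, baseline_j, k_j in probe_params:
            raw = (baseline_j + k_j * signal + sample_eff
                   + rng.normal(0.0, cfg.probe_noise_sd, size=n))
            clipped = np.clip(raw, 0.0, 1.0)
            n_clipped += int(np.sum(raw != clipped))
            n_total += n
            block[probe_id] = clipped
            k_means.setdefault(gi, []).append(k_j)

        for i in range(n):
            sid = f"s{s + 1:03d}_{i + 1:04d}"
            sample_rows.append({"sample_id": sid, "species": species,
                                "tissue": cfg.tissue, "age": ages[i],
                                "stratum_id": stratum_id})
            beta_rows.append({"sample_id": sid,
                              **{p: block[p][i] for p in block}})

        # adult weight loosely tracks lifespan (allometry-like), for the
        # multivariate model analyses
        weight = float(np.exp(-2.0 + 2.2 * np.log(L) + rng.normal(0.0, 0.5)))
        trait_rows.append({"species": species, "max_lifespan": L,
                           "gestation": 0.0, "adult_weight": weight})

        r_young_mean = float(R[R < cfg.knot].mean()) if np.any(R < cfg.knot) \
            else float("nan")
        truth_rows.append({
            "stratum_id": stratum_id, "species": species, "L": L,
            "gamma0": cfg.gamma0, "gamma1": gamma1,
            "window_low": a, "window_high": b,
            "sd_R": float(R.std()),
            "k_bar": float(np.mean(k_means[0])),
            "arocm_old_true": gamma1 / cfg.knot / L,
            "r_young_mean": r_young_mean,
            "arocm_young_true": (gamma1 / (r_young_mean * L)
                                 if np.isfinite(r_young_mean) else float("nan")),
        })

    betas = pd.DataFrame(beta_rows).set_index("sample_id").sort_index()
    betas = betas.reindex(sorted(betas.columns), axis=1)
    samples = pd.DataFrame(sample_rows).sort_values("sample_id").reset_index(drop=True)
    traits = pd.DataFrame(trait_rows).set_index("species")
    annotation = pd.DataFrame(probe_rows).set_index("probe_id").sort_index()

    bundle = StudyBundle(betas=betas, samples=samples, traits=traits,
                         annotation=annotation)
    bundle.validate()

    clip_rate = n_clipped / max(n_total, 1)
    if clip_rate > 0.10:
        import warnings
        warnings.warn(f"{clip_rate:.1%} of betas were clipped to [0, 1]; "
                      "trajectories are distorted")
    truth = SyntheticTruth(config=cfg, seed=seed,
                           frame=pd.DataFrame(truth_rows), clip_rate=clip_rate)
    return bundle, truth


def recover_estimates(bundle: StudyBundle, truth: SyntheticTruth,
                      min_n: int = 3) -> pd.DataFrame:
    """Re-estimate the generator parameters from the emitted betas.

    gamma1 is identified on the beta scale: the slope of mean methylation
    (positive probe group) on g(R) divided by the stratum's known mean
    probe loading k_bar.  Interval-based young/old rates come from OLS
    slopes of the stratum-standardized methylation restricted to each side
    of the knot (common scaling, so their theoretical ratio is preserved).
    """
    cfg = truth.config
    probeset = select_state_cpgs(bundle, "BivProm2", "+")
    views = build_strata(bundle, probeset, AgeInterval(0.0, 1.0), min_n=min_n)
    tf = truth.frame.set_index("stratum_id")
    rows = []
    for view in views:
        t = tf.loc[view.stratum_id]
        T, _ = loglinear_transform(view.rel_ages, cfg.transform, cfg.knot)
        _, slope_beta = ols_line(T, view.methyl)
        gamma1_hat = slope_beta / t["k_bar"]

        young = view.rel_ages < cfg.knot
        arocm_young = arocm_old = float("nan")
        if young.sum() >= 2 and np.asarray(view.ages)[young].std() > 0:
            _, sl = ols_line(view.ages[young], view.scaled[young])
            arocm_young = sl
        if (~young).sum() >= 2 and np.asarray(view.ages)[~young].std() > 0:
            _, sl = ols_line(view.ages[~young], view.scaled[~young])
            arocm_old = sl
        rows.append({"stratum_id": view.stratum_id,
                     "gamma1_hat": gamma1_hat,
                     "arocm_young_hat": arocm_young,
                     "arocm_old_hat": arocm_old})
    return pd.DataFrame(rows)


def recovery_report(truth: SyntheticTruth, estimates: pd.DataFrame) -> dict:
    """Bias / RMSE / correlation between generator truth and estimates."""
    tf = truth.frame.set_index("stratum_id")
    est = estimates.set_index("stratum_id")
    unmatched = est.index.difference(tf.index)
    if len(unmatched):
        raise ArocmError(f"estimates for unknown strata: {list(unmatched)}")
    joined = est.join(tf, how="inner")

    def _metrics(true_col, est_col):
        sub = joined[[true_col, est_col]].dropna()
        if len(sub) < 3:
            return {"n": len(sub)}
        err = sub[est_col] - sub[true_col]
        out = {"n": len(sub), "bias": float(err.mean()),
               "rmse": float(np.sqrt((err ** 2).mean()))}
        if sub[true_col].std() > 0 and sub[est_col].std() > 0:
            out["cor"] = float(np.corrcoef(sub[true_col], sub[est_col])[0, 1])
        return out

    report = {"gamma1": _metrics("gamma1", "gamma1_hat")}
    sub = joined[["arocm_young_hat", "arocm_old_hat", "r_young_mean"]].dropna()
    if len(sub) >= 3 and (sub["arocm_old_hat"] ** 2).sum() > 0:
        slope = float((sub["arocm_young_hat"] * sub["arocm_old_hat"]).sum()
                      / (sub["arocm_old_hat"] ** 2).sum())
        expected = float(truth.config.knot / sub["r_young_mean"].mean())
        report["young_old"] = {"n": len(sub),
                               "through_origin_slope": slope,
                               "expected_slope": expected}
    return report


def write_synthetic(bundle: StudyBundle, truth: SyntheticTruth, out_dir
                    ) -> dict[str, Path]:
    """Emit the four study CSVs plus truth.csv and the config as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    manifest["betas"] = out / "betas.csv"
    bundle.betas.reset_index().to_csv(manifest["betas"], index=False)
    manifest["samples"] = out / "samples.csv"
    bundle.samples.to_csv(manifest["samples"], index=False)
    manifest["traits"] = out / "traits.csv"
    bundle.traits.reset_index().to_csv(manifest["traits"], index=False)
    manifest["annotation"] = out / "annotation.csv"
    bundle.annotation.reset_index().to_csv(manifest["annotation"], index=False)
    manifest["truth"] = out / "truth.csv"
    truth.frame.to_csv(manifest["truth"], index=False)
    manifest["config"] = out / "config.yaml"
    with open(manifest["config"], "w") as fh:
        yaml.safe_dump({"seed": truth.seed, **truth.config.as_dict()}, fh,
                       sort_keys=False)
    return manifest
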