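"""Shared fixtures and construction helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from arocm.core import AgeInterval, StratumView, scale_values

settings.register_profile("fixed", derandomize=True, max_examples=50)
settings.load_profile("fixed")


def exact_cor_stratum(stratum_id: str, rel_design: np.ndarray, rho: float,
                      L: float, seed: int = 0,
                      species: str | None = None) -> StratumView:
    """A stratum whose Pearson Cor(methyl, age) equals ``rho`` exactly.

    Decomposes methyl = rho * z + sqrt(1 - rho^2) * e with z the
    standardized ages and e a standardized residual orthogonal to z, then
    maps into a plausible beta range (correlation is affine-invariant).
    """
    rel = np.asarray(rel_design, dtype=float)
    ages = rel * L
    z = scale_values(ages)
    rng = np.random.default_rng(seed)
    e0 = rng.normal(size=ages.size)
    e0 = e0 - e0.mean() - (e0 * z).mean() / (z * z).mean() * z
    e = scale_values(e0)
    methyl_std = rho * z + np.sqrt(1.0 - rho * rho) * e
    methyl = 0.5 + 0.05 * methyl_std
    return StratumView(
        stratum_id=stratum_id, ages=ages, rel_ages=rel, methyl=methyl,
        scaled=scale_values(methyl), L=L, interval=AgeInterval(0.0, 1.0),
        species=species or stratum_id, tissue="blood",
    )


def window_design(low: float, high: float, n: int = 30) -> np.ndarray:
    """Evenly spaced relative ages in [low, high]; SD controlled by width."""
    return np.linspace(low, high, n)


@pytest.fixture
def toy_study_paths(tmp_path):
    """A 4-sample, 3-probe study on disk (two strata, one species each)."""
    betas = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "cg01": [0.2, 0.6, 0.3, 0.5],
        "cg02": [0.4, 0.8, 0.5, 0.7],
        "cg03": [0.1, 0.2, 0.15, 0.25],
    })
    samples = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "species": ["wolf", "wolf", "vole", "vole"],
        "tissue": ["blood", "blood", "blood", "blood"],
        "age": [1.0, 8.0, 0.5, 2.5],
    })
    traits = pd.DataFrame({
        "species": ["wolf", "vole"],
        "max_lifespan": [16.0, 4.0],
        "gestation": [0.0, 0.0],
        "adult_weight": [40.0, 0.03],
    })
    annotation = pd.DataFrame({
        "probe_id": ["cg01", "cg02", "cg03"],
        "chromatin_state": ["BivProm2", "BivProm2", "Quies1"],
        "prc2_bound": ["+", "-", "+"],
    })
    paths = {}
    for name, frame in [("betas", betas), ("samples", samples),
                        ("traits", traits), ("annotation", annotation)]:
        path = tmp_path / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths
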