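"""Species aggregation, lifespan correlations, trend test, models M1-M4."""

import numpy as np
import pandas as pd
import pytest

from arocm.comparative import (LIFESPAN_GROUP_LABELS, aggregate_by_species,
                               assign_lifespan_group, fit_lifespan_models,
                               lifespan_correlations, mann_kendall_trend,
                               stratified_by_sdr)
from arocm.core import estimate_arocm
from arocm.errors import ArocmError

from conftest import exact_cor_stratum, window_design


def stats_for(species, tissue, arocm_values, L=10.0):
    """Stats records with controlled slope values for aggregation tests."""
    out = []
    for i, a in enumerate(arocm_values):
        v = exact_cor_stratum(f"{species}__{tissue}{i}",
                              window_design(0.05, 0.8, 20), 0.8, L,
                              seed=i, species=species)
        s = estimate_arocm(v).replace(arocm=a, tissue=f"{tissue}{i}")
        out.append(s)
    return out


class TestAggregateBySpecies:
    @pytest.mark.parametrize("values,expected", [
        ([0.1, 0.2, 0.4], 0.2),
        ([0.1, 0.3], 0.2),
        ([0.7], 0.7),
    ])
    def test_median_across_tissues(self, values, expected):
        table = aggregate_by_species(stats_for("fox", "t", values))
        assert table.loc[table["species"] == "fox", "arocm"].iloc[0] == \
            pytest.approx(expected)

    def test_one_row_per_species_with_weight_join(self):
        stats = stats_for("fox", "t", [0.1, 0.2]) + \
            stats_for("vole", "t", [0.5], L=4.0)
        traits = pd.DataFrame({"adult_weight": [5.0, 0.03]},
                              index=["fox", "vole"])
        table = aggregate_by_species(stats, traits=traits)
        assert len(table) == 2
        assert set(table["adult_weight"]) == {5.0, 0.03}


class TestLifespanCorrelations:
    def test_exact_inverse_metric(self):
        L = np.array([5.0, 10.0, 20.0, 40.0])
        table = pd.DataFrame({"arocm": 2.0 / L, "L": L})
        res = lifespan_correlations(table, "arocm", "pearson-vs-inverse-L")
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.n == 4

    def test_monotone_decreasing_spearman(self):
        L = np.array([5.0, 10.0, 20.0, 40.0])
        table = pd.DataFrame({"arocm": np.exp(-L), "L": L})
        res = lifespan_correlations(table, "arocm", "spearman-vs-inverse-L")
        assert res.r == pytest.approx(1.0)  # metric increases with 1/L

    def test_power_law_on_log_scale(self):
        L = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
        table = pd.DataFrame({"arocm": 3.0 / L, "L": L})
        res = lifespan_correlations(table, "arocm", "pearson-log-log")
        assert res.r == pytest.approx(-1.0, abs=1e-12)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_values_dropped_on_log_scale(self):
        table = pd.DataFrame({"arocm": [0.5, -0.1, 0.25, 0.125, 0.4],
                              "L": [2.0, 4.0, 8.0, 16.0, 5.0]})
        res = lifespan_correlations(table, "arocm", "pearson-log-log")
        assert res.n == 4

    def test_insufficient_pairs(self):
        table = pd.DataFrame({"arocm": [0.5, 0.2], "L": [2.0, 4.0]})
        with pytest.raises(ArocmError):
            lifespan_correlations(table, "arocm", "pearson-raw")


class TestLifespanGroups:
    @pytest.mark.parametrize("L,label", [
        (9.9, "<10"), (10.0, "10-19"), (15.0, "10-19"), (19.99, "10-19"),
        (20.0, "20-24"), (24.9, "20-24"), (25.0, "25-39"), (39.9, "25-39"),
        (40.0, ">=40"), (45.0, ">=40"), (211.0, ">=40"),
    ])
    def test_boundaries_to_upper_group(self, L, label):
        assert assign_lifespan_group(L) == label

    def test_labels_are_ordered(self):
        assert assign_lifespan_group(5) == LIFESPAN_GROUP_LABELS[0]
        assert assign_lifespan_group(100) == LIFESPAN_GROUP_LABELS[-1]


def brute_force_mk(values, times=None):
    values = list(values)
    n = len(values)
    times = list(times) if times is not None else list(range(n))
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            dv = int(values[j] > values[i]) - int(values[j] < values[i])
            dt = int(times[j] > times[i]) - int(times[j] < times[i])
            s += dv * dt
    return s


class TestMannKendall:
    def test_monotone_sequence(self):
        res = mann_kendall_trend([1, 2, 3, 4, 5])
        assert res.s == 10
        assert res.z == pytest.approx(2.2045, abs=1e-4)
        assert res.p == pytest.approx(0.0275, abs=1e-4)

    def test_antisymmetry(self):
        fwd = mann_kendall_trend([1, 2, 3, 4, 5])
        rev = mann_kendall_trend([5, 4, 3, 2, 1])
        assert rev.s == -fwd.s
        assert abs(rev.z) == pytest.approx(abs(fwd.z))

    def test_all_tied_values(self):
        res = mann_kendall_trend([2.0, 2.0, 2.0, 2.0])
        assert res.s == 0 and res.p == 1.0

    def test_matches_brute_force_up_to_n50(self):
        rng = np.random.default_rng(11)
        for n in (3, 7, 20, 35, 50):
            values = rng.integers(0, 8, size=n).astype(float)  # many ties
            assert mann_kendall_trend(values).s == brute_force_mk(values)

    def test_grouped_mode_ignores_within_group_order(self):
        values = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        groups = ["a", "a", "b", "b", "c", "c"]
        res = mann_kendall_trend(values, groups=groups)
        ranks = [0, 0, 1, 1, 2, 2]
        assert res.s == brute_force_mk(values, ranks)
        swapped = mann_kendall_trend([3.0, 1.0, 2.0, 5.0, 4.0, 6.0],
                                     groups=groups)
        assert swapped.s == res.s


def model_table(n=60, seed=2, weight_noise=False):
    """Strata generated from the log-linear lifespan model for recovery."""
    rng = np.random.default_rng(seed)
    L = np.exp(rng.uniform(np.log(3), np.log(60), n))
    weight = np.exp(rng.normal(0, 1.5, n)) if weight_noise else \
        np.exp(-2.0 + 2.0 * np.log(L) + rng.normal(0, 0.3, n))
    log_arocm = 1.92 - 1.3 * np.log(L) + 0.015 * np.log(weight)
    tissue = rng.choice(["Blood", "Skin", "Brain", "Liver"], n)
    return pd.DataFrame({"arocm": np.exp(log_arocm), "L": L,
                         "adult_weight": weight, "tissue": tissue})


class TestLifespanModels:
    def test_m2_recovers_generating_coefficients(self):
        out = fit_lifespan_models(model_table(), "M2").set_index("Covariate")
        assert out.loc["(Intercept)", "Estimate"] == pytest.approx(1.92,
                                                                   abs=1e-8)
        assert out.loc["log(Lifespan)", "Estimate"] == pytest.approx(-1.3,
                                                                     abs=1e-8)
        assert out.loc["log(AverageWeight)", "Estimate"] == pytest.approx(
            0.015, abs=1e-8)

    def test_matches_normal_equations(self):
        table = model_table(seed=5, weight_noise=True)
        out = fit_lifespan_models(table, "M1").set_index("Covariate")
        X = np.column_stack([np.ones(len(table)),
                             np.log(table["arocm"]),
                             np.log(table["adult_weight"])])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(table["L"]))
        np.testing.assert_allclose(
            out["Estimate"].to_numpy(),
            beta, atol=1e-8)

    def test_pure_noise_weight_is_insignificant(self):
        rng = np.random.default_rng(9)
        table = model_table(n=120, seed=3)
        table["adult_weight"] = np.exp(rng.normal(0, 1.0, len(table)))
        table["arocm"] = np.exp(
            1.92 - 1.3 * np.log(table["L"]) + rng.normal(0, 0.2, len(table)))
        out = fit_lifespan_models(table, "M2").set_index("Covariate")
        assert abs(out.loc["log(AverageWeight)", "t-value"]) < 2.5
        assert abs(out.loc["log(AverageWeight)", "Estimate"]) < 0.1

    def test_tissue_indicator_models_run(self):
        for model_id, extra in [("M3", {"Brain"}),
                                ("M4", {"Brain", "Blood", "Skin", "Liver",
                                        "Muscle", "Tail"})]:
            out = fit_lifespan_models(model_table(seed=7), model_id)
            assert extra <= set(out["Covariate"])

    def test_underdetermined_errors(self):
        with pytest.raises(ArocmError):
            fit_lifespan_models(model_table().head(2), "M1")


class TestStratifiedBySdr:
    def test_constant_cor_over_sdr_gives_perfect_fit_per_bin(self):
        # Cor / SD(R) constant within a bin -> AROCM exactly proportional
        # to 1/L, the inverse-lifespan law with no adjustment needed
        stats = []
        for i, L in enumerate([4.0, 9.0, 16.0, 30.0]):
            rel = window_design(0.05, 0.95, 40)      # sd_R ~ 0.26
            stats.append(estimate_arocm(
                exact_cor_stratum(f"a{i}", rel, 0.8, L, seed=i)))
        for i, L in enumerate([5.0, 11.0, 21.0, 45.0]):
            rel = window_design(0.05, 0.65, 40)      # sd_R ~ 0.17
            stats.append(estimate_arocm(
                exact_cor_stratum(f"b{i}", rel, 0.8, L, seed=10 + i)))
        results = stratified_by_sdr(stats, bins=((0.22, 0.30), (0.12, 0.22)))
        assert len(results) == 2
        for res in results.values():
            assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_sparse_bin_skipped(self):
        stats = [estimate_arocm(exact_cor_stratum(
            f"s{i}", window_design(0.05, 0.95, 30), 0.8, 5.0 + i, seed=i))
            for i in range(3)]
        results = stratified_by_sdr(stats, bins=((0.22, 0.3), (0.5, 0.6)))
        assert (0.5, 0.6) not in results

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            stratified_by_sdr([], bins=((0.4, 0.2),))


def test_proposition_one_demonstration():
    # constant Cor / SD(R) across strata forces AROCM = constant / L exactly
    stats = []
    rel = window_design(0.05, 0.85, 30)
    for i, L in enumerate([2.0, 5.0, 12.0, 30.0, 60.0]):
        stats.append(estimate_arocm(exact_cor_stratum(f"p{i}", rel, 0.7, L,
                                                      seed=i)))
    from arocm.datasets import stats_to_frame
    res = lifespan_correlations(stats_to_frame(stats), "arocm",
                                "pearson-vs-inverse-L")
    assert res.r == pytest.approx(1.0, abs=1e-10)
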