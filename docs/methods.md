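# Methods

## Estimation model

Within one stratum (a dog breed, or a species × tissue combination) with
`n` samples and a CpG set of size `m`, the per-sample summary is the mean
beta value over the set. Missing betas are ignored in the mean; a sample
missing more than 50% of the set is dropped and logged, so the summary
stays well defined without imputation. The summary is standardized to
mean 0 and population SD 1 within the stratum (`ScaledM`), and the AROCM
is the OLS slope of `ScaledM` on age in years.

All within-stratum moments use the population convention (divisor `n`),
so the identities

    AROCM = Cor(Methyl, Age) / (SD(R) · L),    SD(Age) = SD(R) · L

hold to floating-point rounding, not merely asymptotically. The Pearson
correlation itself is divisor-invariant; the convention matters only for
the standardized values and SD terms. Degenerate strata (n < 2, constant
ages, constant methylation) raise typed errors with machine-readable
reason codes rather than returning NaN, so exclusion filters can log why
a stratum dropped out. Constantness is detected by exact elementwise
equality, not by a variance threshold: a vector like `[0.2, 0.2, 0.2]`
has a nonzero floating-point variance but carries no information.

Relative age is `R = (Age + GT) / (L + GT)` with gestation time `GT`
defaulting to 0; the shift exists to map prenatal samples (negative
chronological age) into `[0, 1)`. A prenatal sample without a gestation
time is an error. When `GT > 0`, the decomposition identities hold with
`L + GT` in place of `L`.

Age intervals are half-open in relative age, `[lower, upper)`, with the
full range `[0, 1)`; a boundary sample at the young/old cutoff belongs to
the old side (`R ≥ 0.1`).

## Adjustment and power selection

The adjustment multiplies the rate by `SD(R)^(1-p)` and divides the
correlation by `SD(R)^p`, preserving `Adj.AROCM = Adj.Cor / L` for every
`p`. The power is selected on a grid (default 0 to 1 in steps of 0.005)
by minimizing the dispersion of the adjusted correlations across strata;
ties resolve to the smallest power, and strata with non-positive age
correlation are excluded from selection and from all log-scale
computations (and counted).

The default objective is the QCOD of the **raw** adjusted correlations.
The QCOD of their logs and the coefficient of variation are available as
alternatives: the log variant is undefined wherever the log-scale
quartiles straddle zero (those grid points are reported as `+inf`), which
is why it is not the default; the CV variant agrees with QCOD on
well-behaved profiles and serves as a cross-check. Quartiles use linear
interpolation between order statistics (the "type 7" rule); with this
convention QCOD is scale-invariant, so when `SD(R)` is constant across
strata the profile is exactly flat — the adjustment cannot discriminate —
and the selection is flagged as degenerate rather than reporting a
spurious optimum.

Cross-stratum variances in the proposition report (variance ratio,
predicted correlation `−1/√(1+ratio)`, `c(p)`) also use the population
convention. When the adjusted correlation is constant across strata its
log-variance is zero and the condition-C1 correlation is reported as 0 (a
constant is trivially uncorrelated with lifespan). The report carries
both the log-variance ratio and the squared-CV ratio; they agree to first
order by the delta method.

## Life-course model

`g(R)` uses the natural log below the knot and is linear above; knot
default 0.1, configurable for sensitivity sweeps. Both `g` and `g'` are
continuous at the knot. Fits are plain OLS of the stratum's `ScaledM` on
`g(R)`; a warning (not an error) is raised when the relative ages do not
span the knot, since one branch is then unconstrained. The derivative
rate at a reference relative age `R0` is `γ1·g'(R0)/L`; the choice of
`R0` is left to the caller rather than fixed, because any value on the
linear branch gives the same old-age rate while the young-age rate
depends on `R0` explicitly.

When young and old interval slopes are to be compared within one stratum
(the proportionality `AROCM_young = AROCM_old · knot / R_young`), both
slopes must be computed on a **common** scaling; `split_young_old` can
therefore keep the parent stratum's standardization (`rescale=False`).
Re-standardizing each side separately — appropriate when the sides are
analyzed as independent strata — destroys the shared `γ1` and with it the
theoretical constant. For interval-averaged (rather than pointwise)
young slopes, the effective young reference age is close to, but not
exactly, the mean young relative age; with a narrow young window the
discrepancy is a couple of percent.

## Quality filters

Dog mode: `n ≥ 3`, `SD(R) ≥ 0.1`, fit `R² ≥ 0.2`. Mammal mode: `n ≥ 3`,
`SD(R) ≥ 0.06`, AROCM inside the open range `(−1, 10)`. Rules are pure
functions of (view, stats, config); every violated rule is reported, not
just the first, and loosening any threshold never rejects a previously
kept stratum.

An out-of-range slope triggers the derived-interval check: the slope is
re-estimated on nested intervals `[0, 0.2)` and `[0, 0.3)` of relative
age within the same stratum. Only when **all** estimable derived slopes
are themselves in range is the primary value declared an outlier and the
stratum dropped; if a derived slope is also extreme, the extremity may be
a real property of the stratum, which is kept but flagged for review. If
any derived interval has too few samples to estimate, the check abstains
and the stratum is rejected conservatively with a distinct reason code
(`range_unverifiable`) — an unverifiable extreme estimate should not
enter comparative analyses.

For dog breeds lacking a recorded maximum lifespan, the maximum is
derived as 1.33 × median lifespan.

## Comparative analyses

Species-level values are medians across a species' tissue strata (mean of
the two middle values for even counts), computed over kept strata only.
Lifespan-group boundaries (10, 20, 25, 40 years) assign the boundary
value to the upper group. The Mann-Kendall trend test uses exhaustive
sign-pair enumeration; in grouped mode the group rank is the time axis,
so within-group pairs contribute nothing to S, and the normal
approximation applies the tie correction for both tied values and tied
group ranks plus a continuity correction. All p-values are two-sided.
The regression models M1–M4 are ordinary least squares on natural-log
scales via statsmodels, with 0/1 tissue indicators; rows with
non-positive rate, lifespan or weight are dropped since the logs are
undefined there.

## Synthetic studies

The generator emulates the structure that drives the estimators:

* lifespans log-uniform over [2, 60] years;
* per-stratum relative-age windows `[a, b]` with uniform start and width —
  uniform sampling within the window gives `SD(R) ≈ (b−a)/√12`, so window
  heterogeneity is the mechanism for `SD(R)` heterogeneity (emulating
  uneven sample ascertainment);
* trajectories `beta = baseline_j + k_j·(γ0 + γ1·g(R)) + noise`, clipped
  to `[0, 1]` with the clipping rate reported (a warning above 10%, since
  clipping bends trajectories — the default baselines/loadings keep it
  around 0.2%);
* two probe groups: low-baseline positive-loading ("BivProm2-like",
  age-gaining, as for PRC2-bound bivalent promoter CpGs) and
  high-baseline negative-loading ("Quies1-like", age-losing), so
  negative-slope strata exist and the non-positive-correlation exclusion
  paths are exercised;
* windows and `γ1` drawn independently of lifespan, so condition C1 holds
  by design up to sampling noise;
* an optional `young_fraction` oversamples the sub-knot range for
  life-course analyses.

Defaults are 50 strata of 200 samples with probe-level noise SD 0.02 —
sizes at which per-stratum estimates are precise but the suite still runs
in seconds. `γ1` is identified on the beta scale through the stratum's
known mean probe loading `k̄` (recorded in the truth table): the recovery
estimator divides the slope of mean methylation on `g(R)` by `k̄`. This
is deliberate — within-stratum standardization makes `γ1`
non-identifiable from `ScaledM` alone, so recovery is defined relative to
the known loading.

What the generator does **not** emulate: probe-level array chemistry,
cross-species probe mappability, tissue-specific trajectory differences
beyond stratum labels, or phylogenetic correlation between strata.
Passing recovery tests therefore demonstrate the estimators' correctness
under the stated sampling model, not robustness to those real-data
features.

## Numerical choices

* Probe and sample orderings are lexicographic everywhere, making
  floating-point reductions bit-reproducible on one platform; reruns with
  the same inputs, config and seed produce byte-identical tables.
* Identity checks in the test suite use absolute tolerances 1e-9/1e-10
  (slope decomposition, adjustment identity) — the identities are exact
  in exact arithmetic, so the tolerance only absorbs rounding.
* PRC2 flags accept `+/−`, `yes/no`, `1/0` and normalize to `+/−`.
* The CSV writers rely on shortest round-trip float repr, so
  `read(write(x)) == x` exactly.

## Limitations

The adjustment power is selected on the analysis data with no
cross-validation, so an overly tight inverse law can be partially
self-fulfilling; presenting adjusted and unadjusted results side by side
(as the pipeline report does) is the intended guard. Formal inference on
the selected power, mixed-effects or weighted per-CpG fits, spline-based
life-course shapes, and phylogenetically independent contrasts are out of
scope.
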