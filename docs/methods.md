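# Methods

## Model

The package estimates spatial panel regressions for a balanced panel of `n`
units observed over `T` periods. The maintained model is the spatial Durbin
model (SDM), written period by period as

    y_t = ρ W y_t + X_t β + (W X_t) θ + μ + ε_t ,     ε_it ~ N(0, σ²) i.i.d.

`W` is a row-standardized spatial weight matrix with zero diagonal; `Wy_t`
and `WX_t` are neighborhood averages of the outcome and covariates. Setting
`θ = 0` yields the spatial lag model (SLM); the spatial error model (SEM)
replaces the outcome lag with an autoregressive disturbance `u = λWu + ε`.
The admissible spatial parameter interval is `(1/λ_min, 1/λ_max)` over the
real spectrum of `W`; for row-standardized matrices `λ_max = 1`.

Assumptions worth stating plainly: the panel is balanced with no missing
cells; `W` is exogenous, fixed over time, and shared by all periods;
disturbances are homoskedastic and serially independent; and the same `ρ`
applies to every unit (regional heterogeneity is handled by refitting on
subsamples, not by regime switching).

## Weight matrices

* **Contiguity** (binary): `w_ij = 1` iff units i and j are adjacent, from a
  user-supplied pair list. Symmetric by construction.
* **Inverse distance**: `w_ij = 1/d_ij` with `d_ij` the planar Euclidean
  distance between unit coordinates. Coordinates are an input; no geodesy.
* **Grouped (inter-regional)**: restrict to two regions' units, zero every
  within-region entry, re-row-standardize. Each unit's spatial lag then
  averages exclusively over the *other* region, isolating cross-region
  spillover. This construction is our explicit convention; the literature the
  grouped analysis follows describes the intent but not the algebra.

Both base kinds are row-standardized before estimation. Isolated units
(all-zero rows) are retained with zero spatial lag and a warning rather than
dropped — dropping would silently change `n` in every downstream statistic.
Restricting a matrix to a subsample (regional runs) re-standardizes from the
kept raw weights, which preserves within-row proportions.

## Moran screening

Global Moran's I per year and variable, with `E(I) = −1/(n−1)` and the
closed-form variance under either the normality null or the
kurtosis-adjusted randomization null (the default — it conditions on the
observed values and is agnostic about their distribution). Significance uses
the two-sided normal approximation with 10/5/1% stars. Scatter quadrants
classify each unit by the signs of its standardized value and spatial lag;
exact zeros are assigned to the positive side (HH/HL) so no unit is dropped —
a measure-zero convention for continuous data.

## Estimation

All models are fitted by concentrated maximum likelihood. The log-Jacobian
`ln|I − ρW|` is evaluated through the eigenvalues of `W` as
`Σ_i ln(1 − ρλ_i)`, precomputed once, so a likelihood evaluation is O(n) and
the profile over `ρ` is cheap. The scalar search runs a deterministic
41-point grid over the 0.999-shrunken admissible interval followed by
bounded Brent refinement (tolerance 1e-8); termination at the interval
boundary raises a non-convergence error rather than returning a boundary
value. No random starts anywhere, so identical inputs give identical fits.

**Fixed effects.** Unit effects are removed by within-demeaning. The
demeaned data are an orthonormal transform of `T−1` periods per unit, so the
likelihood is evaluated in its exact conditional form: `N = n(T−1)`
observations and `T−1` log-determinant terms, with `σ̂² = RSS/N`. This is
*not* a bias correction of the estimates — it is simply the correct
likelihood of the transformed data. It matters in practice: with the naive
`nT` form, the LR and Wald reduction tests reject a true `θ = 0` at roughly
twice the nominal 5% rate at `n = 30, T = 12`; with the conditional form
their empirical sizes sit inside the exact binomial band (see the
calibration tests). The remaining O(1/n) incidental-parameter distortion is
left uncorrected and is visible as a small negative bias in `ρ̂`
(≈ −0.03 at `n = 30, T = 12, ρ = −0.5`), within the package's documented
recovery tolerance. Time fixed effects are not included by default.

**Random effects.** Quasi-demeaning with weight `1 − θ_qd`,
`θ_qd = √(σ² / (σ² + Tσ_μ²))`, gives spherical errors; the likelihood gains
the Jacobian term `n ln θ_qd`, and `(ρ, θ_qd)` are maximized jointly by
L-BFGS-B from three fixed starts (best kept). `θ_qd → 1` signals a zero
variance component (RE collapses toward pooled OLS) and warns. An intercept
is included (the within-transform of the FE case absorbs it).

**SEM.** Spatial Cochrane-Orcutt filtering `(I − λW)` of the within-demeaned
outcome and covariates, with the same concentrated-scalar machinery over λ.

**Covariances.** From a central-difference numerical Hessian of the full
log-likelihood at the optimum (relative step 1e-5), inverted and reduced to
the `(ρ, β, θ)` block. The reported `R²` is the squared correlation between
observed and fitted outcomes — ML spatial models have no canonical `R²`, and
this is the interpretation-neutral choice.

## Specification tests

* **LR**: `2(ll_full − ll_restricted)` against χ² with df = number of
  restrictions; defined for the nested pairs SDM→SLM and SDM→SEM.
* **Wald**: `θ = 0` directly from the `θ` block of the covariance;
  `θ + ρβ = 0` by the delta method with Jacobian `G = [β, ρI, I]`.
* **Hausman**: `(b_FE − b_RE)' (V_FE − V_RE)⁻ (b_FE − b_RE)` over the common
  slopes `(β, θ)`, using the Moore-Penrose inverse restricted to the
  positive eigenspace of the variance difference (so the statistic is
  nonnegative even when the difference is indefinite), df = retained rank.
  **Known fragility:** at `n = 30` the difference of two Hessian-based
  covariances carries relative noise of order one across 14 dimensions, and
  the statistic's finite-sample size substantially exceeds its nominal
  level even under an exogenous-effects process — our Monte-Carlo diagnosis
  shows the FE−RE contrast itself is well calibrated when its covariance is
  estimated across replicates, so the instability lies in the per-sample
  variance difference, a documented weakness of the classic Hausman form.
  Treat small-sample Hausman p-values as indicative, not exact.

## Impact decomposition

`S_r(W) = (I − ρ̂W)^{-1}(Iβ̂_r + Wθ̂_r)` is computed by linear solve with a
condition-number guard (threshold 1e12), never by explicit inversion of an
ill-conditioned system. Direct = mean diagonal, total = mean of all entries,
indirect = total − direct; the identity total = direct + indirect holds to
machine precision by construction. Standard errors follow the parameter-
simulation approach: `D = 1,000` seeded multivariate-normal draws of
`(ρ, β, θ)` at the estimate and covariance, draws with `ρ` outside the
admissible interval redrawn (a warning fires if more than 10% fall outside),
effects recomputed per draw via the `ρ`-only multiplier summaries, and
p-values from the normal approximation to the draw t-ratio.

## Synthetic data generator

The generator reproduces the statistical structure of the motivating
application — a Chinese provincial panel of farmers' medical-expenditure
share (FME) regressed on log toilet-retrofitting investment (lnRTI) and six
controls — without any restricted data:

* **Map**: `n` uniform points on the unit square; contiguity from their
  Delaunay triangulation (planar, connected); four spatially coherent
  regions from a median split on x then on y within each half.
* **Covariates**: independent processes per variable,
  `mean + SD·(√w·a_i + √(1−w)·v_it)` with `a_i` standard-normal unit
  heterogeneity (`w = 0.3`) and `v_it` a stationary AR(1) (φ = 0.5). Means
  and SDs default to the application's descriptive table (e.g. lnRTI
  0.536/1.305, FME centered at 0.067). The persistence and heterogeneity
  shares are our choices — provincial socioeconomic series are strongly
  persistent — fixed once; because of them the standard error of a sample
  mean is about 2.4× the i.i.d. value, and the moment tests use the exact
  closed form.
* **Outcome**: the SDM reduced form
  `y_t = (I − ρW)^{-1}(X_tβ + WX_tθ + α + μ + ε_t)` with
  `μ_i ~ N(0, fe_sd²)` fixed over time, `ε_it ~ N(0, σ²)`, and `α` solved so
  the unconditional outcome mean hits its target. Default truth: the
  application's fixed-effects SDM estimates under contiguity
  (β = −0.055, −0.021, 0.142, −0.230, 0.107, 0.034, 0.056 and the matching
  θ vector), `σ² = 0.004`, `ρ = −0.5`, `fe_sd = 0.02`. A `fe_x_corr` switch
  tilts `μ` toward the unit means of the first covariate to violate the
  random-effects assumption on demand; `region_betas` overrides the own-
  covariate response per region for heterogeneity experiments.

What the generator does **not** emulate: spatially correlated covariates,
real Chinese geography or any actual province adjacency, deflator dynamics,
or construction of FME from separate expenditure/income series (it is drawn
directly on the ratio scale). Passing tests therefore demonstrate that the
estimators recover the parameters of this DGP — they do not validate the
substantive conclusions of any particular empirical study.

## Calibration results the tests enforce

At the default study shape (`n = 30, T = 12`, one fixed map): mean bias of
`ρ̂` below 0.05 over 200 panels; 95% Wald coverage of the investment
coefficient inside the exact binomial band; LR(SDM vs SLM) and Wald(θ = 0)
empirical sizes inside the binomial band over 400 panels; a −0.05 vs −0.03
regional effect contrast recovered in ≥ 90% of 200 panels; Moran's I equal
to a brute-force double sum to 1e-12; log-determinants equal to dense
`slogdet` to 1e-10 up to `n = 60`; and a byte-identical report bundle on
pipeline re-runs. The realized size of the reduction tests moves by a few
percentage points with the drawn map (the spatial design matters at this
`n`), so the acceptance script's reported sizes under a different seed can
sit slightly above the band the fixed-map tests enforce.

## Numerical conventions

Eigenvalues of `W` must be real to tolerance 1e-8 (guaranteed for matrices
similar to symmetric ones, as all built kinds are); complex spectra raise.
Rank deficiency of the design after the panel transform raises a
collinearity error; constant variables make Moran's I undefined and are
flagged per year rather than failing whole tables. Log and ratio variable
construction hard-errors on nonpositive inputs, naming the offending cells —
no silent offsets, since an offset would corrupt elasticities. Deflation
normalizes the index to the base year per unit, so base-year values are
unchanged and the expenditure/income ratio is deflation-invariant.

## Limitations

No Lee–Yu bias correction for the fixed-effects spatial likelihood; no
dynamic or unbalanced panels; no SARAR/GNS specifications; SEM is
implemented for fixed effects only; no geodesic distances; no polygon-based
contiguity derivation. The Hausman fragility and the map-dependence of
finite-sample test sizes are described above.
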