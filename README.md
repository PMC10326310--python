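# sdmpanel

Spatial Durbin panel econometrics for regional health-economics analysis:
spatial weight matrices, Moran's I screening, maximum-likelihood estimation of
spatial panel models, spillover (direct/indirect effect) decomposition, and
intra-/inter-regional comparison — with a synthetic data generator so the
whole pipeline is testable without restricted yearbook data.

## The problem

Public-investment programs such as rural toilet retrofitting plausibly reduce
farmers' medical-and-health expenditure, but provinces are not independent
observations: investment effects spill across borders through imitation,
factor flows, and market competition. Ignoring that spatial dependence biases
ordinary panel estimates. The standard remedy is the **spatial Durbin model
(SDM)** for a balanced panel of `n` units over `T` periods:

    y_t = ρ W y_t + X_t β + (W X_t) θ + μ + ε_t

where `W` is an `n×n` row-standardized spatial weight matrix (border
contiguity or inverse distance between capitals), `ρ` the spatial
autoregressive parameter, `θ` the coefficients on neighbors' covariates, and
`μ` unit effects (fixed or random). The SDM nests the spatial lag model
(SLM, `θ = 0`) and — under the common-factor restriction `θ + ρβ = 0` — the
spatial error model (SEM), adjudicated by LR and Wald tests; fixed vs random
effects by the Hausman test.

Because a unit's outcome feeds back through `ρW`, coefficients are not
marginal effects. The matrix of partial derivatives for covariate `r` is

    S_r(W) = (I − ρW)^{-1} (I β_r + W θ_r)

and the reported summaries are the **direct** effect `n⁻¹ tr(S_r)` (average
own-unit response), the **total** effect `n⁻¹ 1'S_r 1`, and their difference,
the **indirect** (spillover) effect, with simulation-based standard errors.

Before any of this, cross-sectional clustering is screened per year with
global **Moran's I** and its normal test `Z = (I − E(I))/√VAR(I)`,
`E(I) = −1/(n−1)`, plus Moran-scatter quadrant labels (HH/LL clustering,
HL/LH outliers).

## Worked example

```python
import sdmpanel as sp

bundle = sp.generate_panel(seed=7)          # 30 units x 12 years, known DGP
panel, W = bundle["panel"], bundle["W_contiguity"]
cfg = bundle["config"]                      # true rho = -0.5, beta, theta

print(sp.yearly_moran_table(panel, "FME", W).head(3).round(3))

spec = sp.SDMSpec("FME", cfg.covariates, W)
fit = sp.fit_sdm_fe(panel, spec)
print(f"rho = {fit.rho:.3f}  sigma2 = {fit.sigma2:.4f}  loglik = {fit.loglik:.1f}")

dec = sp.impact_inference(fit, D=1000, seed=7)
print(dec.to_report().loc[["lnRTI"]])
```

prints

```
          I      Z      p stars
year
2006 -0.242 -1.988  0.047    **
2007  0.059  0.887  0.375
2008 -0.191 -1.499  0.134

rho = -0.352  sigma2 = 0.0039  loglik = 443.4
                     total               direct            indirect
lnRTI  -0.0174*** (0.0063)  -0.0624*** (0.0035)  0.0450*** (0.0061)
```

The outcome `FME` is the medical-expenditure-to-income ratio; `lnRTI` is log
investment. The generator's default truth has `ρ = −0.5` (negative spatial
dependence), so yearly Moran's I values hover at or below their null
expectation −1/29 — the 2006 value −0.242 is significantly *negative*. The
fitted `ρ̂ = −0.352` is within sampling error of the truth. The impact row
reads: a unit increase in log investment changes own-unit expenditure share
by −0.062 (direct), neighbors' by +0.045 (indirect), −0.017 in total;
parenthesized values are simulation standard errors from 1,000 parameter
draws, stars mark 10/5/1% significance.

## Command line

```sh
sdmpanel simulate --n 30 --periods 12 --seed 5 --out syn/   # panel + map CSVs
sdmpanel moran    --panel syn/panel.csv --variable FME --adjacency syn/adjacency.csv
sdmpanel fit      --panel syn/panel.csv --adjacency syn/adjacency.csv
sdmpanel impacts  --panel syn/panel.csv --adjacency syn/adjacency.csv --draws 1000
sdmpanel regional --panel syn/panel.csv --coords syn/coords.csv \
                  --weight-kind inverse_distance --regions syn/regions.csv
sdmpanel report   --config run.yaml       # full pipeline, one report CSV per stage
```

All inputs and outputs are plain CSV; `run.yaml` holds a `RunConfig`
(paths, covariates, weight kinds, impact draws, seed, output directory).

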