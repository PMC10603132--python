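# firelink

Causal attribution of weekly burned-area variability to top-down
(weather-driven) and bottom-up (fuel/vegetation-driven) precursors, using
two-stage lagged causal discovery on detrended weekly anomalies per
ecoregion.

## The scientific problem

Burned area (BA) in a region co-varies with many environmental drivers, and
lagged correlations alone cannot separate a genuine precursor from a variable
that merely shares a season, a trend, or a common driver with fire. This
package implements the chain

1. **Preprocessing** — quality masking, weekly aggregation, `log1p` of BA,
   OLS detrending and week-of-year anomaly computation, so that the series
   entering the causal analysis are stationary weekly anomalies;
2. **Ecoregion stratification** — pixels are grouped into ecoregions defined
   by the cross of climate zones and vegetation types (29 × 8 = 232 at full
   scale), BA is area-summed and precursors cosine-latitude-weight averaged
   per ecoregion and week;
3. **Causal discovery** — a from-scratch two-stage PCMCI-style procedure:
   a PC-like condition-selection stage prunes the candidate lagged parents of
   every variable, then a momentary-conditional-independence (MCI) stage
   tests each candidate link `X(t−τ) → Y(t)` with a linear partial-correlation
   test conditioned on the discovered parents of both variables. For a link
   the model is

   `ρ(X_{t−τ}, Y_t | pa(Y_t) \ {X_{t−τ}}, pa(X_{t−τ}))`

   with a two-sided t test on `ρ`, retaining links with `p ≤ α`
   (defaults `α = 0.05`, `τ_max = 156` weeks ≈ 3 years);
4. **Dominance attribution** — precursors of BA are grouped into *top-down*
   (Tmax, VPD, ET0, Wind, AAI) and *bottom-up* (FPAR, GPP, NDVI, EVI, SWDI);
   each ecoregion is assigned the group of its strongest precursor by |ρ|, a
   predictability score `Σ ρ²`, sign fractions, and |ρ|-weighted mean lags.

Everything is exercised against a synthetic generator that plants known
lagged causal links inside stable linear systems with seasonality, trends and
burned-area-like zero-inflated skewed marginals, so every stage has a
ground-truth test surface.

## Worked example

Plant two links into BA — ET0 at lag 1 (coefficient 0.7) and soil-water
deficit SWDI at lag 8 (coefficient −0.45) — inside an 11-variable system,
then recover them:

```python
import firelink as fl

spec = fl.ScenarioSpec(
    variables=dict(fl.STANDARD_VARIABLES),
    links=[
        fl.PlantedLink("ET0", "BA", lag=1, coefficient=0.7),
        fl.PlantedLink("SWDI", "BA", lag=8, coefficient=-0.45),
    ],
    n_weeks=936,          # 18 years of weekly data
    seed=42,
)
panel, truth = fl.generate_var_panel(spec)

model = fl.LaggedCausalModel(panel, fl.PCMCIConfig(alpha=0.01, tau_max=20))
results = model.fit()
print(results.links_to("BA").to_string(index=False))

rec = results.attribution()
print("dominant group     :", rec.dominant_group)
print("dominant precursor :", rec.dominant_precursor, "at lag", rec.dominant_lag)
print("predictability     :", round(rec.score, 3))
```

Output:

```text
source target  lag       rho       pvalue  n_eff
   ET0     BA    1  0.575681 1.051086e-81    918
  SWDI     BA    8 -0.429895 1.251416e-42    921

dominant group     : top-down
dominant precursor : ET0 at lag 1
predictability     : 0.516
```

Both planted links are recovered with the correct signs and lags and nothing
spurious survives at `α = 0.01`; the ecoregion is classified top-down
dominant because the strongest precursor (ET0, |ρ| = 0.58) is a weather
variable. `results.summary()` prints the full retained graph,
`results.to_json()/to_csv()` export it, and `results.save_audit()` stores the
complete ρ/p-value/sample-size matrices for every tested `(source, target,
lag)` triple.

The full gridded pipeline (scene → mask → stratify → preprocess → discover →
attribute, with per-ecoregion graphs, a dominance table and a run manifest)
runs from a YAML config:

```sh
firelink run-all --config config.yaml --out results/
```

See `firelink --help` for the individual stages (`simulate`, `preprocess`,
`stratify`, `discover`, `attribute`).

## Documentation

`docs/methods.md` describes the statistical procedure, all defaults and their
rationale, what the synthetic generator does and does not emulate, and the
open design decisions.
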