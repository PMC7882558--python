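# cyclesem

Climate-window selection and Bayesian structural equation models for the
population dynamics of a long-distance migratory bird around its annual
cycle.

## The problem

Breeding populations of migrants such as the pied flycatcher (*Ficedula
hypoleuca*) are shaped by conditions they meet at the breeding grounds, on
migration and in the African non-breeding range. Quantifying those effects
from a long nest-box survey raises three coupled statistical problems:

1. **Which climate, when?** For each location along the migratory route,
   find the contiguous run of months whose aggregated temperature or
   precipitation best predicts an annual response — an exhaustive
   sliding-window scan scored by ΔAICc against a climate-free null model.
2. **Population growth.** Annual growth rate
   `R_t = ln N_t − ln N_{t−1}` (with `N_t` the percentage of available nest
   boxes occupied) is modelled by a path model whose endogenous residuals
   follow autoregressive processes, separating density dependence, the
   fledgling production of the previous two years and three climate windows
   from serial correlation:

   ```
   R_t     = a + b1 N_{t−1} + b2 F_{t−1} + b3 F_{t−2} + b4 MedTemp_t
               + b5 EurPrecip_t + b6 AfrPrecip_{t−1} + e_t,   e ~ AR(1..3)
   N_{t−1} = c + d F_{t−2} + f_t,                             f ~ AR(1..3)
   ```

   AR terms whose 95 % credibility interval covers zero are pruned by
   refitting; the indirect effect of `F_{t−2}` via density is the per-draw
   product of the two paths.
3. **Fledgling production.** Nest-level breeding data form a two-level
   structural equation model: within years, hatch date → clutch →
   fledglings with nestling-period weather and a temperature × precipitation
   interaction; between years, the latent annual means form the same
   mediation chain, driven by European and African winter temperature. All
   within predictors are centered at latent year means, and total, direct
   and indirect effects are decomposed draw by draw.

Everything is estimated by conjugate-block Gibbs sampling (posterior
medians, equal-tailed 95 % credibility intervals, split-R̂ convergence
checks). Because the 77-year field dataset is not publicly deposited, the
package ships a forward simulator whose defaults are the fitted posterior
medians; generate → refit round trips are the package's primary evidence of
correctness. See `docs/methods.md` for the full model account.

The estimators follow scikit-learn conventions (`fit`,
`get_params`/`set_params`, fitted attributes with a trailing underscore):
`ClimateWindowScanner`, `BayesianARRegression`, `TwoLevelRegression`,
`RDSEM` (the growth model) and `MultilevelSEM` (the nest model).

## Worked example

```python
from cyclesem.simulate import GeneratorConfig, gen_full_dataset
from cyclesem.rdsem import RDSEM, build_rdsem
from cyclesem.msem import MultilevelSEM, within_total_hatch_effect

data = gen_full_dataset(GeneratorConfig(), seed=11)       # 77 synthetic years

growth = RDSEM(chains=2, draws=800, random_state=1).fit(build_rdsem(data["series"]))
print("retained growth AR lags:", growth.growth_lags_)
print(growth.summary_.set_index("parameter")
      .loc[["growth_on_density_lag1", "growth_on_med_winter_temp"],
           ["median", "ci_lower", "ci_upper"]].round(4))
print(growth.effects_.round(4).to_string(index=False))

nest = MultilevelSEM(chains=2, draws=600, random_state=1).fit(data["nests"], data["between"])
print(nest.summary_.set_index("parameter")
      .loc[["w_fled_on_clutch", "b_fled_on_afr_winter_temp"],
           ["median", "ci_lower", "ci_upper"]].round(3))
print(within_total_hatch_effect(nest)[["median", "ci_lower", "ci_upper"]]
      .astype(float).round(4))
```

prints

```
retained growth AR lags: [2]
                           median  ci_lower  ci_upper
parameter
growth_on_density_lag1    -0.0027   -0.0037   -0.0017
growth_on_med_winter_temp -0.0238   -0.0359   -0.0119
  effect  median  ci_lower  ci_upper  n_draws    psr  nonzero
  direct  0.0141   -0.0049    0.0322     1600 1.0041    False
indirect -0.0170   -0.0273   -0.0094     1600 1.0003     True
   total -0.0034   -0.0215    0.0156     1600 1.0019    False
                           median  ci_lower  ci_upper
parameter
w_fled_on_clutch            0.714     0.660     0.769
b_fled_on_afr_winter_temp   0.618     0.309     0.903
median     -0.0406
ci_lower   -0.0499
ci_upper   -0.0313
```

Reading this: on data simulated at the reference truth values, the refit recovers
density dependence (−0.0027 per index point, truth −0.003), the
Mediterranean winter-temperature effect (−0.024 per °C, truth −0.025) and
keeps exactly the planted second-order AR term on growth residuals. The
indirect effect of fledgling production two years back, acting through next
year's density, is credibly negative while its direct path is not. At the
nest level, one extra egg yields ~0.71 extra fledglings within years, a
1 °C warmer African winter adds ~0.6 fledglings to the annual mean
(truth 0.67 inside the interval), and the within-year total effect of a
one-day hatching delay is −0.041 fledglings (via the clutch route).

The same pipeline runs from the shell:

```bash
cyclesem generate --seed 11 --out data/
cyclesem run --config examples/pipeline.yaml --seed 11 --out out/
```

`examples/pipeline.yaml` shows the window-selection block: the scan stage
only *ranks* windows, and the structural stages refuse to run until windows
are named explicitly (or automatic selection is switched on deliberately).

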