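# dietshift

**Culturally acceptable, nutritionally adequate, low-emission diets by
quadratic programming.**

`dietshift` answers a question at the centre of sustainable-nutrition policy:
for a given population group, what is the *smallest* dietary change that makes
the diet nutritionally adequate and cuts its greenhouse-gas emissions (GHGE)
by a given fraction?  It is aimed at nutrition and food-system researchers
who work with group-level intake surveys, food-composition tables and
per-food life-cycle emission coefficients.

## The model

For a socio-demographic group with observed average diet
$\bar{x} = (\bar{x}_1, \dots, \bar{x}_n)$ (g/cap/day over $n \approx 74$ food
categories), the optimised diet $x^\*$ solves

$$\min_x \; \sum_{i=1}^n \left( \frac{x_i - \bar{x}_i}{\bar{x}_i} \right)^2$$

subject to linear constraints:

* **isoenergetic**: $\sum_i c_i x_i = E_0$, with $c_i$ the energy density
  (kJ/g) and $E_0$ the group's observed energy intake;
* **nutrient adequacy**: $L_j \le \sum_i a_{ji} x_i \le U_j$ per nutrient
  $j$, in absolute units or as a share of energy (E%), the E% form being
  linear because $E_0$ is fixed;
* **food habits**: $P10_i \le x_i \le P90_i$, the 10th/90th centiles of the
  group's consumption distribution — a cultural-acceptability box;
* **emission cap**: $\sum_i e_i x_i \le (1-r)\sum_i e_i \bar{x}_i$ with
  $e_i$ in kg CO2e/kg and $r \in \{0, \tfrac13, \tfrac12\}$;
* **beef-dairy jointness**: $\rho \sum_i b_i x_i \ge \sum_i m_i x_i$ with
  $\rho = 33.9$ g raw milk per g beef carcass, $b_i$ the beef-carcass
  fraction and $m_i$ the raw-milk-equivalent coefficient — dairy demand
  implies a minimum beef supply because most beef is a dairy-chain
  co-product.

The objective is strictly convex (diagonal Hessian with weights
$1/\bar{x}_i^2$), so the minimiser is unique and certified by first-order
(KKT) conditions.  The solver is an exact active-set method with an
independent brute-force oracle for small instances.  Because the underlying
survey data are not public, the package ships a calibrated synthetic
generator that reproduces the statistical structure of the study population
(group centile structure, composition closure, emission-coefficient
rankings, baseline inadequacies).

## Worked example

```python
from dietshift import DietProblem, GeneratorConfig, STANDARD_SCENARIOS, generate

bundle = generate(GeneratorConfig(seed=0))          # synthetic survey
result = DietProblem(bundle, "male/all", STANDARD_SCENARIOS[2]).fit()
print(result.summary())
```

prints (abridged):

```
group:      male/all
scenario:   ghge_minus_50 (r=0.5, variant=lca, beef_dairy=True, fe=observed)
status:     optimal
objective:  25.400898 (sum of squared relative deviations)
energy:     9,349 kJ/cap/day (observed 9,349)
GHGE:       5.11 -> 2.56 kg CO2e/cap/day (-50.0 %)

Dietary adjustments by main category (g/cap/day):
                 baseline  optimised      delta  percent
cereals             303.8      495.4      191.6  +63.1 %
potatoes             96.9      156.6       59.7  +61.6 %
meat                159.7       16.5     -143.3  -89.7 %
milk                422.1      309.4     -112.7  -26.7 %
milk_eq             853.3      337.3     -516.0  -60.5 %
...

Binding constraints:
energy, nut:fibre:min, nut:sodium:max, nut:calcium:min, ghge_cap, beef_dairy
```

Reading the output: halving emissions while staying isoenergetic (9,349 kJ)
replaces most meat with cereals, potatoes and fruit; dairy drops by a quarter
in grams but by 60 % in raw-milk equivalents because cheese (10 g milk per
gram) is substituted by liquid milk.  The binding constraints show *why* the
diet looks as it does — the fibre floor, sodium and calcium bounds, the
emission cap and the beef-dairy co-production floor are all active, while
none of the protein or amino-acid constraints is.  The dual of `ghge_cap`
(20.4 per kg CO2e) is the marginal acceptability cost of a tighter cap.

The same model runs from the shell:

```bash
dietshift synth --out data --seed 0
dietshift run --data data --out results --groups all
dietshift sensitivity --data data --out sens --variant ghge_landuse
dietshift report results
```

Three sensitivity variants probe the model's assumptions: emission
coefficients that include land-use CO2 (`ghge_landuse`), removal of the
beef-dairy constraint (`no_beef_dairy`), and raising the female iron floor
from its observed 10 mg/cap/day to the recommended 15 mg (`fe_recommended`).

## Layout

| module | contents |
| --- | --- |
| `dietshift.foods` | domain types and linear accounting (energy, nutrients, GHGE, aggregation, milk equivalents) |
| `dietshift.io` | CSV schemas, cross-validated loading, deterministic writing |
| `dietshift.constraints` | recommendation sets, scenario specs, constraint builders, problem assembly |
| `dietshift.optimise` | the QP solver, KKT verification, brute-force oracle |
| `dietshift.model` | `DietProblem` / `DietResult` — the fit-and-summarise interface |
| `dietshift.scenarios` | scenario grid runner and report tables |
| `dietshift.sensitivity` | sensitivity variants and run comparison |
| `dietshift.synthetic` | the calibrated synthetic survey generator and toy bundle |

See `docs/methods.md` for the modelling choices, calibration targets and
limitations.
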