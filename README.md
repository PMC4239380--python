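# metasim

Discrete-event simulation of metastatic progression in a tumour-bearing
host, built around the biology of an HT29 colon-cancer xenograft model in
immunodeficient mice. The package answers a quantitative question: how strongly
does perforin-dependent NK-cell killing suppress lung metastasis, and what
dormancy behaviour of disseminated tumour cells is needed to explain the
observed metastasis sizes?

Two mouse strains anchor the model. In *pfp/rag2* mice (perforin knockout, NK
cells cannot kill) lung metastases are frequent and reach 10–100 cells; in
*rag2* mice (cytotoxic NK cells intact) metastases are rare and mostly single
disseminated tumour cells (DTCs).

## Model

* **Primary tumour growth** follows a Gompertz law
  `x(t) = b^(1 − exp(−a (t + t0)))`, with growth-rate constant `a` (day⁻¹),
  saturation size `b` (4.5 g ≙ 4.5·10⁹ cells at 10⁹ cells/g) and start-size
  offset `t0` computed from the surviving inoculum `x0 = 10⁴` cells.
* **Seeding** of metastasis founders is a non-homogeneous Poisson process with
  colonization rate `β(x) = m·x^α`, where `α = 0.663` is the fractal dimension
  of the tumour vasculature and `m` the colonization constant.
* **Blood compartment**: each founder is killed by NK cells with probability
  `p_kill` or extravasates and founds a metastasis growing at 1/3, 1/2 or 1 ×
  the primary growth-rate constant. Metastases never seed further metastases.
* **Dormancy**: a new metastasis may stay at size 1 for `t_d ~ N(µ, σ)` days
  (dormancy), or arrest for `t_ld` days once it reaches a random trigger size
  of 10–100 cells (late dormancy).

All constants are *fitted*, not assumed: `a` by closed-form inversion of the
Gompertz curve through the cohort mean (weight, duration); `m` by linear
inversion of the expected-founder integral `∫₀ᵀ β(x(t)) dt` against the
observed metastasis count; `p_kill` by the closed form `1 − observed/expected`
cross-checked against a simulated 5 %-step grid.

## Worked example

```python
from metasim import (CalibrationInputs, ColonizationModel,
                     fit_growth_rate_constant, fit_colonization_constant,
                     run_replicates)
from metasim.presets import scenario_config

pfp = CalibrationInputs(mean_tumor_weight=1.23, mean_duration=49.9,
                        observed_metastases=788)
rag2 = CalibrationInputs(mean_tumor_weight=1.16, mean_duration=69.4,
                         observed_metastases=209)

print(f"a (pfp/rag2) = {fit_growth_rate_constant(pfp):.4f} /day")
print(f"a (rag2)     = {fit_growth_rate_constant(rag2):.4f} /day")
print(f"m            = {fit_colonization_constant(pfp):.3e} /(cell*day)")

summary = run_replicates(scenario_config("rag2", seed=0))
print(f"rag2 mean final metastases over 100 runs = {summary.mean_n_metastases:.1f}")
```

prints

```
a (pfp/rag2) = 0.0462 /day
a (rag2)     = 0.0326 /day
m            = 5.195e-05 /(cell*day)
rag2 mean final metastases over 100 runs = 209.4
```

i.e. the perforin-deficient cohort's tumour grows ~40 % faster, one
colonization constant explains both strains, and an 80 % NK kill probability
reproduces the rag2 metastasis burden (209 observed vs 209.4 simulated).

A command-line interface exposes the same pipeline:

```bash
metasim fit growth inputs.json          # closed-form growth constant
metasim fit colonization inputs.json    # colonization constant
metasim scenario-grid --strain rag2 --out out/   # dormancy × growth-rate grid
metasim make-cohort --n-mice 20 --out cohort.csv # synthetic mice
metasim recover --cohort cohort.csv              # parameter recovery
```

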