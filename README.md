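# photoensemble

Multi-hypothesis analysis of the two dominant enzyme-kinetic C3 leaf
photosynthesis model families — Farquhar-type (strict minimum of limiting
rates) and Collatz-type (quadratic co-limitation smoothing plus TPU
limitation) — for modellers who want to know *which structural assumptions,
not just which parameters*, drive simulated carbon assimilation.

The package provides:

* a **12-member factorial ensemble** of demand-side models
  (TPU on/off × minimum/smoothing selection × three electron-transport
  hypotheses), coupled to the unified Medlyn stomatal model by a robust
  vectorized bisection solver;
* **process-level sensitivity analysis** whose factors are whole processes
  (hypothesis choice + that process's parameters), capturing between- and
  within-model variance, alongside classical **first-order Sobol parameter
  SA** (Saltelli estimator);
* **closed-form analysis** of the assimilation reduction imposed by
  quadratic smoothing relative to the minimum rule;
* a **synthetic high-resolution A–Ci curve generator** (dense 5 µmol/mol
  scan across the co-limitation transition) and **DREAM MCMC estimation** of
  V_cmax,25, J_max,25 and the smoothing curvature θ_cj, with Gelman–Rubin
  convergence checks.

## The model in brief

Net assimilation at intercellular CO2 partial pressure Ci is

    A = A_g (1 − Γ*/Ci) − R_d

where A_g is selected from the carboxylation-limited rate
A_c,g = V_cmax·Ci/(Ci + K_c(1+O_i/K_o)), the RuBP-regeneration-limited rate
A_j,g = (J/4)·Ci/(Ci + 2Γ*) and (optionally) the TPU-limited rate
A_p,g = 3·TPU·Ci/(Ci − (1+3α_tpu)Γ*), either as the strict minimum or by
two-stage quadratic smoothing — the smaller root of
θz² − (x1+x2)z + x1·x2 = 0 with curvatures θ_cj, then θ_cjp. The minimum is
the θ = 1 special case; smoothing always sits *below* the minimum, so it
acts as an additional, non-mechanistic limitation on A. At exact
co-limitation the reduction has a closed form: 18% for θ = 0.95 alone, 23%
for θ = (0.95, 0.98) with three equal rates. See `docs/methods.md` for the
full model, estimators and numerical choices.

## Worked example

```python
from photoensemble import (Environment, SA_CENTRAL, model_from_id,
                           solve_coupled, colimitation_scalar, process_sa)

env = Environment(ca=400.0, irradiance=1000.0)   # µmol/mol, µmol m⁻² s⁻¹

# Farquhar-style member (minimum rule, saturating electron transport)
fvcb = solve_coupled(env, SA_CENTRAL, model_from_id("M1111"))
# Collatz-style member (smoothing, TPU, linear electron transport)
cbgb = solve_coupled(env, SA_CENTRAL, model_from_id("M1223"))
print(round(fvcb.a_net, 2), round(cbgb.a_net, 2))   # 13.63 12.2
print(round(cbgb.ci, 2), cbgb.limiting_state)        # 33.17 Ac

print(round(float(colimitation_scalar(0.95, 0.98)), 4))   # 0.7668

res = process_sa(n=100, seed=0)      # 9 Ca×I scenarios, 12 members
print({k: round(v, 2) for k, v in res.integrated.items()})
# {'mean': 11.59, 'variance': 2.66, 'S_carboxylation': 0.24,
#  'S_electron_transport': 0.11, 'S_tpu': 0.02,
#  'S_limiting_rate_selection': 0.57}
```

Under identical central parameters the smoothing member assimilates ~1.4
µmol m⁻² s⁻¹ less than the minimum-rule member at present-day CO2 and high
light, and the co-limitation scalar 0.7668 says smoothing removes 23% of
gross assimilation where all three rates meet. The process SA attributes
57% of ensemble variance in A to the limiting-rate-selection process alone
— more than carboxylation (24%), electron transport (11%) and TPU (2%)
combined — even though the carboxylation *parameters* dominate the purely
parametric Sobol indices.

A command-line interface mirrors the library:

```bash
photoensemble curve --model M1111 --preset fvcb-original -o curve.csv
photoensemble sa-process --n 100 --seed 0 -o process_sa.csv
photoensemble smooth-scan --theta-cj 0.95 --theta-cjp 0.98 -o smoothing.csv
photoensemble synth --vcmax 150 --theta-cj 0.99 --seed 3 -o aci.csv
photoensemble fit-aci --curve aci.csv --chains 7 --iters 4000 -o posterior.csv
```

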