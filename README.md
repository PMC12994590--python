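# mitrapk

Integrated parent–metabolite pharmacokinetics of **mitragynine** (the
principal psychoactive alkaloid of kratom, *Mitragyna speciosa*) and its
active metabolite **7-hydroxymitragynine**, for pharmacometricians and
clinical-pharmacology researchers who need to model both analytes jointly
from oral study-mean concentration data and to simulate repeated dosing
with propagated posterior uncertainty.

## The model

Both analytes share one linear ODE system in five amounts (mg): an oral
DEPOT drained at first-order rate *k*ₐ, a two-compartment disposition model
for the parent, and a two-compartment model for the metabolite fed by a
fraction *F*_met of the parent's elimination flux:

```
dDEPOT/dt          = -ka·DEPOT
dCENTER/dt         =  ka·DEPOT - (CL_app/Vc_app)·CENTER - (Q_app/Vc_app)·CENTER + (Q_app/Vp_app)·PERIPHERAL
dPERIPHERAL/dt     =  (Q_app/Vc_app)·CENTER - (Q_app/Vp_app)·PERIPHERAL
dMETABOLITE/dt     =  F_met·(CL_app/Vc_app)·CENTER - (CL_met_app/Vc_met_app)·METABOLITE
                      - (Q_met_app/Vc_met_app)·METABOLITE + (Q_met_app/Vp_met_app)·PERIPHERAL_MET
dPERIPHERAL_MET/dt =  (Q_met_app/Vc_met_app)·METABOLITE - (Q_met_app/Vp_met_app)·PERIPHERAL_MET
```

Concentrations are ng·mL⁻¹ (1000 × amount/central volume).  All parameters
are apparent (bioavailability-scaled) since only oral data inform them.

The analysis pipeline has four stages:

1. **data_prep** — ingest `time_h, mean_ng_ml, sd_ng_ml, analyte` CSVs,
   apply explicit outlier-exclusion rules (default: the metabolite point at
   35 h), compute per-point CVs floored at 0.05.
2. **prior fit** — deterministic weighted least squares on the natural-log
   concentration scale (weights 1/CV, normalized to mean 1; penalty 10¹⁰
   for unsolvable parameter vectors) via multi-start L-BFGS-B; the result
   seeds log-normal priors (fixed SD template, half-normal(0.5) residual
   priors).
3. **Bayesian inference** — log-normal observation model whose log-scale SD
   combines the observed CV and a proportional residual in quadrature;
   affine-invariant ensemble MCMC run as four independent chains;
   rank-normalized split-R̂, bulk ESS, pairwise correlations, and posterior
   predictive bands.
4. **multi-dose simulation** — posterior draws (or log-normal marginals
   matched to a published posterior summary) pushed through a repeated-dose
   regimen; per-dose Cmax/Cmin/tmax/AUC and accumulation factors.

A synthetic-data generator (`mitrapk.synthetic`) emulates the digitized
study-mean data structure so the whole pipeline is testable end to end.

## Worked example

```python
import mitrapk as mp

design = mp.SyntheticDesign(seed=7)          # 25 mg oral, 12 timepoints, cv 0.25/0.30
ds     = mp.generate_dataset(design)
fit    = mp.fit_deterministic(ds, dose=25.0, start=design.truth)
priors = mp.build_priors(fit)
draws  = mp.sample_posterior(ds, 25.0, priors, chains=4, iterations=500, seed=2)
print(draws.summary().loc[["ka", "CL_app", "F_met"]].round(2))
```

```
            mean  median    sd  ci_lower  ci_upper  rhat       ess
parameter
ka          2.50    2.36  0.78      1.39      4.49  1.01  28027.82
CL_app     15.53   15.51  2.19     11.30     19.82  1.01  33772.80
F_met       0.62    0.61  0.15      0.37      0.92  1.02  30059.55
```

R̂ ≈ 1 and large bulk ESS indicate converged, well-mixed chains; the 95 %
credible intervals cover the generating values (ka 1.99, CL_app 17.85,
F_met 0.65).  The same objects feed `posterior_predictive` (calibration
bands + coverage) and `simulate_ensemble`/`summarize_metrics` (repeated-dose
tables), or use the CLI:

```sh
mitrapk make-synthetic --seed 3 --out data.csv
mitrapk fit-prior  --data data.csv --dose-mg 25 --out priors.yaml
mitrapk fit-bayes  --data data.csv --dose-mg 25 --priors priors.yaml --seed 1 --out post.csv
mitrapk diagnose   --posterior post.csv --out diag.json
mitrapk ppc        --posterior post.csv --data data.csv --dose-mg 25 --out ppc.csv
mitrapk simulate   --posterior post.csv --dose-mg 25 --n-doses 7 --out-metrics metrics.csv
```

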