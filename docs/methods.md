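# Methods

## Model and assumptions

`mitrapk` models mitragynine and 7-hydroxymitragynine as one linked linear
ODE system: first-order oral absorption into the parent's two-compartment
disposition model, with a fraction `F_met` of the parent's central
elimination flux forming the metabolite, which has its own two-compartment
disposition.  Assumptions:

* **Linearity.** All processes are first-order; doubling the dose doubles
  every concentration.  No saturable metabolism or transport.
* **Apparent parameters.** Only oral data inform the model, so clearances
  and volumes are bioavailability-scaled (CL/F-type quantities); `F_met`
  likewise absorbs the metabolite's bioavailability scaling and may not be
  interpreted as an absolute molar conversion fraction.
* **Study-mean data.** Observations are per-timepoint means with SDs across
  subjects, not individual profiles.  There are no inter-individual random
  effects or covariates; the "posterior uncertainty" is uncertainty about
  the mean-profile parameters.
* **No metabolite dosing route.** The metabolite appears only via
  formation, so its scale is structurally tied to the parent (see
  *Identifiability*).

Units are fixed package-wide: amounts mg, volumes L, clearances L/h, times
h; concentrations ng/mL via the factor 1000 (mg/L → ng/mL with the model's
mg-and-L bookkeeping).

### Solver

Between doses the system is linear time-invariant, so the default solver
propagates the state **exactly** through an eigendecomposition of the 5×5
rate matrix, restarted at each bolus (doses are instantaneous additions to
the depot at exact multiples of the interval).  This is both more accurate
and ~20× faster than adaptive integration, which matters inside MCMC.  An
adaptive Runge-Kutta 4(5) integrator (rtol 1e-8, atol 1e-10) is available
via `method="rk45"`; the two agree to integrator tolerance in the test
suite, and the exact path falls back to RK45 if the eigenbasis is
ill-conditioned (condition number > 1e10).  Negative concentrations from
round-off are clipped to zero after solving because the downstream
log-likelihood requires positivity.

## Data preparation

Input tables carry `time_h, mean_ng_ml, sd_ng_ml, analyte` with analyte ∈
{parent, metabolite}.  Validation rejects duplicate (analyte, time) pairs
and unparseable values, naming the offending rows.  Records with mean ≤ 0
(e.g. pre-dose zeros) are retained for plotting but barred from log-scale
fitting.  Outlier handling is an **explicit, auditable rule list**, not an
algorithm: the default rule removes the metabolite observation at 35 h
(identified by visual inspection in the source study); removed records move
to an exclusions table with a reason string.  Per-point CVs are
sd/mean floored at 0.05 so that near-zero reported SDs cannot produce
unbounded weights.

## Deterministic prior fit

The first stage minimizes

    Cost(θ) = SSE_parent + SSE_metabolite,
    SSE = Σᵢ w̃ᵢ (ln C_obs,i − ln C_pred,i)²

with weights w̃ᵢ ∝ 1/CVᵢ normalized to mean 1 **within each analyte**, so
each analyte's SSE is internally balance-weighted (the normalization scope
is a design choice; pooled normalization differs only by a relative
analyte weighting that the plain two-term sum does not attempt to set).
Any parameter vector for which the model cannot be evaluated — solver
failure, non-finite or non-positive prediction at an observation time —
receives the penalty value exactly 1e10.

Optimization runs on an unconstrained scale (natural log for the nine
positive parameters, logit for `F_met`) under box bounds chosen as
realistic physiological limits: ka ∈ [0.05, 20] h⁻¹, clearances ∈
[0.1, 1000] L/h, volumes ∈ [1, 5000] L, F_met ∈ [0.01, 1].  L-BFGS-B is
started from the user's start plus 8 multiplicative jitters (log-normal,
SD 0.3, seeded).

**Ridge anchoring.**  The metabolite side has an exactly flat cost
direction (below).  A quasi-Newton method drifts arbitrarily far along an
exactly flat direction, driven only by finite-difference noise — in
experiments every start converged to the same cost at wildly different
ridge positions.  The optimizer therefore minimizes the cost plus a
vanishing Tikhonov anchor `1e-3·‖u − u_start‖²` on the transformed scale.
The anchor pins flat directions to the provided start (the minimal-change
solution, the same convention used to break ties between cost-equivalent
multi-start results) while biasing identified directions negligibly: their
curvature exceeds the anchor weight by ~4 orders of magnitude, and the
reported optimum cost is the unpenalized value.

`build_priors` centres a log-normal prior at ln(θ̂) for each structural
parameter and takes the log-scale prior SDs from a fixed shipped template
(per-parameter values 0.33–0.78, overridable); the two proportional
residual SDs get half-normal priors with scale 0.5 regardless of the fit.
How wide the template SDs "should" be is not derivable from the fit; they
are deliberately shipped as data, not computed.

## Identifiability

Jointly rescaling `F_met, CL_met_app, Vc_met_app, Q_met_app, Vp_met_app`
by any c > 0 (with F_met·c ≤ 1) leaves **both** concentration profiles
unchanged: the metabolite's rate constants and its amplitude
`F_met/Vc_met_app` are the only identifiable combinations, because no
route doses the metabolite directly.  This is the familiar
formation-fraction/volume confounding of parent–metabolite models without
IV metabolite reference data, and it surfaces as the strong
`F_met`–`CL_met_app` posterior correlation.  Consequences:

* the deterministic stage cannot estimate the metabolite's absolute scale —
  the anchor keeps it at the start value;
* the Bayesian stage resolves the scale **only through the priors**;
* the metabolite's peripheral distribution parameters (`Vc_met_app`,
  `Q_met_app`, `Vp_met_app`) are additionally only weakly informed by
  mean concentration data even along identified directions, and recover
  poorly (30–70 % errors at study-level noise) from the unregularized fit.

## Bayesian inference

Observed means are log-normal around the model prediction:

    ln y_i ~ Normal(ln C_pred,i, s_i),
    s_i = sqrt((σ_obs,i / C_obs,i)² + σ_prop²)

i.e. the observed CV (≈ log-scale SD of the reported mean) and a
proportional residual add in quadrature on the log-SD scale, with separate
σ_prop for parent and metabolite.  An alternative natural-scale combination
`sqrt(σ_obs² + (σ_prop·C_pred)²)/C_pred` is available via
`error_model="natural"`.  Priors: log-normal per structural parameter
(F_met's truncated to (0, 1)); half-normal(0.5) on each σ_prop — a positive
support is required of an SD even where a plain normal is quoted for it.

Sampling runs on the unconstrained scale with the exact Jacobian, one ODE
solve per proposal covering both analytes' observation times.  The sampler
is emcee's affine-invariant stretch ensemble, run as **four independent
ensembles of 32 walkers** mapped to the four chains (each with its own
seeded random state, so runs are bit-reproducible); the first half of the
iterations is discarded as warmup, and each chain's post-warmup draws are
flattened iteration-major so split-chain diagnostics see the serial
structure.  The backend is deliberately thin — any sampler that accepts the
same unconstrained log-posterior can replace it.  After sampling, split-R̂
is screened and the run is flagged (warning + metadata) if any parameter
exceeds 1.05.

### Diagnostics

R̂ and ESS are the rank-normalized split variants (split each chain in
half, replace draws by normal scores of pooled ranks with the Blom 3/8
offset; R̂ takes the max of the bulk and folded statistics; bulk ESS uses
FFT autocovariances with Geyer's initial-monotone truncation).  These are
the modern conservative defaults; the implementation agrees with an
independent reference implementation to 1e-6 in the test suite.  Note that
bulk ESS can legitimately exceed the number of stored draws when draws are
anticorrelated — walker-flattened ensembles produce this routinely — so
"ESS ≤ N" is not asserted anywhere.

The posterior predictive check replays the fitted observation model:
for each replicate a posterior draw is re-simulated and log-normal noise
with that draw's combined residual SD is added.  Percentile ribbons
(5/25/50/75/95) are computed on a dense grid using the proportional
component only (no observed SD exists off the sampling times); coverage is
the fraction of observed points inside the replicated 2.5–97.5 percentile
band at the observation times.

## Repeated-dose simulation

Parameter sets are either subsampled from a posterior (seeded, without
replacement by default) or — when only a printed posterior summary is
available — drawn from **independent log-normal marginals** matched to each
parameter's median and 95 % CI (μ = ln median, σ = ln(U/L)/(2·1.96);
F_met truncated at 1 by resampling).  The independence approximation
ignores posterior correlations; ensemble *medians* of the reported metrics
are robust to this (they are medians of monotone functions of
log-normals), while ensemble extremes are somewhat widened.

Default regimen and grid follow the reference analysis: 25 mg every 24 h ×
7 doses, 0 to 200 h in 0.5 h steps.  Per dosing interval [kτ, (k+1)τ):
Cmax is the grid maximum, tmax its grid time minus the dose time (reported
on the grid, no interpolation), Cmin is the concentration immediately
*before* the dose (so dose 1 reports 0 — the pre-dose trough convention),
and AUC is the composite trapezoid over the closed interval [kτ, kτ+τ],
the seventh interval ending at 168 h even though the grid runs to 200 h.
The accumulation factor is Cmax(dose 7)/Cmax(dose 1).  Summaries report
median/min/max across draws per dose event and metric.

A knife-edge worth knowing: at the reference posterior medians the
continuous parent peak time is 1.20 h, almost exactly between grid points,
so the pooled median grid-tmax of a 200-draw ensemble flips between 1.0 and
1.5 h with the random seed.  That is a property of reporting peak times on
a 0.5 h grid, not of the solver.

## Synthetic data

The generator emulates the structure of digitized study-mean oral PK data:
a single 25 mg dose sampled at {0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24, 36,
48} h, per-timepoint mean and SD for both analytes.  Means are drawn
log-normally around the model value with log-SD equal to the analyte CV
(0.25 parent, 0.30 metabolite — the magnitude of the between-subject
scatter visible in single-dose kratom studies), and the SD column is
reconstructed as CV × mean; the generator is therefore exactly
well-specified for the package's likelihood.  `inject_outlier` appends a
record at a chosen multiple of the model value to exercise the exclusion
rule.

What passing tests on these data do **not** show: robustness to
model misspecification (real profiles are not generated by this ODE),
to non-log-normal noise, to digitization error structure, or to
individual-level variability — none of which the study-mean design can
expose.

## Numerical choices

* Exact propagator with RK45 fallback and cross-check (above); rtol 1e-8 /
  atol 1e-10 when RK45 is used.
* Penalty constant exactly 1e10, bit-compatible with the stated rule.
* Anchor weight 1e-3 (above); L-BFGS-B maxiter 500.
* Multi-start tie window: relative 1e-6 on the anchored cost; ties resolve
  to the result closest to the start.
* emcee requires ≥ 24 walkers for 12 dimensions; the default is 32.
* Walker initialization: prior centres jittered by 0.25 prior SD;
  σ_prop initialized at half its prior scale.
* Trapezoid AUC on the 0.5 h grid carries ~0.7 % discretization error over
  the first parent interval (peak curvature); refining the grid to 0.25 h
  reduces it fourfold.  Reported reference tables use the same 0.5 h grid.

## Known limitations

* The metabolite's absolute scale is prior-driven (identifiability above);
  deterministic point estimates of the five metabolite parameters should
  not be trusted beyond the identifiable combinations, and at study-mean
  noise the unregularized weighted fit recovers fewer than 8 of 10
  parameters within 25 % in every tested replicate.
* No inter-individual variability, covariates, or nonlinear kinetics.
* The simulation's independence approximation to the posterior ignores the
  CL_app–Vc_app and F_met–CL_met_app correlations; medians are insensitive
  but min/max ranges widen.
* Ensemble MCMC provides no divergence diagnostics (a Hamiltonian notion);
  convergence screening rests on R̂/ESS and the PPC.
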