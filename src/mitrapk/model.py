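"""Linked parent-metabolite pharmacokinetic model.

The model tracks mitragynine (parent) and its active metabolite
7-hydroxymitragynine in a single linear ODE system with five states:

* ``DEPOT`` — unabsorbed oral parent drug, drained at first-order rate ``ka``;
* ``CENTER`` / ``PERIPHERAL`` — parent amounts in a two-compartment
  disposition model (apparent clearance ``CL_app``, central volume ``Vc_app``,
  intercompartmental clearance ``Q_app``, peripheral volume ``Vp_app``);
* ``METABOLITE`` / ``PERIPHERAL_MET`` — metabolite amounts in its own
  two-compartment model, fed by a fraction ``F_met`` of the parent's
  elimination flux (clearance ``CL_met_app``, volumes ``Vc_met_app`` /
  ``Vp_met_app``, intercompartmental clearance ``Q_met_app``).

All parameters are "apparent" (oral-bioavailability scaled) because only
oral data inform them.  Units are fixed package-wide: amounts mg, volumes L,
clearances L/h, times h; concentrations are reported in ng/mL via a factor
of 1000 (mg/L -> ng/mL... 1 mg/L == 1000 ng/L == 1 ug/mL; amounts in mg over
volumes in L give mg/L, and 1 mg/L = 1000 ng/mL).

Because the system is linear and time-invariant between doses, the default
solver propagates the state exactly through an eigendecomposition of the
system matrix; an adaptive RK45 integrator (rtol 1e-8, atol 1e-10) is
available via ``method="rk45"`` and agrees with the exact propagator to
integrator tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "PKParameters",
    "DoseRegimen",
    "SimulatedProfile",
    "pk_rhs",
    "system_matrix",
    "solve_profile",
    "metabolite_exposure_identity",
]

#: Canonical ordering of the ten structural parameters.
PARAM_NAMES = (
    "ka",
    "CL_app",
    "Vc_app",
    "Q_app",
    "Vp_app",
    "F_met",
    "CL_met_app",
    "Vc_met_app",
    "Q_met_app",
    "Vp_met_app",
)

STATE_NAMES = ("DEPOT", "CENTER", "PERIPHERAL", "METABOLITE", "PERIPHERAL_MET")

#: mg/L -> ng/mL
CONC_SCALE = 1000.0


class InvalidParameterError(ValueError):
    """A parameter vector violates the model invariants."""


class IntegrationFailure(RuntimeError):
    """The ODE solver failed; carries the offending parameter set."""

    def __init__(self, message: str, params: "PKParameters | None" = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters of the parent-metabolite model.

    ka : first-order absorption rate constant (1/h)
    CL_app : apparent parent clearance (L/h)
    Vc_app : apparent parent central volume (L)
    Q_app : apparent parent intercompartmental clearance (L/h)
    Vp_app : apparent parent peripheral volume (L)
    F_met : fraction of parent clearance forming the metabolite (0..1)
    CL_met_app : apparent metabolite clearance (L/h)
    Vc_met_app : apparent metabolite central volume (L)
    Q_met_app : apparent metabolite intercompartmental clearance (L/h)
    Vp_met_app : apparent metabolite peripheral volume (L)
    """

    ka: float
    CL_app: float
    Vc_app: float
    Q_app: float
    Vp_app: float
    F_met: float
    CL_met_app: float
    Vc_met_app: float
    Q_met_app: float
    Vp_met_app: float

    def __post_init__(self):
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError(f"non-finite parameter in {self}")
        positives = {n: v for n, v in zip(PARAM_NAMES, vals) if n != "F_met"}
        bad = [n for n, v in positives.items() if v <= 0]
        if bad:
            raise InvalidParameterError(f"parameters must be > 0: {bad}")
        if not 0.0 <= self.F_met <= 1.0:
            raise InvalidParameterError(f"F_met must lie in [0, 1], got {self.F_met}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "PKParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise InvalidParameterError(
                f"expected {len(PARAM_NAMES)} parameters, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, values)))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def replace(self, **kwargs) -> "PKParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class DoseRegimen:
    """Oral bolus regimen: ``dose`` mg into DEPOT every ``interval`` h, ``n_doses`` times."""

    dose: float
    interval: float = 24.0
    n_doses: int = 1

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def dose_times(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.interval


@dataclass
class SimulatedProfile:
    """Concentration-time profile for both analytes on a common grid.

    ``amounts`` keeps the raw compartment amounts (n_times x 5, mg) for
    mass-balance work; concentrations are ng/mL.
    """

    times: np.ndarray
    conc_parent: np.ndarray
    conc_metabolite: np.ndarray
    amounts: np.ndarray | None = None

    def concentration(self, analyte: str) -> np.ndarray:
        if analyte == "parent":
            return self.conc_parent
        if analyte == "metabolite":
            return self.conc_metabolite
        raise KeyError(f"unknown analyte {analyte!r}")


def system_matrix(params: PKParameters) -> np.ndarray:
    """Coefficient matrix A of the linear system d(state)/dt = A @ state."""
    ka = params.ka
    kel = params.CL_app / params.Vc_app
    k12 = params.Q_app / params.Vc_app
    k21 = params.Q_app / params.Vp_app
    kmel = params.CL_met_app / params.Vc_met_app
    k34 = params.Q_met_app / params.Vc_met_app
    k43 = params.Q_met_app / params.Vp_met_app
    fm = params.F_met
    return np.array(
        [
            [-ka, 0.0, 0.0, 0.0, 0.0],
            [ka, -(kel + k12), k21, 0.0, 0.0],
            [0.0, k12, -k21, 0.0, 0.0],
            [0.0, fm * kel, 0.0, -(kmel + k34), k43],
            [0.0, 0.0, 0.0, k34, -k43],
        ]
    )


def pk_rhs(state, params: PKParameters) -> np.ndarray:
    """Time-derivative of the five compartment amounts.

    Explicit form (amounts mg, time h):

    * dDEPOT/dt      = -ka*DEPOT
    * dCENTER/dt     = ka*DEPOT - (CL_app/Vc_app)*CENTER
      - (Q_app/Vc_app)*CENTER + (Q_app/Vp_app)*PERIPHERAL
    * dPERIPHERAL/dt = (Q_app/Vc_app)*CENTER - (Q_app/Vp_app)*PERIPHERAL
    * dMETABOLITE/dt = F_met*(CL_app/Vc_app)*CENTER
      - (CL_met_app/Vc_met_app + Q_met_app/Vc_met_app)*METABOLITE
      + (Q_met_app/Vp_met_app)*PERIPHERAL_MET
    * dPERIPHERAL_MET/dt = (Q_met_app/Vc_met_app)*METABOLITE
      - (Q_met_app/Vp_met_app)*PERIPHERAL_MET
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (5,):
        raise InvalidParameterError(f"state must have 5 components, got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise InvalidParameterError("non-finite state")
    return system_matrix(params) @ state


def _propagate_exact(A, x0, dts, w=None, V=None, Vinv=None):
    """Evaluate exp(A*dt) @ x0 for each dt via eigendecomposition."""
    c = Vinv @ x0.astype(complex)
    # states columns: V @ (exp(w*dt) * c)
    E = np.exp(np.outer(w, dts))  # (5, n)
    return (V @ (E * c[:, None])).real


def _eig_factors(A):
    w, V = np.linalg.eig(A)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
    return w, V, np.linalg.inv(V)


def solve_profile(
    params: PKParameters,
    regimen: DoseRegimen,
    grid=None,
    *,
    method: str = "exact",
    conc_scale: float = CONC_SCALE,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    keep_amounts: bool = False,
) -> SimulatedProfile:
    """Solve the dosing regimen on a time grid and return concentrations.

    Doses are instantaneous boluses into DEPOT at times k*interval,
    k = 0..n_doses-1; the propagation is restarted at each dose time so the
    depot discontinuity is handled exactly.  A grid point that coincides
    with a dose time reports the (continuous) plasma concentration there.

    Parameters
    ----------
    grid : array-like of times (h), strictly increasing, all >= 0.
        Defaults to a 0.5 h grid over the full regimen plus one interval.
    method : ``"exact"`` (eigendecomposition propagator; default) or
        ``"rk45"`` (adaptive Runge-Kutta 4(5)).
    conc_scale : factor converting mg/L to the reported unit (1000 -> ng/mL).

    Negative concentrations from round-off are clipped to zero.
    """
    if grid is None:
        horizon = regimen.interval * regimen.n_doses
        grid = np.arange(0.0, horizon + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array of times")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid times must be strictly increasing")
    if grid[0] < 0:
        raise ValueError("grid times must be >= 0")

    A = system_matrix(params)
    dose_times = regimen.dose_times
    # segment boundaries: dose times within/after grid start, plus grid end
    t_end = grid[-1]
    bounds = [t for t in dose_times if t <= t_end] or [0.0]
    if bounds[0] != 0.0:
        bounds = [0.0] + bounds

    if method == "exact":
        try:
            w, V, Vinv = _eig_factors(A)
        except np.linalg.LinAlgError:
            w = None
    elif method != "rk45":
        raise ValueError(f"unknown method {method!r}")

    x = np.zeros(5)
    out = np.empty((grid.size, 5))
    for i, t0 in enumerate(bounds):
        if t0 in dose_times:
            x = x.copy()
            x[0] += regimen.dose
        t1 = bounds[i + 1] if i + 1 < len(bounds) else np.inf
        # grid points in [t0, t1); the final segment is closed on the right
        sel = (grid >= t0) & (grid < t1) if np.isfinite(t1) else (grid >= t0)
        ts = grid[sel]
        if method == "exact" and w is not None:
            if ts.size:
                out[sel] = _propagate_exact(A, x, ts - t0, w, V, Vinv).T
            if np.isfinite(t1):
                x = _propagate_exact(A, x, np.array([t1 - t0]), w, V, Vinv)[:, 0]
        else:
            t_stop = t1 if np.isfinite(t1) else (ts[-1] if ts.size else t0)
            if t_stop > t0:
                t_eval = np.unique(np.append(ts, t_stop))
                sol = solve_ivp(
                    lambda t, y: A @ y,
                    (t0, t_stop),
                    x,
                    method="RK45",
                    t_eval=t_eval,
                    rtol=rtol,
                    atol=atol,
                )
                if not sol.success:
                    raise IntegrationFailure(
                        f"RK45 failed on [{t0}, {t_stop}]: {sol.message}", params
                    )
                if ts.size:
                    out[sel] = sol.y[:, np.searchsorted(t_eval, ts)].T
                x = sol.y[:, -1]
            elif ts.size:
                out[sel] = x

    if not np.all(np.isfinite(out)):
        raise IntegrationFailure("non-finite amounts in solution", params)
    out = np.clip(out, 0.0, None)
    conc_parent = conc_scale * out[:, 1] / params.Vc_app
    conc_met = conc_scale * out[:, 3] / params.Vc_met_app
    return SimulatedProfile(
        times=grid,
        conc_parent=conc_parent,
        conc_metabolite=conc_met,
        amounts=out if keep_amounts else None,
    )


def metabolite_exposure_identity(params: PKParameters, dose: float) -> float:
    """Infinite-time metabolite AUC (ng*h/mL) implied by mass balance.

    Every mg of parent eliminated sends F_met mg to the metabolite, and the
    metabolite's own AUC over (0, inf) is (amount formed)/CL_met_app; in
    ng*h/mL this is ``F_met * dose * 1e6 / (CL_met_app * 1000)``.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return params.F_met * dose * 1e6 / (params.CL_met_app * 1000.0)
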