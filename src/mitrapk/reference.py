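"""Reference posterior summary for oral mitragynine in healthy adults.

The package bundles, as plain data, the posterior summary of a Bayesian fit
of this parent-metabolite model to single-dose (25 mg range) oral
mitragynine study-mean data.  It serves two roles:

* default ground truth for the synthetic-data generator, so that recovery
  experiments run at a realistic point of parameter space; and
* the basis of the repeated-dose simulation example, where posterior
  uncertainty is emulated by independent log-normal marginals matched to
  each parameter's median and 95 % credible interval.

``REFERENCE_POSTERIOR`` columns: mean, median, sd, ci_lower, ci_upper
(2.5th/97.5th percentiles).  Structural-parameter units follow
:mod:`mitrapk.model`; the two proportional residual SDs are dimensionless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import PARAM_NAMES, PKParameters

__all__ = [
    "REFERENCE_POSTERIOR",
    "REFERENCE_MEDIAN_PARAMS",
    "DEFAULT_PRIOR_MEANS",
    "DEFAULT_PRIOR_SDS",
    "lognormal_marginals",
]

_rows = {
    # name:          (mean,  median,   sd,  ci_lo,  ci_hi)
    "ka":            (2.11,   1.99,  0.72,   1.05,   3.92),
    "CL_app":        (18.01,  17.85, 2.23,  14.08,  22.86),
    "Vc_app":        (117.98, 115.71, 21.26, 82.08, 165.48),
    "Q_app":         (11.03,  10.76, 2.08,   7.74,  15.94),
    "Vp_app":        (358.87, 355.64, 69.81, 230.25, 487.40),
    "F_met":         (0.66,   0.65,  0.14,   0.41,   0.95),
    "CL_met_app":    (108.03, 106.29, 23.47, 67.38, 156.60),
    "Vc_met_app":    (57.37,  50.61, 28.49,  23.01, 130.45),
    "Q_met_app":     (10.11,  8.52,  6.54,   1.83,  26.53),
    "Vp_met_app":    (87.57,  71.76, 58.62,  17.82, 248.95),
    "sigma_prop_parent": (0.17, 0.14, 0.13,  0.01,   0.49),
    "sigma_prop_met":    (0.13, 0.11, 0.10,  0.01,   0.39),
}

REFERENCE_POSTERIOR = pd.DataFrame.from_dict(
    _rows, orient="index", columns=["mean", "median", "sd", "ci_lower", "ci_upper"]
)
REFERENCE_POSTERIOR.index.name = "parameter"

#: Posterior-median structural parameters (the default synthetic truth).
REFERENCE_MEDIAN_PARAMS = PKParameters(
    **{n: float(REFERENCE_POSTERIOR.loc[n, "median"]) for n in PARAM_NAMES}
)

#: Log-scale prior means for the structural parameters (natural-log of a
#: deterministic pre-fit of the same data; see :mod:`mitrapk.priorfit`).
DEFAULT_PRIOR_MEANS = {
    "ka": 0.60,
    "CL_app": 3.00,
    "Vc_app": 4.99,
    "Q_app": 2.39,
    "Vp_app": 5.77,
    "F_met": -0.48,
    "CL_met_app": 4.58,
    "Vc_met_app": 4.40,
    "Q_met_app": 2.09,
    "Vp_met_app": 4.41,
}

#: Log-scale prior SDs shipped as a fixed template (overridable).
DEFAULT_PRIOR_SDS = {
    "ka": 0.41,
    "CL_app": 0.33,
    "Vc_app": 0.39,
    "Q_app": 0.42,
    "Vp_app": 0.36,
    "F_met": 0.36,
    "CL_met_app": 0.33,
    "Vc_met_app": 0.56,
    "Q_met_app": 0.77,
    "Vp_met_app": 0.78,
}


def lognormal_marginals(summary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Log-normal (mu, sigma) per parameter matched to median and 95 % CI.

    mu = ln(median); sigma = ln(ci_upper/ci_lower) / (2 * z_0.975).  Used to
    emulate posterior marginals when only a printed summary is available.
    """
    if summary is None:
        summary = REFERENCE_POSTERIOR
    z = norm.ppf(0.975)
    mu = np.log(summary["median"])
    sigma = np.log(summary["ci_upper"] / summary["ci_lower"]) / (2.0 * z)
    return pd.DataFrame({"mu": mu, "sigma": sigma})
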