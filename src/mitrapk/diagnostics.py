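"""Convergence diagnostics and posterior predictive checking.

R-hat is the rank-normalized split potential scale reduction factor and ESS
the rank-normalized bulk effective sample size (Vehtari et al. 2021):
each chain is split in half, draws are replaced by normal scores of their
pooled ranks, and the classic between/within variance ratio (for R-hat) or
the Geyer initial-monotone autocorrelation sum (for ESS) is applied to the
transformed chains.  These rank-based variants are the modern defaults and
are strictly more conservative than the classic statistics.

The posterior predictive check replays the fitted observation model:
parameter draws are sampled from the posterior, profiles are re-simulated,
log-normal observation noise with that draw's residual SDs is added, and
percentile bands of the replicated observations are compared with the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len
from scipy.special import ndtri
from scipy.stats import rankdata

from .bayes import FULL_PARAM_NAMES, PosteriorDraws, _combined_log_sd
from .data import ConcentrationDataset
from .model import PARAM_NAMES, DoseRegimen, PKParameters, solve_profile

__all__ = [
    "DiagnosticsSummary",
    "PPCBands",
    "compute_rhat_ess",
    "posterior_predictive",
]

PPC_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)


@dataclass
class DiagnosticsSummary:
    """Per-parameter R-hat/ESS table, pairwise correlations, divergences."""

    table: pd.DataFrame
    correlations: pd.DataFrame
    divergences: int = 0


@dataclass
class PPCBands:
    """Replicated-observation percentile bands per analyte and time.

    ``bands`` columns: analyte, time_h, p5, p25, p50, p75, p95.
    ``coverage`` maps analyte (and "overall") to the fraction of observed
    points inside the replicated 2.5th-97.5th percentile band.
    """

    bands: pd.DataFrame
    coverage: dict
    n_rep: int


def _z_scale(x: np.ndarray) -> np.ndarray:
    """Normal scores of pooled ranks (Blom offset 3/8)."""
    r = rankdata(x, method="average")
    return ndtri((r - 0.375) / (x.size + 0.25)).reshape(x.shape)


def _split_chains(x: np.ndarray) -> np.ndarray:
    half = x.shape[1] // 2
    return np.vstack([x[:, :half], x[:, -half:]])


def _basic_rhat(x: np.ndarray) -> float:
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    return float(np.sqrt((b / w + n - 1) / n))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased FFT autocovariance along the draw axis, per chain."""
    n = x.shape[1]
    m = next_fast_len(2 * n)
    xc = x - x.mean(axis=1, keepdims=True)
    f = np.fft.rfft(xc, n=m, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), n=m, axis=1)[:, :n].real
    return acov / n


def _bulk_ess(x: np.ndarray) -> float:
    """Geyer initial-monotone ESS of split rank-normalized chains."""
    z = _z_scale(_split_chains(x))
    m, n = z.shape
    if (z.max() - z.min()) < np.finfo(float).resolution:
        return float(z.size)
    acov = _autocov(z)
    mean_var = acov[:, 0].mean() * n / (n - 1.0)
    var_plus = mean_var * (n - 1.0) / n
    if m > 1:
        var_plus += z.mean(axis=1).var(ddof=1)

    rho = np.zeros(n)
    rho_even = 1.0
    rho[0] = rho_even
    rho_odd = 1.0 - (mean_var - acov[:, 1].mean()) / var_plus
    rho[1] = rho_odd
    t = 1
    while t < (n - 3) and (rho_even + rho_odd) > 0.0:
        rho_even = 1.0 - (mean_var - acov[:, t + 1].mean()) / var_plus
        rho_odd = 1.0 - (mean_var - acov[:, t + 2].mean()) / var_plus
        if (rho_even + rho_odd) >= 0:
            rho[t + 1] = rho_even
            rho[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:
        rho[max_t + 1] = rho_even
    # enforce monotone decreasing pair sums
    t = 1
    while t <= max_t - 2:
        if (rho[t + 1] + rho[t + 2]) > (rho[t - 1] + rho[t]):
            rho[t + 1] = (rho[t - 1] + rho[t]) / 2.0
            rho[t + 2] = rho[t + 1]
        t += 2
    size = m * n
    tau = -1.0 + 2.0 * np.sum(rho[: max_t + 1]) + np.sum(rho[max_t + 1 : max_t + 2])
    tau = max(tau, 1.0 / np.log10(size))
    return float(size / tau)


def rhat_rank(chains: np.ndarray) -> float:
    """Rank-normalized split R-hat for one parameter, chains shape (m, n)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("R-hat needs >= 2 chains of draws")
    if chains.shape[1] < 4:
        raise ValueError("R-hat needs >= 4 draws per chain")
    split = _split_chains(chains)
    bulk = _basic_rhat(_z_scale(split))
    folded = _basic_rhat(_z_scale(np.abs(split - np.median(split))))
    return max(bulk, folded)


def ess_bulk(chains: np.ndarray) -> float:
    """Rank-normalized bulk ESS for one parameter, chains shape (m, n)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-D (chains, draws)")
    if chains.shape[1] < 4:
        raise ValueError("ESS needs >= 4 draws per chain")
    return _bulk_ess(chains)


def compute_rhat_ess(draws: PosteriorDraws) -> DiagnosticsSummary:
    """Split R-hat, bulk ESS and pairwise correlations for every parameter."""
    if draws.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    rows = {}
    for name in draws.param_names:
        x = draws.parameter(name)
        rows[name] = {"rhat": rhat_rank(x), "ess": ess_bulk(x)}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    flat = draws.flattened()
    corr = pd.DataFrame(
        np.corrcoef(flat, rowvar=False),
        index=draws.param_names,
        columns=draws.param_names,
    )
    return DiagnosticsSummary(
        table=table,
        correlations=corr,
        divergences=int(draws.metadata.get("divergences", 0)),
    )


def posterior_predictive(
    draws: PosteriorDraws,
    ds: ConcentrationDataset,
    dose: float,
    n_rep: int = 500,
    seed: int = 0,
    *,
    grid=None,
    error_model: str | None = None,
) -> PPCBands:
    """Replicate datasets from the posterior and band them against the data.

    For each of ``n_rep`` posterior draws the single-dose profile is
    re-simulated and log-normal noise with that draw's combined residual SD
    is added.  Bands are computed on a dense grid (residual term only, since
    no observed SD exists off the sampling times); coverage counts observed
    points inside the replicated 2.5th-97.5th band at the observation times.
    """
    if error_model is None:
        error_model = draws.metadata.get("error_model", "cv")
    rng = np.random.default_rng(seed)
    flat = draws.flattened()
    idx = rng.integers(0, flat.shape[0], size=n_rep)
    fit = ds.fittable()
    if grid is None:
        t_max = float(fit["time_h"].max())
        grid = np.arange(0.0, t_max + 0.25, 0.5)
        if grid[0] == 0.0:
            grid = grid[1:]  # concentration at t=0 is 0; log-noise undefined
    grid = np.asarray(grid, dtype=float)

    obs = {a: fit[fit["analyte"] == a] for a in ("parent", "metabolite")}
    grid_rep = {a: np.empty((n_rep, grid.size)) for a in obs}
    obs_rep = {a: np.empty((n_rep, len(obs[a]))) for a in obs}

    sig_idx = {
        "parent": FULL_PARAM_NAMES.index("sigma_prop_parent"),
        "metabolite": FULL_PARAM_NAMES.index("sigma_prop_met"),
    }
    for r, i in enumerate(idx):
        vec = flat[i]
        theta = PKParameters.from_array(vec[: len(PARAM_NAMES)])
        regimen = DoseRegimen(dose=dose, interval=24.0, n_doses=1)
        all_t = np.unique(np.concatenate([grid] + [o["time_h"].to_numpy() for o in obs.values()]))
        prof = solve_profile(theta, regimen, grid=all_t)
        for a in obs:
            sigma = vec[sig_idx[a]]
            pred_grid = np.interp(grid, all_t, prof.concentration(a))
            noise = np.exp(sigma * rng.standard_normal(grid.size))
            grid_rep[a][r] = pred_grid * noise
            o = obs[a]
            pred_obs = np.interp(o["time_h"].to_numpy(), all_t, prof.concentration(a))
            s = _combined_log_sd(
                o["mean_ng_ml"].to_numpy(),
                o["sd_ng_ml"].to_numpy(),
                pred_obs,
                sigma,
                error_model,
            )
            obs_rep[a][r] = np.exp(
                np.log(np.maximum(pred_obs, 1e-300)) + s * rng.standard_normal(len(o))
            )

    frames = []
    coverage = {}
    n_in_total = n_total = 0
    for a in obs:
        pct = np.percentile(grid_rep[a], PPC_PERCENTILES, axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "analyte": a,
                    "time_h": grid,
                    **{f"p{int(p)}": pct[j] for j, p in enumerate(PPC_PERCENTILES)},
                }
            )
        )
        o = obs[a]
        if len(o):
            lo, hi = np.percentile(obs_rep[a], [2.5, 97.5], axis=0)
            y = o["mean_ng_ml"].to_numpy()
            inside = (y >= lo) & (y <= hi)
            coverage[a] = float(inside.mean())
            n_in_total += int(inside.sum())
            n_total += len(o)
    coverage["overall"] = n_in_total / n_total if n_total else np.nan
    return PPCBands(bands=pd.concat(frames, ignore_index=True), coverage=coverage, n_rep=n_rep)
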