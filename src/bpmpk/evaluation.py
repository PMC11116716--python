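"""Model evaluation: prediction-error metrics, bootstrap, pcVPC, GOF residuals.

Prediction-error metrics follow the external-validation convention:
PE_i = (PRED_i - DV_i)/DV_i * 100%, summarized by the median (MDPE),
median absolute value (MAPE) and the fractions of predictions within
+/-20% (F20) and +/-30% (F30).  A model is judged satisfactory when
|MDPE| <= 15%, MAPE <= 30%, F20 > 35% and F30 > 50%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .estimation import (
    CompiledDataset,
    FitResult,
    ValidationError,
    _fo_terms,
    ebe_estimate,
    fit_fo,
)
from .pkmodel import DomainError
from .population import PopulationModel

__all__ = [
    "PredictionErrorSummary",
    "BootstrapResult",
    "VPCResult",
    "prediction_errors",
    "summarize_pe",
    "bias_percent",
    "bootstrap_model",
    "simulate_observations",
    "pc_vpc",
    "gof_table",
]

logger = logging.getLogger(__name__)

# acceptability standards for external validation
MDPE_LIMIT = 15.0
MAPE_LIMIT = 30.0
F20_FLOOR = 35.0
F30_FLOOR = 50.0


@dataclass(frozen=True)
class PredictionErrorSummary:
    mdpe: float
    mape: float
    f20: float
    f30: float
    n: int
    satisfactory: bool


def prediction_errors(pred, obs) -> np.ndarray:
    """Signed relative prediction errors in percent."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValidationError("pred and obs must have equal length")
    if (obs <= 0).any():
        raise DomainError("observations must be > 0 for relative prediction error")
    return (pred - obs) / obs * 100.0


def summarize_pe(pe) -> PredictionErrorSummary:
    """MDPE/MAPE/F20/F30 summary with the acceptability verdict."""
    pe = np.asarray(pe, float)
    if pe.size == 0:
        raise ValidationError("empty prediction-error vector")
    ape = np.abs(pe)
    mdpe = float(np.median(pe))
    mape = float(np.median(ape))
    f20 = float(100.0 * np.mean(ape <= 20.0))
    f30 = float(100.0 * np.mean(ape <= 30.0))
    ok = abs(mdpe) <= MDPE_LIMIT and mape <= MAPE_LIMIT and f20 > F20_FLOOR and f30 > F30_FLOOR
    return PredictionErrorSummary(mdpe, mape, f20, f30, int(pe.size), ok)


def bias_percent(point_estimate: float, bootstrap_median: float) -> float:
    """(bootstrap median - point estimate) / point estimate * 100."""
    if point_estimate == 0:
        raise DomainError("point estimate must be nonzero")
    return (bootstrap_median - point_estimate) / point_estimate * 100.0


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap summary (median, 5th–95th percentiles, bias%)."""

    table: pd.DataFrame
    n_requested: int
    n_successful: int
    warning: str = ""


def bootstrap_model(
    data: list[SubjectRecord] | CompiledDataset,
    fit: FitResult,
    n_reps: int = 1000,
    seed: int = 0,
    **fit_kwargs,
) -> BootstrapResult:
    """Non-parametric bootstrap: resample subjects with replacement, refit.

    Failed replicates (non-convergence or numerical failure) are dropped and
    counted; a warning is set when more than 20% fail.
    """
    subjects = data.subjects if isinstance(data, CompiledDataset) else list(data)
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("n_starts", 1)
    fit_kwargs.setdefault("compute_se", False)
    point = fit.estimates()
    rows: list[dict[str, float]] = []
    for rep in range(n_reps):
        idx = rng.integers(0, len(subjects), size=len(subjects))
        resampled = [
            SubjectRecord(
                id=j + 1,
                covariates=subjects[i].covariates,
                doses=subjects[i].doses,
                observations=subjects[i].observations,
            )
            for j, i in enumerate(idx)
        ]
        try:
            rep_fit = fit_fo(resampled, fit.model, **fit_kwargs)
        except (ValidationError, DomainError, np.linalg.LinAlgError) as exc:
            logger.debug("bootstrap replicate %d failed: %s", rep, exc)
            continue
        if not rep_fit.converged:
            continue
        rows.append(rep_fit.estimates())
    n_ok = len(rows)
    reps = pd.DataFrame(rows)
    records = []
    for name, est in point.items():
        if n_ok:
            col = reps[name].to_numpy()
            med = float(np.median(col))
            p5, p95 = (float(v) for v in np.percentile(col, [5, 95]))
        else:
            med = p5 = p95 = math.nan
        records.append(
            {
                "parameter": name,
                "estimate": est,
                "median": med,
                "p5": p5,
                "p95": p95,
                "bias_percent": bias_percent(est, med) if n_ok and est != 0 else math.nan,
            }
        )
    warning = ""
    if n_reps and (n_reps - n_ok) / n_reps > 0.20:
        warning = f"{n_reps - n_ok}/{n_reps} bootstrap replicates failed"
        logger.warning(warning)
    return BootstrapResult(pd.DataFrame(records), n_reps, n_ok, warning)


# ---- simulation-based diagnostics ----------------------------------------


def simulate_observations(
    data: CompiledDataset, model: PopulationModel, rng: np.random.Generator
) -> np.ndarray:
    """One replicate of the dataset's observations under `model`.

    Same design (subjects, doses, times); fresh eta and residual draws.
    Residual noise is truncated at zero like the generator's.
    """
    typ = model.typical_arrays(data.covariates)
    params = dict(typ)
    for name, var in model.omega.items():
        eta = rng.normal(0.0, math.sqrt(var), size=data.n_subjects) if var > 0 else 0.0
        params[name] = typ[name] * np.exp(eta)
    f = data.predict(params, model.n_compartments)
    var = model.residual_var(f)
    y = f + rng.normal(0.0, np.sqrt(var), size=f.size)
    return np.maximum(y, 0.0)


@dataclass
class VPCResult:
    """Prediction-corrected VPC summary.

    ``bins`` has one row per time bin with observed percentiles and the
    simulated confidence bands; ``coverage`` is the fraction of observations
    inside the simulated 95% prediction band of their bin.
    """

    bins: pd.DataFrame
    coverage: float
    n_simulations: int
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))


def _time_after_last_dose(data: CompiledDataset) -> np.ndarray:
    tald = np.full(data.obs_y.size, np.inf)
    np.minimum.at(tald, data.pair_obs, data.pair_u)
    tald[~np.isfinite(tald)] = 0.0
    return tald


def _make_bins(tald: np.ndarray, n_bins: int, min_per_bin: int = 5) -> np.ndarray:
    """Quantile bin edges on time after last dose; sparse bins merged."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(tald, qs))
    while len(edges) > 2:
        idx = np.clip(np.searchsorted(edges, tald, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        small = np.flatnonzero(counts < min_per_bin)
        if small.size == 0:
            break
        k = small[0]
        drop = k + 1 if k + 1 < len(edges) - 1 or k == 0 else k
        logger.info("merging sparse VPC bin %d with its neighbor", k)
        edges = np.delete(edges, drop)
    return edges


def pc_vpc(
    data: list[SubjectRecord] | CompiledDataset,
    model: PopulationModel,
    n_sim: int = 1000,
    n_bins: int = 6,
    seed: int = 0,
) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Each observed and simulated value is rescaled by (bin median typical
    prediction / its own typical prediction) to normalize dose and covariate
    differences, then observed 5th/50th/95th percentiles per bin are compared
    with the 95% confidence bands of the same percentiles across replicates.
    """
    if not isinstance(data, CompiledDataset):
        data = CompiledDataset(data)
    rng = np.random.default_rng(seed)
    f0, _, _ = _fo_terms(data, model)
    pred = np.maximum(f0, 1e-12)
    tald = _time_after_last_dose(data)
    edges = _make_bins(tald, n_bins)
    bin_idx = np.clip(np.searchsorted(edges, tald, side="right") - 1, 0, len(edges) - 2)
    n_b = len(edges) - 1

    bin_median_pred = np.array(
        [np.median(pred[bin_idx == b]) if (bin_idx == b).any() else np.nan for b in range(n_b)]
    )
    correction = bin_median_pred[bin_idx] / pred
    pc_obs = data.obs_y * correction

    sims = np.empty((n_sim, data.obs_y.size))
    for k in range(n_sim):
        sims[k] = simulate_observations(data, model, rng) * correction

    pcts = (5.0, 50.0, 95.0)
    rows = []
    inside = np.zeros(data.obs_y.size, dtype=bool)
    for b in range(n_b):
        mask = bin_idx == b
        obs_b = pc_obs[mask]
        sim_b = sims[:, mask]
        obs_p = np.percentile(obs_b, pcts)
        sim_p = np.percentile(sim_b, pcts, axis=1)  # (3, n_sim)
        ci_lo = np.percentile(sim_p, 2.5, axis=1)
        ci_hi = np.percentile(sim_p, 97.5, axis=1)
        pooled = sim_b.ravel()
        band_lo, band_hi = np.percentile(pooled, [2.5, 97.5])
        band10, band90 = np.percentile(pooled, [10.0, 90.0])
        inside[mask] = (obs_b >= band_lo) & (obs_b <= band_hi)
        rows.append(
            {
                "bin": b,
                "t_lo": edges[b],
                "t_hi": edges[b + 1],
                "n_obs": int(mask.sum()),
                "obs_p5": obs_p[0],
                "obs_p50": obs_p[1],
                "obs_p95": obs_p[2],
                "sim_p5_lo": ci_lo[0],
                "sim_p5_hi": ci_hi[0],
                "sim_p50_lo": ci_lo[1],
                "sim_p50_hi": ci_hi[1],
                "sim_p95_lo": ci_lo[2],
                "sim_p95_hi": ci_hi[2],
                "band95_lo": band_lo,
                "band95_hi": band_hi,
                "band_p10": band10,
                "band_p90": band90,
            }
        )
    return VPCResult(
        bins=pd.DataFrame(rows),
        coverage=float(inside.mean()),
        n_simulations=n_sim,
        bin_edges=edges,
    )


def gof_table(
    data: list[SubjectRecord] | CompiledDataset, model: PopulationModel
) -> pd.DataFrame:
    """Goodness-of-fit table: DV, PRED, IPRED, WRES and time per observation.

    WRES is the FO weighted residual C^{-1/2}(y - f(0)) under the FO marginal
    covariance; with FO estimation this is the consistent analogue of the
    conditional weighted residual used with conditional methods.
    """
    if not isinstance(data, CompiledDataset):
        data = CompiledDataset(data)
    f0, var, F = _fo_terms(data, model)
    omega_diag = np.array([model.omega[n] for n in model.eta_names()])
    wres = np.empty_like(f0)
    for idx in data.subj_obs:
        Fi = F[idx]
        Ci = Fi @ np.diag(omega_diag) @ Fi.T + np.diag(var[idx])
        vals, vecs = np.linalg.eigh(Ci)
        inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(np.maximum(vals, 1e-300))) @ vecs.T
        wres[idx] = inv_sqrt @ (data.obs_y[idx] - f0[idx])
    ipred = np.empty_like(f0)
    for s_idx, subject in enumerate(data.subjects):
        _, ip = ebe_estimate(subject, model)
        ipred[data.subj_obs[s_idx]] = ip
    return pd.DataFrame(
        {
            "ID": [data.subjects[i].id for i in data.obs_subj],
            "TIME": data.obs_time,
            "DV": data.obs_y,
            "PRED": f0,
            "IPRED": ipred,
            "WRES": wres,
        }
    )
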