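"""Robust estimation of mean and variance of log-fluorescence per promoter.

Single-cell log-fluorescence distributions are approximately Gaussian with a
small admixture of outliers (debris, contaminants, non-growing cells). Each
event set is therefore fit with a two-component mixture — a Gaussian bulk
plus a uniform outlier component whose support is fixed to the observed data
range — by expectation-maximization. The Gaussian component's mean and
variance are the promoter's expression summary; the uniform mixing weight is
the estimated outlier fraction.

A batched EM (:func:`fit_mixture_batch`) runs the same update on thousands
of equally sized event sets at once, which is what makes library-scale
summarization (~14,500 promoter x condition fits) cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "MixtureFitError",
    "MixtureFit",
    "fit_gaussian_uniform_mixture",
    "fit_mixture_batch",
    "summaries_frame",
    "summarize_replicates",
    "replicate_r2",
    "filter_above_background",
    "background_threshold",
]


class MixtureFitError(ValueError):
    """Degenerate or failed mixture fit (flagged, never silently zeroed)."""


@dataclass
class MixtureFit:
    """Result of one Gaussian+uniform EM fit."""

    mean: float
    variance: float
    outlier_weight: float
    n: int
    n_iter: int
    converged: bool
    loglik: float
    loglik_trajectory: "np.ndarray | None" = None


def _check_events(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("event values must be one-dimensional")
    if x.size < 10:
        raise ValueError("need at least 10 events for a mixture fit")
    if not np.all(np.isfinite(x)):
        raise ValueError("event values must be finite")
    return x


def fit_gaussian_uniform_mixture(
    values,
    max_iter: int = 500,
    tol: float = 1e-8,
    keep_trajectory: bool = False,
) -> MixtureFit:
    """EM fit of a Gaussian bulk plus uniform outliers to one event set.

    The uniform support is fixed to [min, max] of the observed events so the
    likelihood is bounded. Initialization is robust: Gaussian mean from the
    median, variance from (1.4826 * MAD)^2, outlier weight 0.05. Convergence
    is declared when successive log-likelihoods differ by less than ``tol``.

    Raises :class:`MixtureFitError` on all-identical values or when the
    fitted Gaussian variance collapses below 1e-12.
    """
    x = _check_events(values)
    res = fit_mixture_batch(
        x[None, :], max_iter=max_iter, tol=tol, keep_trajectory=keep_trajectory
    )
    traj = res["loglik_trajectory"][0] if keep_trajectory else None
    return MixtureFit(
        mean=float(res["mean"][0]),
        variance=float(res["variance"][0]),
        outlier_weight=float(res["outlier_weight"][0]),
        n=x.size,
        n_iter=int(res["n_iter"][0]),
        converged=bool(res["converged"][0]),
        loglik=float(res["loglik"][0]),
        loglik_trajectory=traj,
    )


def fit_mixture_batch(
    X,
    max_iter: int = 500,
    tol: float = 1e-8,
    keep_trajectory: bool = False,
) -> dict[str, np.ndarray]:
    """Vectorized Gaussian+uniform EM over a (n_sets, n_events) array.

    All sets share the event count; each set has its own parameters and its
    own fixed uniform support. Sets are dropped from the update as soon as
    their log-likelihood increment falls below ``tol`` (EM is monotone, so
    parameters of converged sets are final).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (n_sets, n_events)")
    n_sets, n = X.shape
    if n < 10:
        raise ValueError("need at least 10 events per set")
    if not np.all(np.isfinite(X)):
        raise ValueError("event values must be finite")

    lo = X.min(axis=1)
    hi = X.max(axis=1)
    if np.any(hi == lo):
        bad = int(np.flatnonzero(hi == lo)[0])
        raise MixtureFitError(f"all events identical in set {bad}")
    log_u = -np.log(hi - lo)

    med = np.median(X, axis=1)
    mad = np.median(np.abs(X - med[:, None]), axis=1)
    mu = med.copy()
    var = np.maximum((1.4826 * mad) ** 2, 1e-10)
    w = np.full(n_sets, 0.05)

    ll = np.full(n_sets, -np.inf)
    n_iter = np.zeros(n_sets, dtype=int)
    converged = np.zeros(n_sets, dtype=bool)
    active = np.arange(n_sets)
    traj: list[list[float]] | None = [[] for _ in range(n_sets)] if keep_trajectory else None

    for it in range(max_iter):
        Xa = X[active]
        mu_a, var_a, w_a = mu[active], var[active], w[active]
        d = Xa - mu_a[:, None]
        log_phi = -0.5 * (d * d) / var_a[:, None] - 0.5 * (
            np.log(var_a)[:, None] + _LOG_2PI
        )
        c_out = w_a[:, None] * np.exp(log_u[active])[:, None]
        c_in = (1.0 - w_a)[:, None] * np.exp(log_phi)
        denom = c_in + c_out
        ll_new = np.log(denom).sum(axis=1)
        r_in = c_in / denom

        sw = r_in.sum(axis=1)
        mu_new = (r_in * Xa).sum(axis=1) / sw
        d2 = Xa - mu_new[:, None]
        var_new = (r_in * d2 * d2).sum(axis=1) / sw
        w_new = 1.0 - sw / n

        mu[active], var[active], w[active] = mu_new, var_new, w_new
        n_iter[active] = it + 1
        if traj is not None:
            for j, s in enumerate(active):
                traj[s].append(float(ll_new[j]))

        done = np.abs(ll_new - ll[active]) < tol
        ll[active] = ll_new
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    if np.any(var < 1e-12):
        bad = int(np.flatnonzero(var < 1e-12)[0])
        raise MixtureFitError(
            f"degenerate Gaussian variance ({var[bad]:.3e}) in set {bad}"
        )
    out = {
        "mean": mu,
        "variance": var,
        "outlier_weight": w,
        "n_iter": n_iter,
        "converged": converged,
        "loglik": ll,
    }
    if keep_trajectory:
        out["loglik_trajectory"] = [np.asarray(t) for t in traj]
    return out


def summaries_frame(
    promoter_ids,
    condition_id: str,
    fit: dict[str, np.ndarray],
    n_events: int,
    replicate_id: str = "r1",
) -> pd.DataFrame:
    """Tidy per-replicate summary rows from a batched fit."""
    return pd.DataFrame(
        {
            "promoter_id": list(promoter_ids),
            "condition_id": condition_id,
            "replicate_id": replicate_id,
            "mean": fit["mean"],
            "variance": fit["variance"],
            "outlier_weight": fit["outlier_weight"],
            "n_used": int(n_events),
            "converged": fit["converged"],
        }
    )


def summarize_replicates(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pool per-replicate summaries into one row per promoter x condition.

    Means and variances are averaged across replicates; standard errors are
    the between-replicate sample SD divided by sqrt(k). With a single
    replicate the value passes through and the SE fields are NaN
    (unavailable), never zero.
    """
    if summaries.empty:
        raise ValueError("no summaries to pool")

    def _pool(g: pd.DataFrame) -> pd.Series:
        k = len(g)
        out = {
            "mean": g["mean"].mean(),
            "variance": g["variance"].mean(),
            "outlier_weight": g["outlier_weight"].mean(),
            "n_replicates": k,
            "n_used": g["n_used"].sum(),
        }
        if k >= 2:
            out["se_mean"] = g["mean"].std(ddof=1) / np.sqrt(k)
            out["se_variance"] = g["variance"].std(ddof=1) / np.sqrt(k)
        else:
            out["se_mean"] = np.nan
            out["se_variance"] = np.nan
        return pd.Series(out)

    pooled = (
        summaries.groupby(["promoter_id", "condition_id"], sort=True)
        .apply(_pool, include_groups=False)
        .reset_index()
    )
    pooled["n_replicates"] = pooled["n_replicates"].astype(int)
    pooled["n_used"] = pooled["n_used"].astype(int)
    return pooled


def replicate_r2(
    rep_a: pd.DataFrame, rep_b: pd.DataFrame, field: str = "mean"
) -> float:
    """Squared Pearson correlation of a summary field between two replicates.

    Promoters are matched by id; at least 3 shared promoters are required.
    """
    if field not in ("mean", "variance"):
        raise ValueError("field must be 'mean' or 'variance'")
    a = rep_a.set_index("promoter_id")[field]
    b = rep_b.set_index("promoter_id")[field]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared promoters")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to replicate_r2")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def background_threshold(control_values, q: float = 0.975) -> float:
    """Background level from a negative-control event set (default 97.5th pct)."""
    return float(np.quantile(np.asarray(control_values, dtype=float), q))


def filter_above_background(
    summaries: pd.DataFrame, background_mean: float
) -> pd.DataFrame:
    """Keep summaries whose mean exceeds the background level; log the rest."""
    keep = summaries["mean"] > background_mean
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "filter_above_background: removed %d of %d summaries at background %.4g",
            n_removed, len(summaries), background_mean,
        )
    return summaries.loc[keep].copy()
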