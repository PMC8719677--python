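"""Minimal-variance envelope, noise levels, and the floor's growth-rate trend.

Across a promoter library, the variance of log-fluorescence shows a clear
lower bound as a function of mean expression: a condition-specific
"extrinsic" floor ``a_c`` plus a Poissonian measurement term that decays
with the mean, ``v_min(m) = a_c + b_c * exp(-m)``. The noise level of a
promoter is the part of its variance above that envelope,
``N_pc = v_pc - v_min(m_pc)`` — a mean-independent measure that can be
compared across promoters and conditions.

The envelope is fit by taking a low quantile of the variance within
equal-count bins of the mean and least-squares fitting (a_c, b_c) to those
envelope points under non-negativity constraints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseFloorFit",
    "minimal_variance",
    "fit_noise_floor",
    "noise_level",
    "noise_matrix",
    "floor_vs_growth_rate",
    "noise_distribution_tests",
]


@dataclass
class NoiseFloorFit:
    """Per-condition floor parameters and fit diagnostics."""

    condition_id: str
    a_c: float              # variance of log-fluorescence; extrinsic floor
    b_c: float              # Poissonian (measurement) term magnitude
    quantile: float
    n_bins: int
    n_points: int

    def __post_init__(self) -> None:
        if not self.a_c > 0:
            raise ValueError(f"a_c must be positive (got {self.a_c})")
        if self.b_c < 0:
            raise ValueError("b_c must be non-negative")


def minimal_variance(m, fit: "NoiseFloorFit | tuple[float, float]"):
    """Envelope value v_min(m) = a_c + b_c * exp(-m); decreasing in m, -> a_c."""
    if isinstance(fit, NoiseFloorFit):
        a, b = fit.a_c, fit.b_c
    else:
        a, b = fit
    return a + b * np.exp(-np.asarray(m, dtype=float))


def fit_noise_floor(
    summaries: pd.DataFrame,
    condition_id: str | None = None,
    q: float = 0.05,
    n_bins: int = 20,
    method: str = "quantreg",
) -> NoiseFloorFit:
    """Fit the minimal-variance envelope for one condition.

    The default method regresses the variance on [1, exp(-m)] at quantile
    level ``q`` (linear quantile regression, pinball loss): the fitted
    ``q``-quantile curve is the envelope, with coefficients clipped at
    non-negativity. Because the sampling scatter of a variance estimate is
    itself proportional to the variance (SE ~ v * sqrt(2/n)), the downward
    shift that a low quantile applies has the same shape as the envelope
    and is absorbed into (a_c, b_c) rather than distorting the curve, which
    keeps the resulting noise levels mean-independent.

    ``method="binned"`` instead sorts promoters by mean into ``n_bins``
    equal-count bins, takes the ``q``-quantile of the variance per bin, and
    fits (a_c, b_c) to the envelope points by non-negative least squares;
    bins are merged (with a warning) when they would hold fewer than 5
    promoters.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if condition_id is None:
        ids = summaries["condition_id"].unique()
        if len(ids) != 1:
            raise ValueError("summaries span several conditions; pass condition_id")
        condition_id = str(ids[0])
    else:
        summaries = summaries[summaries["condition_id"] == condition_id]
    m = summaries["mean"].to_numpy(dtype=float)
    v = summaries["variance"].to_numpy(dtype=float)
    if m.size < 50:
        raise ValueError("need at least 50 promoters above background")

    u = np.exp(-m)
    if method == "quantreg":
        import statsmodels.api as sm

        design = np.column_stack([np.ones_like(u), u])
        res = sm.QuantReg(v, design).fit(q=q, max_iter=5000)
        coef = np.maximum(np.asarray(res.params), 0.0)
    elif method == "binned":
        if m.size // n_bins < 5:
            n_bins_new = max(1, m.size // 5)
            warnings.warn(
                f"fewer than 5 promoters per bin; merging {n_bins} -> {n_bins_new} bins"
            )
            n_bins = n_bins_new
        order = np.argsort(m, kind="stable")
        u_env, v_env = [], []
        for idx in np.array_split(order, n_bins):
            u_env.append(np.median(u[idx]))
            v_env.append(np.quantile(v[idx], q))
        design = np.column_stack([np.ones(len(u_env)), np.asarray(u_env)])
        coef, _ = optimize.nnls(design, np.asarray(v_env))
    else:
        raise ValueError("method must be 'quantreg' or 'binned'")

    a_c, b_c = float(coef[0]), float(coef[1])
    if a_c <= 0:
        raise RuntimeError(
            f"noise-floor fit failed for {condition_id}: non-positive a_c"
        )
    return NoiseFloorFit(
        condition_id=condition_id,
        a_c=a_c,
        b_c=b_c,
        quantile=q,
        n_bins=n_bins,
        n_points=int(m.size),
    )


def noise_level(summaries: pd.DataFrame, fit: NoiseFloorFit) -> pd.Series:
    """N_pc = v_pc - v_min(m_pc) for each summary row (not clipped at zero)."""
    return summaries["variance"] - minimal_variance(
        summaries["mean"].to_numpy(), fit
    )


def noise_matrix(
    summaries: pd.DataFrame, fits: "dict[str, NoiseFloorFit] | list[NoiseFloorFit]"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoters x conditions noise levels plus per-cell standard errors.

    Standard errors are propagated directly from ``se_variance`` (the floor
    is treated as fixed); cells without replicate information are NaN.
    Returns (N, se) DataFrames indexed by promoter id.
    """
    if not isinstance(fits, dict):
        fits = {f.condition_id: f for f in fits}
    parts = []
    for cond, grp in summaries.groupby("condition_id", sort=True):
        fit = fits[str(cond)]
        part = grp[["promoter_id"]].copy()
        part["condition_id"] = cond
        part["noise"] = noise_level(grp, fit).to_numpy()
        part["se"] = grp["se_variance"].to_numpy() if "se_variance" in grp else np.nan
        parts.append(part)
    tidy = pd.concat(parts, ignore_index=True)
    N = tidy.pivot(index="promoter_id", columns="condition_id", values="noise")
    se = tidy.pivot(index="promoter_id", columns="condition_id", values="se")
    N.columns.name = None
    se.columns.name = None
    return N, se


def floor_vs_growth_rate(
    fits: "list[NoiseFloorFit]", growth_rates
) -> dict[str, float]:
    """OLS of the noise floor a_c on growth rate; returns slope, intercept, R^2."""
    a = np.asarray([f.a_c for f in fits], dtype=float)
    rates = np.asarray(growth_rates, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 conditions")
    if a.size == 2:
        warnings.warn("two points: R^2 is 1 by construction")
    if np.ptp(rates) == 0:
        raise ValueError("growth rates are constant")
    res = stats.linregress(rates, a)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "slope_se": float(res.stderr),
        "intercept_se": float(res.intercept_stderr),
    }


def noise_distribution_tests(
    noise_a, noise_b
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum comparison of noise levels between conditions."""
    x = np.asarray(noise_a, dtype=float)
    y = np.asarray(noise_b, dtype=float)
    if x.size < 10 or y.size < 10:
        raise ValueError("need at least 10 promoters per condition")
    stat, p = stats.ranksums(x, y)
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "median_a": float(np.median(x)),
        "median_b": float(np.median(y)),
    }
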