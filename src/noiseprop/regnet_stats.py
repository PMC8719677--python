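"""Statistics linking noise to regulatory inputs.

Plasticity is the variance of a promoter's mean expression (expression
plasticity) or noise level (noise plasticity) across conditions. The
operations here test the signatures of noise propagation: noisier promoters
have more known regulatory inputs (cutoff curves and Welch t-statistics),
high-noise promoters are mostly regulated (fraction-regulated curve), and
noise plasticity grows with the number of inputs (group ECDFs and tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

__all__ = [
    "compute_plasticities",
    "inputs_above_cutoff_curve",
    "fraction_regulated_curve",
    "cutoff_t_statistics",
    "plasticity_by_input_group",
    "constitutive_vs_regulated_comparison",
]


def compute_plasticities(
    means: pd.DataFrame, noise: pd.DataFrame, network: pd.DataFrame
) -> pd.DataFrame:
    """Per-promoter plasticities, mean noise, and regulatory input counts.

    ``means`` and ``noise`` are promoters x conditions; variances use
    denominator C-1. Promoters absent from the network annotation count as
    having zero known inputs.
    """
    if means.shape[1] < 2 or noise.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    idx = means.index.intersection(noise.index)
    n_inputs = network.reindex(idx).fillna(0).sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "promoter_id": idx,
            "expression_plasticity": means.loc[idx].var(axis=1, ddof=1).to_numpy(),
            "noise_plasticity": noise.loc[idx].var(axis=1, ddof=1).to_numpy(),
            "mean_noise": noise.loc[idx].mean(axis=1).to_numpy(),
            "mean_expression": means.loc[idx].mean(axis=1).to_numpy(),
            "n_inputs": n_inputs.to_numpy(),
        }
    ).reset_index(drop=True)


def _cutoff_grid(values: np.ndarray) -> np.ndarray:
    return np.unique(values)


def inputs_above_cutoff_curve(
    table: pd.DataFrame, min_group: int = 10
) -> pd.DataFrame:
    """Mean (+SE) number of known inputs among promoters with mean noise >= cutoff.

    The cutoff grid is every observed distinct mean noise value; the curve
    is truncated where fewer than ``min_group`` promoters remain.
    """
    if len(table) < 20:
        raise ValueError("need at least 20 promoters")
    nbar = table["mean_noise"].to_numpy()
    k = table["n_inputs"].to_numpy(dtype=float)
    order = np.argsort(nbar, kind="stable")
    nbar_s, k_s = nbar[order], k[order]
    rows = []
    for cutoff in _cutoff_grid(nbar):
        i = np.searchsorted(nbar_s, cutoff, side="left")
        sel = k_s[i:]
        if sel.size < min_group:
            break
        rows.append(
            {
                "cutoff": cutoff,
                "mean_inputs": sel.mean(),
                "se": sel.std(ddof=1) / np.sqrt(sel.size),
                "n": sel.size,
            }
        )
    return pd.DataFrame(rows)


def fraction_regulated_curve(
    table: pd.DataFrame, min_group: int = 10
) -> pd.DataFrame:
    """Fraction (+binomial SE) of promoters with >=1 input above each noise cutoff."""
    if len(table) < 20:
        raise ValueError("need at least 20 promoters")
    nbar = table["mean_noise"].to_numpy()
    reg = (table["n_inputs"].to_numpy() >= 1).astype(float)
    order = np.argsort(nbar, kind="stable")
    nbar_s, reg_s = nbar[order], reg[order]
    rows = []
    for cutoff in _cutoff_grid(nbar):
        i = np.searchsorted(nbar_s, cutoff, side="left")
        sel = reg_s[i:]
        if sel.size < min_group:
            break
        p = sel.mean()
        rows.append(
            {
                "cutoff": cutoff,
                "fraction_regulated": p,
                "se": np.sqrt(p * (1 - p) / sel.size),
                "n": sel.size,
            }
        )
    return pd.DataFrame(rows)


def cutoff_t_statistics(
    n_inputs, noise_values, min_group: int = 10
) -> pd.DataFrame:
    """Welch t of input counts, promoters above vs below each noise cutoff.

    ``noise_values`` may be one condition's noise levels or the
    condition-averaged noise; cutoffs with an undersized group are omitted.
    """
    k = np.asarray(n_inputs, dtype=float)
    n = np.asarray(noise_values, dtype=float)
    rows = []
    for cutoff in _cutoff_grid(n):
        above = k[n >= cutoff]
        below = k[n < cutoff]
        if above.size < min_group or below.size < min_group:
            continue
        t, p = stats.ttest_ind(above, below, equal_var=False)
        rows.append(
            {
                "cutoff": cutoff,
                "t": float(t),
                "p_value": float(p),
                "n_above": above.size,
                "n_below": below.size,
            }
        )
    return pd.DataFrame(rows)


_GROUPS = (
    ("0", lambda k: k == 0),
    ("1-2", lambda k: (k >= 1) & (k <= 2)),
    ("3+", lambda k: k >= 3),
)


def plasticity_by_input_group(
    table: pd.DataFrame, field: str = "noise_plasticity", min_group: int = 5
) -> tuple[dict[str, ECDF], pd.DataFrame]:
    """ECDFs of noise plasticity for input-count groups {0}, {1,2}, {>=3}.

    Returns the per-group ECDFs and a table of pairwise two-sided Welch
    tests; comparisons involving a group smaller than ``min_group`` are
    omitted.
    """
    k = table["n_inputs"].to_numpy()
    vals = table[field].to_numpy(dtype=float)
    groups = {name: vals[sel(k)] for name, sel in _GROUPS}
    ecdfs = {name: ECDF(v) for name, v in groups.items() if v.size > 0}
    names = [n for n, v in groups.items() if v.size >= min_group]
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_a": groups[a].mean(),
                    "mean_b": groups[b].mean(),
                    "t": float(t),
                    "p_value": float(p),
                }
            )
    return ecdfs, pd.DataFrame(rows)


def constitutive_vs_regulated_comparison(
    constitutive: pd.DataFrame, regulated: pd.DataFrame
) -> pd.DataFrame:
    """Welch tests for expression plasticity, mean noise, and noise plasticity.

    Compares a constitutive-like promoter set against a regulated set,
    reporting group means so the direction of each effect is checkable.
    """
    if len(constitutive) < 5 or len(regulated) < 5:
        raise ValueError("need at least 5 promoters per set")
    rows = []
    for f in ("expression_plasticity", "mean_noise", "noise_plasticity"):
        a = constitutive[f].to_numpy(dtype=float)
        b = regulated[f].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "feature": f,
                "mean_constitutive": a.mean(),
                "mean_regulated": b.mean(),
                "t": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
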