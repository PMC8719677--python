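"""Inference of condition-dependent noise-propagating activities of regulators.

Noise levels of promoters are modeled as a centered linear function of their
known regulatory inputs: with ``S_pr`` the binary regulator -> promoter
annotation and ``N_pc`` the noise level of promoter ``p`` in condition ``c``,

    N_pc - Nbar_c = eps + sum_r (S_pr - Sbar_r) * A_rc,

where ``A_rc`` is the (unknown) noise-propagating activity of regulator
``r`` in condition ``c`` and ``eps`` is Gaussian. A Gaussian prior on the
activities (ridge penalty ``lambda``) keeps the fit from overfitting the
sparse annotation and yields a full posterior: the posterior mean is the
ridge solution and the error bars ``dA_rc`` are the square roots of the
diagonal of the posterior covariance with plug-in residual variance.

Activity significance follows the convention ``A_rc > dA_rc``; regulators
significant in exactly one condition are condition-specific propagators,
and regulators whose condition-averaged activity exceeds its combined error
are consistent (global) propagators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "CenteredModel",
    "ActivityEstimates",
    "center_model_inputs",
    "infer_activities",
    "select_prior_strength",
    "explained_variance",
    "randomized_fov",
    "condition_specific_propagators",
    "average_activities",
]


@dataclass
class CenteredModel:
    """Centered response (promoters x conditions) and design (promoters x regulators)."""

    X: np.ndarray
    Y: np.ndarray
    promoter_ids: list[str]
    regulator_ids: list[str]
    condition_ids: list[str]
    n_unannotated: int = 0


@dataclass
class ActivityEstimates:
    """Posterior activities, error bars, and per-condition fit diagnostics."""

    A: pd.DataFrame         # regulators x conditions
    delta_A: pd.DataFrame   # same shape, > 0
    lam: float
    sigma2: pd.Series       # residual variance per condition
    fov: pd.Series          # in-sample fraction of variance explained
    n_promoters: int
    model: CenteredModel = field(repr=False)

    @property
    def A_bar(self) -> pd.Series:
        return self.A.mean(axis=1)

    @property
    def delta_A_bar(self) -> pd.Series:
        C = self.A.shape[1]
        return np.sqrt((self.delta_A**2).sum(axis=1)) / C

    def significant(self) -> pd.DataFrame:
        """Boolean table of A_rc > dA_rc."""
        return self.A > self.delta_A


def center_model_inputs(
    N: pd.DataFrame, S: pd.DataFrame, unannotated: str = "zero"
) -> CenteredModel:
    """Align promoter ids of the noise matrix and network and center both.

    ``unannotated`` controls promoters present in N but absent from S:
    ``"zero"`` (default) keeps them as all-zero annotation rows —
    unregulated as far as known — while ``"drop"`` restricts to the
    intersection. Promoters in S without noise measurements are always
    dropped. Column means of the centered design and response are zero.
    """
    if unannotated not in ("zero", "drop"):
        raise ValueError("unannotated must be 'zero' or 'drop'")
    n_index = N.index
    if unannotated == "drop":
        keep = n_index.intersection(S.index)
        n_missing = len(n_index) - len(keep)
    else:
        keep = n_index
        n_missing = len(n_index.difference(S.index))
    if len(keep) == 0:
        raise ValueError("no promoters shared between noise matrix and network")
    if n_missing:
        logger.info(
            "center_model_inputs: %d promoters without annotation (%s)",
            n_missing, "dropped" if unannotated == "drop" else "kept as zero rows",
        )
    S_aligned = S.reindex(keep).fillna(0.0)
    N_aligned = N.loc[keep]
    X = S_aligned.to_numpy(dtype=float)
    Y = N_aligned.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    Y = Y - Y.mean(axis=0, keepdims=True)
    return CenteredModel(
        X=X,
        Y=Y,
        promoter_ids=list(keep),
        regulator_ids=list(S.columns),
        condition_ids=list(N.columns),
        n_unannotated=n_missing,
    )


def _ridge_solve(X: np.ndarray, Y: np.ndarray, lam: float):
    """Posterior mean A = (X'X + lam I)^-1 X'Y and the gram inverse diagonal."""
    R = X.shape[1]
    G = X.T @ X + lam * np.eye(R)
    if lam == 0:
        if np.linalg.matrix_rank(X) < R:
            raise np.linalg.LinAlgError(
                "singular system with lambda=0; use a positive prior strength"
            )
        cho = linalg.cho_factor(G)
    else:
        cho = linalg.cho_factor(G)
    A = linalg.cho_solve(cho, X.T @ Y)
    Ginv_diag = np.diag(linalg.cho_solve(cho, np.eye(R)))
    return A, Ginv_diag


def infer_activities(model: CenteredModel, lam: float) -> ActivityEstimates:
    """Fit all conditions of the centered model with prior strength ``lam``.

    Per condition the posterior mean is ``(X'X + lam I)^-1 X' y``; the
    residual variance ``sigma2`` is the mean squared residual and the error
    bars are ``sqrt(sigma2 * diag((X'X + lam I)^-1))``. Deterministic given
    its inputs.
    """
    if lam < 0:
        raise ValueError("prior strength lambda must be >= 0")
    X, Y = model.X, model.Y
    A, Ginv_diag = _ridge_solve(X, Y, lam)
    resid = Y - X @ A
    sigma2 = (resid**2).mean(axis=0)
    delta = np.sqrt(np.outer(Ginv_diag, sigma2))
    var_y = Y.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fov = 1.0 - (resid**2).mean(axis=0) / var_y
    fov = np.where(var_y > 0, fov, np.nan)
    conds = model.condition_ids
    regs = model.regulator_ids
    return ActivityEstimates(
        A=pd.DataFrame(A, index=regs, columns=conds),
        delta_A=pd.DataFrame(delta, index=regs, columns=conds),
        lam=float(lam),
        sigma2=pd.Series(sigma2, index=conds),
        fov=pd.Series(fov, index=conds),
        n_promoters=X.shape[0],
        model=model,
    )


def explained_variance(model: CenteredModel, A: np.ndarray) -> np.ndarray:
    """In-sample FOV per condition for given activities (true or fitted)."""
    resid = model.Y - model.X @ np.asarray(A, dtype=float)
    var_y = model.Y.var(axis=0)
    if np.any(var_y == 0):
        raise ValueError("zero response variance; FOV undefined")
    return 1.0 - (resid**2).mean(axis=0) / var_y


def select_prior_strength(
    N: pd.DataFrame,
    S: pd.DataFrame,
    lambda_grid,
    k_folds: int = 10,
    seed: int = 0,
    unannotated: str = "zero",
) -> tuple[float, pd.DataFrame]:
    """Promoter-wise k-fold cross-validation of the prior strength.

    For each candidate lambda, promoters are split into folds; the model is
    fit on the training promoters (centering on the training set) and the
    out-of-fold fraction of explained variance is accumulated per condition.
    Returns the lambda maximizing the mean out-of-fold FOV across
    conditions (ties -> smallest lambda) plus the full CV table.
    """
    grid = np.asarray(sorted(lambda_grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("lambda_grid must be nonempty and positive")
    base = center_model_inputs(N, S, unannotated=unannotated)
    X0 = base.X + base.X.mean(axis=0, keepdims=True)  # uncentered copies
    Y0 = base.Y + base.Y.mean(axis=0, keepdims=True)
    n = X0.shape[0]
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    press = np.zeros((grid.size, Y0.shape[1]))  # residual SS out-of-fold
    sstot = np.zeros_like(press)
    for train, test in kf.split(np.arange(n)):
        xm = X0[train].mean(axis=0, keepdims=True)
        ym = Y0[train].mean(axis=0, keepdims=True)
        Xtr, Ytr = X0[train] - xm, Y0[train] - ym
        Xte, Yte = X0[test] - xm, Y0[test] - ym
        for i, lam in enumerate(grid):
            A, _ = _ridge_solve(Xtr, Ytr, lam)
            resid = Yte - Xte @ A
            press[i] += (resid**2).sum(axis=0)
            sstot[i] += (Yte**2).sum(axis=0)
    fov = 1.0 - press / sstot
    mean_fov = fov.mean(axis=1)
    best = int(np.argmax(mean_fov))  # argmax returns first (smallest) on ties
    table = pd.DataFrame(fov, index=grid, columns=list(N.columns))
    table.index.name = "lambda"
    table["mean_fov"] = mean_fov
    return float(grid[best]), table


def randomized_fov(
    N: pd.DataFrame,
    S: pd.DataFrame,
    n_shuffles: int,
    lam: float,
    seed: int,
    unannotated: str = "zero",
) -> pd.DataFrame:
    """Permutation null for the explained variance.

    Whole promoter rows of the noise matrix are shuffled jointly across
    conditions (preserving each promoter's cross-condition noise profile
    while breaking its association with the annotation), the model is refit
    and the in-sample FOV recorded. Returns per-condition mean, sd and
    se (= sd / sqrt(n_shuffles)) of the null FOV.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    rng = np.random.default_rng(seed)
    model = center_model_inputs(N, S, unannotated=unannotated)
    X, Y = model.X, model.Y
    R = X.shape[1]
    cho = linalg.cho_factor(X.T @ X + lam * np.eye(R))
    fovs = np.empty((n_shuffles, Y.shape[1]))
    var_y = Y.var(axis=0)
    for s in range(n_shuffles):
        perm = rng.permutation(Y.shape[0])
        Yp = Y[perm]
        A = linalg.cho_solve(cho, X.T @ Yp)
        resid = Yp - X @ A
        fovs[s] = 1.0 - (resid**2).mean(axis=0) / var_y
    out = pd.DataFrame(
        {
            "condition_id": model.condition_ids,
            "fov_mean": fovs.mean(axis=0),
            "fov_sd": fovs.std(axis=0, ddof=1),
        }
    )
    out["fov_se"] = out["fov_sd"] / np.sqrt(n_shuffles)
    return out


def condition_specific_propagators(
    est: ActivityEstimates,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Regulators significant (A_rc > dA_rc) in exactly one condition.

    Returns a table of condition-specific propagators (regulator, condition,
    activity, error) plus the per-condition significant lists.
    """
    sig = est.significant()
    per_condition = {
        str(c): list(sig.index[sig[c]]) for c in sig.columns
    }
    n_sig = sig.sum(axis=1)
    rows = []
    for r in sig.index[n_sig == 1]:
        c = sig.columns[sig.loc[r]][0]
        rows.append(
            {
                "regulator_id": r,
                "condition_id": c,
                "activity": est.A.loc[r, c],
                "delta": est.delta_A.loc[r, c],
            }
        )
    table = pd.DataFrame(rows, columns=["regulator_id", "condition_id", "activity", "delta"])
    return table, per_condition


def average_activities(est: ActivityEstimates, top_k: int = 6) -> pd.DataFrame:
    """Condition-averaged activities ranked by significance.

    Abar_r is the mean activity over conditions and dAbar_r combines the
    per-condition error bars assuming independence
    (sqrt(sum dA^2) / C). Regulators with Abar_r > dAbar_r are ranked by
    |Abar_r / dAbar_r| descending; the ``top_k`` strongest consistent
    propagators are flagged.
    """
    abar = est.A_bar
    dbar = est.delta_A_bar
    table = pd.DataFrame(
        {
            "regulator_id": abar.index,
            "A_bar": abar.to_numpy(),
            "delta_A_bar": dbar.to_numpy(),
        }
    )
    table["z"] = np.abs(table["A_bar"] / table["delta_A_bar"])
    table = table[table["A_bar"] > table["delta_A_bar"]]
    table = table.sort_values("z", ascending=False, kind="stable").reset_index(drop=True)
    table["top"] = np.arange(len(table)) < top_k
    return table
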