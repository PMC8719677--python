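"""Correlation structure and PCA of the 10-gene-feature table.

The canonical feature set combines literature-style features (RNA and
protein levels, codon bias, evolutionary rates dN and dS, number of
regulatory inputs) with features measured by this pipeline (mean expression,
expression plasticity, mean noise, noise plasticity). Pairwise-complete
Pearson correlations between the 10 features form a matrix R whose
eigendecomposition organizes genes along a small number of axes — an
absolute-expression axis and a regulation/noise axis in the data this
package emulates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CANONICAL_FEATURES = [
    "rna_level",
    "protein_level",
    "codon_bias",
    "dN",
    "dS",
    "n_inputs",
    "mean_expression",
    "expression_plasticity",
    "mean_noise",
    "noise_plasticity",
]

__all__ = [
    "CANONICAL_FEATURES",
    "correlation_matrix",
    "pca_of_correlation",
    "component_contributions",
    "nearest_psd",
]


def correlation_matrix(
    features: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations and the pair counts per cell.

    Missing values are allowed; every feature pair must retain at least
    ``min_pairs`` complete observations. A feature with zero variance is
    rejected by name.
    """
    cols = [c for c in features.columns if c != "gene_id" and c != "promoter_id"]
    X = features[cols]
    for c in cols:
        v = X[c].dropna()
        if v.size < 2 or float(np.var(v)) == 0.0:
            raise ValueError(f"feature '{c}' has zero variance")
    notna = X.notna().astype(int).to_numpy()
    n_pairs = pd.DataFrame(notna.T @ notna, index=cols, columns=cols)
    if (n_pairs.to_numpy() < min_pairs).any():
        raise ValueError(f"some feature pairs have fewer than {min_pairs} complete rows")
    R = X.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(R.to_numpy(), 1.0)
    return R, n_pairs


def nearest_psd(R: pd.DataFrame) -> pd.DataFrame:
    """Nearest positive-semidefinite repair: clip eigenvalues, restore unit diagonal."""
    vals, vecs = np.linalg.eigh(R.to_numpy())
    vals = np.clip(vals, 0.0, None)
    M = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    np.fill_diagonal(M, 1.0)
    return pd.DataFrame(M, index=R.index, columns=R.columns)


def pca_of_correlation(
    R: pd.DataFrame, repair: bool = False
) -> tuple[np.ndarray, pd.DataFrame]:
    """Eigendecomposition of the feature correlation matrix.

    Returns (eigenvalues, loadings) with eigenvalues sorted descending;
    the variance fraction of component i is eigenvalue_i / n_features.
    Loadings columns are named PC1.. and sign-fixed so the largest-magnitude
    loading of each component is positive.

    Pairwise-complete estimation can produce an indefinite matrix; negative
    eigenvalues below -1e-8 raise unless ``repair=True`` applies a
    nearest-PSD correction first.
    """
    M = R.to_numpy(dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    vals = np.linalg.eigvalsh(M)
    if vals.min() < -1e-8:
        if not repair:
            raise ValueError(
                "correlation matrix is indefinite (pairwise-complete artifact); "
                "rerun with repair=True for a nearest-PSD correction"
            )
        R = nearest_psd(R)
        M = R.to_numpy()
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    loadings = pd.DataFrame(
        vecs, index=R.index, columns=[f"PC{j + 1}" for j in range(vecs.shape[1])]
    )
    return vals, loadings


def component_contributions(
    loadings: pd.DataFrame, component: int = 1, subset: "list[str] | None" = None
) -> tuple[pd.Series, float]:
    """Relative contributions |loading| / sum|loading| of one component.

    Returns the per-feature contribution shares (summing to 1) and the
    cumulative share of the named feature subset (0 if none given).
    """
    col = f"PC{component}"
    if col not in loadings.columns:
        raise ValueError(f"no component {component}")
    w = loadings[col].abs()
    contrib = w / w.sum()
    share = float(contrib.loc[list(subset)].sum()) if subset else 0.0
    return contrib, share
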