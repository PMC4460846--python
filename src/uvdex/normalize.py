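"""Gene-wise standardization, PCA, and removal of unwanted components.

In designed expression experiments run on live animals, the dominant
principal components of the (gene-standardized) matrix typically capture
unwanted variation -- individual variability, batch, circadian time --
rather than the treatment.  The workflow here is: standardize each gene,
decompose with an SVD, inspect per-component variance fractions, and
subtract the leading components before differential expression.

Orientation convention: genes are the observations.  ``gene_scores`` (genes x
components) carry the per-gene weights, ``sample_loadings`` (samples x
components, orthonormal) the per-sample weights, so that

    X  =  gene_scores @ sample_loadings.T
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DesignError
from .matrix import ExpressionMatrix


@dataclass
class PcaModel:
    """SVD decomposition of a standardized expression matrix.

    ``variance_fractions[i] = s_i**2 / sum_j s_j**2`` where ``s`` are the
    singular values.  Components carry a deterministic sign: the
    largest-magnitude sample loading of each component is positive.
    """

    gene_scores: pd.DataFrame       # genes x components (U * s)
    sample_loadings: pd.DataFrame   # samples x components, orthonormal
    singular_values: np.ndarray     # non-negative, non-increasing
    variance_fractions: np.ndarray

    def __post_init__(self):
        s = self.singular_values
        if (s < -1e-12).any() or (np.diff(s) > 1e-9 * max(s[0], 1.0)).any():
            raise DataError("singular values must be non-negative, non-increasing")
        v = self.variance_fractions
        if ((v < 0) | (v > 1)).any() or v.sum() > 1 + 1e-8:
            raise DataError("variance fractions must lie in [0,1] and sum to <= 1")

    @property
    def n_components(self) -> int:
        return len(self.singular_values)


def standardize_genes(X: ExpressionMatrix, scale: bool = False) -> ExpressionMatrix:
    """Center each gene at zero mean; optionally scale to unit sample sd.

    Zero-variance genes are left at 0 and flagged in
    ``zero_variance_genes`` of the returned matrix.
    """
    if X.n_samples < 2:
        raise DesignError("standardization requires at least 2 samples")
    vals = X.values
    centered = vals.sub(vals.mean(axis=1), axis=0)
    sd = vals.std(axis=1, ddof=1)
    zero = sd.to_numpy() == 0
    if scale:
        centered = centered.div(sd.where(sd > 0, 1.0), axis=0)
    flagged = tuple(vals.index[zero])
    return X.with_values(centered, zero_variance_genes=flagged)


def compute_pca(X: ExpressionMatrix) -> PcaModel:
    """Thin SVD of the standardized matrix.

    Warns if gene means are not (numerically) zero, since variance fractions
    are only interpretable on a centered matrix.
    """
    A = X.values.to_numpy(dtype=float)
    if not np.isfinite(A).all():
        raise DataError("matrix contains non-finite values")
    scale = max(float(np.abs(A).max()), 1.0)
    if np.abs(A.mean(axis=1)).max() > 1e-6 * scale:
        warnings.warn(
            "matrix rows are not centered; run standardize_genes first",
            stacklevel=2,
        )
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    V = Vt.T
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    total = float((s ** 2).sum())
    fractions = (s ** 2) / total if total > 0 else np.zeros_like(s)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PcaModel(
        gene_scores=pd.DataFrame(U * s, index=X.gene_ids, columns=comp),
        sample_loadings=pd.DataFrame(V, index=X.sample_ids, columns=comp),
        singular_values=s,
        variance_fractions=fractions,
    )


def remove_components(X: ExpressionMatrix, model: PcaModel, k: int) -> ExpressionMatrix:
    """Project out the top-``k`` components: X - (X L_k) L_k^T.

    On the matrix the model was fitted to, X L_k equals the model's gene
    scores, so this is exactly X - sum_{i<=k} score_i loading_i^T; as a
    projection it is idempotent on any input and the residual is exactly
    orthogonal to the removed sample loadings.  ``k = 0`` returns the input
    unchanged.
    """
    if not 0 <= k <= model.n_components:
        raise ValueError(f"k must be in [0, {model.n_components}], got {k}")
    if k == 0:
        return X.with_values(X.values.copy(),
                             zero_variance_genes=X.zero_variance_genes)
    A = X.values.to_numpy(dtype=float)
    L = model.sample_loadings.to_numpy()[:, :k]
    resid = A - (A @ L) @ L.T
    return X.with_values(
        pd.DataFrame(resid, index=X.gene_ids, columns=X.sample_ids),
        zero_variance_genes=X.zero_variance_genes,
    )


def correlated_pc_module(
    model: PcaModel, pc_a: int, pc_b: int, top_fraction: float
) -> set:
    """Genes driving two components jointly (a correlated score module).

    Ranks genes by |score_a * score_b|, restricted to the dominant sign of
    the score product (i.e. the dominant quadrant pair of the score
    scatter), and returns the top ``ceil(top_fraction * n_genes)`` of them.
    Components are 0-based indices into the model.
    """
    if pc_a == pc_b:
        raise ValueError("pc_a and pc_b must differ")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    scores = model.gene_scores.to_numpy()
    n_comp = scores.shape[1]
    if not (0 <= pc_a < n_comp and 0 <= pc_b < n_comp):
        raise ValueError("component index out of range")
    prod = scores[:, pc_a] * scores[:, pc_b]
    if not np.any(prod):
        return set()
    k = math.ceil(top_fraction * len(prod))
    # dominant quadrant pair: judged on the strongest score products
    top = np.argsort(-np.abs(prod), kind="stable")[:k]
    dominant = 1.0 if prod[top].sum() >= 0 else -1.0
    idx = np.flatnonzero(dominant * prod > 0)
    order = idx[np.argsort(-np.abs(prod[idx]), kind="stable")]
    return set(model.gene_scores.index[order[:k]])


def pca_report(model: PcaModel) -> pd.DataFrame:
    """Tidy per-component summary (singular value, variance fraction)."""
    return pd.DataFrame(
        {
            "component": model.gene_scores.columns,
            "singular_value": model.singular_values,
            "variance_fraction": model.variance_fractions,
        }
    )
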