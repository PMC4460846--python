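"""Genome-wide clustering of per-condition average expression profiles.

Average-linkage agglomeration on correlation distance (1 - r) between the
condition columns of a standardized matrix.  Centered (Pearson) correlation
is the default metric; uncentered (cosine) is available.  A companion
replicate-level silhouette helper quantifies that individual replicates do
not separate by condition when unwanted variance dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import DesignError
from .matrix import ExpressionMatrix

MAX_CORRELATION_DISTANCE = 2.0


def condition_means(X: ExpressionMatrix, conditions=None) -> pd.DataFrame:
    """Per-gene arithmetic mean over each condition's replicates.

    Column order follows the design (first appearance) unless ``conditions``
    is given explicitly.
    """
    conditions = list(conditions) if conditions is not None else X.groups
    cols = {}
    for cond in conditions:
        ids = X.group_samples(cond)
        if not ids:
            raise DesignError(f"condition {cond!r} has no samples")
        cols[cond] = X.values[ids].mean(axis=1)
    return pd.DataFrame(cols, index=X.gene_ids)


def _correlation_distance(P: pd.DataFrame, metric: str):
    """Full distance matrix 1 - correlation between columns; flags degenerate
    (zero-variance) columns, whose distances are set to the maximum."""
    A = P.to_numpy(dtype=float)
    flagged = []
    if metric == "centered":
        sd = A.std(axis=0)
        zero = sd == 0
        flagged = list(P.columns[zero])
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(A, rowvar=False)
        D = 1.0 - R
        D[zero, :] = MAX_CORRELATION_DISTANCE
        D[:, zero] = MAX_CORRELATION_DISTANCE
    elif metric == "uncentered":
        norms = np.linalg.norm(A, axis=0)
        zero = norms == 0
        flagged = list(P.columns[zero])
        safe = np.where(zero, 1.0, norms)
        R = (A.T @ A) / np.outer(safe, safe)
        D = 1.0 - R
        D[zero, :] = MAX_CORRELATION_DISTANCE
        D[:, zero] = MAX_CORRELATION_DISTANCE
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    D = np.clip(0.5 * (D + D.T), 0.0, None)  # symmetrize tiny float noise
    return D, flagged


@dataclass
class DendrogramResult:
    """Average-linkage merge structure over condition profiles."""

    labels: list
    linkage: np.ndarray      # scipy linkage matrix
    flagged_columns: list

    def merge_table(self) -> pd.DataFrame:
        """Tidy merge list: step, left, right, height.

        Leaves are named by their condition label; internal clusters by the
        step that created them (``C1``, ``C2``, ...).
        """
        n = len(self.labels)

        def name(i):
            i = int(i)
            return self.labels[i] if i < n else f"C{i - n + 1}"

        rows = [
            (s + 1, name(a), name(b), float(h))
            for s, (a, b, h, _) in enumerate(self.linkage)
        ]
        return pd.DataFrame(rows, columns=["step", "left", "right", "height"])

    def merges_as_pair(self, label_a: str, label_b: str) -> bool:
        """True if the two leaves merge directly with each other (i.e. they
        are mutual nearest neighbours under the linkage)."""
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        for a, b, _, _ in self.linkage:
            if {int(a), int(b)} == {i, j}:
                return True
        return False

    def to_newick(self) -> str:
        """Render the dendrogram as a Newick string with branch lengths."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: _quote_newick(self.labels[i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            idx = n + step
            nodes[idx] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[idx] = h
        return nodes[n + len(self.linkage) - 1] + ";"


def _quote_newick(label: str) -> str:
    import re

    if re.fullmatch(r"[A-Za-z0-9_.\-]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def cluster_conditions(
    P: pd.DataFrame, metric: str = "centered"
) -> DendrogramResult:
    """Average-linkage hierarchical clustering of condition profiles.

    Distance is 1 - correlation between condition columns; ties break
    deterministically by input order (scipy linkage is deterministic for a
    fixed condensed distance ordering); merge heights are non-decreasing
    (average linkage admits no inversions).
    """
    if P.shape[1] < 3:
        raise DesignError("clustering requires at least 3 conditions")
    if not np.isfinite(P.to_numpy()).all():
        raise DesignError("profiles contain non-finite values")
    D, flagged = _correlation_distance(P, metric)
    Z = linkage(squareform(D, checks=False), method="average")
    return DendrogramResult(list(P.columns), Z, flagged)


def replicate_silhouette(X: ExpressionMatrix, metric: str = "centered") -> float:
    """Silhouette of individual replicates under their condition labels.

    Uses correlation distance between sample columns.  Values near zero mean
    replicate-level clustering carries no condition structure.
    """
    from sklearn.metrics import silhouette_score

    D, _ = _correlation_distance(X.values, metric)
    labels = X.samples["group"].to_numpy()
    return float(silhouette_score(D, labels, metric="precomputed"))
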