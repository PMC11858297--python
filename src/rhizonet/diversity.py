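"""Alpha-diversity indices and Bray-Curtis / UPGMA beta diversity.

Chao1 uses the bias-corrected denominator ``2 (F2 + 1)``, which is defined
even when no doubletons are observed and matches common amplicon-pipeline
defaults (the classic estimator divides by ``2 F2`` instead).  Shannon
entropy defaults to natural-log units; Pielou's evenness divides by
``log(S_obs)`` in the same base.

UPGMA is implemented directly so its tie-break is part of the contract:
when several cluster pairs are at the minimal distance, the pair whose
(lexicographically smallest leaf label of each cluster) pair sorts first
is merged.  Heights are half the average inter-cluster distance, so the
output tree is ultrametric for any valid input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if arr.sum() == 0:
        raise ValueError("all-zero count vector: index undefined")
    return arr


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1 (F1 - 1) / (2 (F2 + 1))."""
    arr = _as_counts(counts)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts, base: float | None = None) -> float:
    """Shannon-Wiener H' = -sum p_i log p_i (natural log by default)."""
    arr = _as_counts(counts)
    p = arr[arr > 0] / arr.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        if base <= 1:
            raise ValueError("log base must exceed 1")
        h /= np.log(base)
    return h


def pielou(counts, base: float | None = None) -> float:
    """Pielou's evenness J = H / log(S_obs); undefined below 2 taxa."""
    arr = _as_counts(counts)
    s_obs = int((arr > 0).sum())
    if s_obs < 2:
        raise ValueError("evenness undefined for fewer than 2 observed taxa")
    denom = np.log(s_obs) if base is None else np.log(s_obs) / np.log(base)
    return shannon(arr, base=base) / denom


def alpha_diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample observed richness, Chao1, Shannon (nat. log) and Pielou."""
    rows = []
    for sample in table.columns:
        counts = table[sample].to_numpy()
        rows.append(
            {
                "sample_id": sample,
                "observed": int((counts > 0).sum()),
                "chao1": chao1(counts),
                "shannon": shannon(counts),
                "pielou": pielou(counts),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (columns) of a count table."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    mat = squareform(pdist(table.T.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(mat, ids=[str(c) for c in table.columns])


def upgma_tree(dm: DistanceMatrix | pd.DataFrame | np.ndarray, ids=None) -> TreeNode:
    """Average-linkage (UPGMA) tree over a distance matrix.

    Accepts a skbio DistanceMatrix, a labelled DataFrame, or an array plus
    ``ids``.  Returns a rooted skbio TreeNode whose root-to-leaf path
    lengths are all equal (ultrametric).
    """
    if isinstance(dm, DistanceMatrix):
        labels = list(dm.ids)
        d = dm.data.astype(float).copy()
    elif isinstance(dm, pd.DataFrame):
        labels = [str(c) for c in dm.columns]
        d = dm.to_numpy(dtype=float).copy()
    else:
        d = np.asarray(dm, dtype=float).copy()
        labels = list(ids) if ids is not None else [str(i) for i in range(len(d))]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if n == 1:
        return TreeNode(name=labels[0], length=None)

    # active clusters: key -> (node, size, height, lexicographically min leaf)
    clusters: dict[int, tuple[TreeNode, int, float, str]] = {
        i: (TreeNode(name=labels[i]), 1, 0.0, labels[i]) for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }

    while len(clusters) > 1:
        best = None
        for (i, j), val in dist.items():
            key = (val, tuple(sorted((clusters[i][3], clusters[j][3]))))
            if best is None or key < best[0]:
                best = (key, (i, j))
        (dmin, _), (i, j) = best
        node_i, size_i, h_i, min_i = clusters[i]
        node_j, size_j, h_j, min_j = clusters[j]
        height = dmin / 2.0
        node_i.length = height - h_i
        node_j.length = height - h_j
        parent = TreeNode(children=[node_i, node_j])
        new_key = min(i, j)
        other = max(i, j)
        # average linkage update, weighted by leaf counts
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.pop(tuple(sorted((i, k))))
            djk = dist.pop(tuple(sorted((j, k))))
            dist[tuple(sorted((new_key, k)))] = (size_i * dik + size_j * djk) / (
                size_i + size_j
            )
        dist.pop((min(i, j), max(i, j)))
        del clusters[other]
        clusters[new_key] = (parent, size_i + size_j, height, min(min_i, min_j))

    root = next(iter(clusters.values()))[0]
    root.length = None
    return root


def to_newick(tree: TreeNode, decimals: int = 6) -> str:
    """Serialize a tree to Newick with fixed-precision branch lengths."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            body = node.name or ""
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.length is not None:
            body += f":{node.length:.{decimals}f}"
        return body

    return render(tree) + ";\n"


def ultrametric_deviation(tree: TreeNode) -> float:
    """Max spread of root-to-leaf path lengths (0 for an ultrametric tree)."""
    depths = []

    def walk(node: TreeNode, acc: float) -> None:
        acc += node.length or 0.0
        if node.is_tip():
            depths.append(acc)
        for child in node.children:
            walk(child, acc)

    walk(tree, 0.0)
    return float(max(depths) - min(depths)) if depths else 0.0
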