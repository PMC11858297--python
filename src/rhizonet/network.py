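"""Correlation-based co-occurrence network inference and graph topology.

Edges are Spearman rank correlations between taxa computed on relative
abundances (a CLR transform is available behind a flag), with two-sided
p-values from the tie-corrected t-approximation and Benjamini-Hochberg
adjustment over all tested pairs jointly.  An edge is kept when
``|rho| >= rho_min`` and ``q <= q_max``; its sign is stored for reporting
but degree counts both signs.

The topology report emits raw Freeman degree centralization
``sum_i (d_max - d_i)``, its normalization by ``(n - 1)(n - 2)``, and the
total degree ``2 |E|``: published "degree centralization" magnitudes are
compatible with more than one of these readings, so all three are
reported.
"""

from __future__ import annotations

import itertools
import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def filter_taxa(
    table: pd.DataFrame,
    min_prevalence: float = 0.0,
    min_mean_relabund: float = 0.0,
) -> pd.DataFrame:
    """Keep taxa present in >= min_prevalence of samples with mean relative
    abundance >= min_mean_relabund; samples are preserved."""
    for name, value in (
        ("min_prevalence", min_prevalence),
        ("min_mean_relabund", min_mean_relabund),
    ):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    prevalence = (table > 0).mean(axis=1)
    rel = table / table.sum(axis=0)
    mean_rel = rel.mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_rel >= min_mean_relabund)
    if not keep.any():
        raise ValueError("filter removed every taxon")
    return table.loc[keep]


def _clr(rel: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    counts = rel + pseudocount
    log = np.log(counts)
    return log - log.mean(axis=0)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 10)."""
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p supported only for n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += _count_extreme(rx, ry, np.array(chunk), obs)
            total += len(chunk)
            chunk = []
    if chunk:
        count += _count_extreme(rx, ry, np.array(chunk), obs)
        total += len(chunk)
    return count / total


def _count_extreme(rx, ry, perms, obs) -> int:
    permuted = ry[perms]  # (k, n)
    rx_c = rx - rx.mean()
    py_c = permuted - permuted.mean(axis=1, keepdims=True)
    num = py_c @ rx_c
    denom = np.sqrt((rx_c**2).sum() * (py_c**2).sum(axis=1))
    rho = num / denom
    return int((np.abs(rho) >= obs - 1e-12).sum())


def correlation_network(
    table: pd.DataFrame,
    method: str = "spearman",
    rho_min: float = 0.6,
    q_max: float = 0.05,
    use_clr: bool = False,
    p_method: str = "t",
    taxonomy: pd.Series | None = None,
) -> nx.Graph:
    """Infer the co-occurrence network from a filtered abundance table.

    Nodes are all (non-constant) taxa; edges carry ``rho``, ``p``, ``q``
    and ``sign``.  Thresholds are recorded as graph attributes.
    """
    if method != "spearman":
        raise ValueError(f"unsupported correlation method {method!r}")
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples for a correlation network")

    constant = table.nunique(axis=1) <= 1
    if constant.any():
        dropped = list(table.index[constant])
        warnings.warn(
            f"excluding {len(dropped)} constant taxa (correlation undefined): "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
        table = table.loc[~constant]

    rel = table / table.sum(axis=0)
    profile = _clr(rel) if use_clr else rel
    values = profile.to_numpy(dtype=float)
    taxa = [str(t) for t in table.index]
    n_taxa, n_samples = values.shape

    rho_mat, p_mat = stats.spearmanr(values.T)
    if n_taxa == 2:  # scipy returns scalars for a single pair
        rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
        p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])

    iu = np.triu_indices(n_taxa, k=1)
    rhos = rho_mat[iu]
    if p_method == "exact":
        pvals = np.array(
            [
                _exact_spearman_p(values[i], values[j])
                for i, j in zip(iu[0], iu[1])
            ]
        )
    elif p_method == "t":
        pvals = p_mat[iu]
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    qvals = multipletests(pvals, method="fdr_bh")[1]

    graph = nx.Graph(
        rho_min=float(rho_min),
        q_max=float(q_max),
        method=method,
        clr=bool(use_clr),
        n_samples=int(n_samples),
    )
    for t in taxa:
        attrs = {}
        if taxonomy is not None and t in taxonomy.index:
            attrs["lineage"] = str(taxonomy.loc[t])
        graph.add_node(t, **attrs)
    for idx, (i, j) in enumerate(zip(iu[0], iu[1])):
        rho = float(rhos[idx])
        if abs(rho) >= rho_min and qvals[idx] <= q_max:
            graph.add_edge(
                taxa[i],
                taxa[j],
                rho=rho,
                p=float(pvals[idx]),
                q=float(qvals[idx]),
                sign="+" if rho >= 0 else "-",
            )
    return graph


def topology(net: nx.Graph) -> dict:
    """Vertex number, edge count, total degree and degree centralization."""
    n = net.number_of_nodes()
    degrees = [d for _, d in net.degree()]
    d_max = max(degrees) if degrees else 0
    raw = float(sum(d_max - d for d in degrees))
    norm = raw / ((n - 1) * (n - 2)) if n >= 3 else 0.0
    return {
        "vertex_number": n,
        "edge_count": net.number_of_edges(),
        "total_degree": 2 * net.number_of_edges(),
        "centralization_raw": raw,
        "centralization_norm": norm,
    }


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    annotated = net.copy()
    for node, degree in annotated.degree():
        annotated.nodes[node]["degree"] = int(degree)
    nx.write_graphml(annotated, str(path))


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "taxon_a": a,
            "taxon_b": b,
            "rho": data["rho"],
            "p": data["p"],
            "q": data["q"],
            "sign": data["sign"],
        }
        for a, b, data in sorted(net.edges(data=True))
    ]
    df = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "q", "sign"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_topology_report(net: nx.Graph, path: str | Path) -> dict:
    report = topology(net)
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
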