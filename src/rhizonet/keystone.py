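"""Module detection and Zi/Pi node-role classification.

Within-module connectivity Zi is the z-score of a node's within-module
degree against its module's degree distribution (population standard
deviation; Zi = 0 when the module is degree-homogeneous).  Among-module
connectivity Pi is the participation coefficient
``1 - sum_t (k_it / k_i)^2``.  Roles follow the standard four-way rule
with strict inequalities at the thresholds z* = 2.5 and p* = 0.62:
network hub (Zi > z*, Pi > p*), module hub (Zi > z*, Pi <= p*),
connector (Zi <= z*, Pi > p*), else peripheral.  Keystone taxa are the
non-peripheral nodes.

Module detection defaults to deterministic greedy modularity maximization
so repeated runs agree without seed sensitivity; Louvain is available as
an alternative.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from rhizonet.io import rank_of

Z_THRESHOLD = 2.5
P_THRESHOLD = 0.62

ROLE_ORDER = ("peripheral", "connector", "module_hub", "network_hub")


def detect_modules(
    net: nx.Graph,
    seed: int | None = None,
    algorithm: str = "greedy",
    positive_only: bool = True,
) -> tuple[dict, float]:
    """Partition the network into modules; returns (node -> module id, Q).

    By default modularity is maximized on the unweighted simple subgraph of
    positive associations: a negative correlation marks mutual exclusion,
    not co-membership, and in compositional data the closure operation
    systematically anticorrelates distinct modules, so counting negative
    edges as ties merges genuinely separate modules.  Every node is kept
    (nodes with only negative edges become singleton modules); Zi/Pi are
    computed downstream on the full unsigned graph.

    Module ids are contiguous integers ordered by decreasing module size
    (ties by smallest member label).  An edgeless network yields singleton
    modules and Q = 0 with a warning.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    simple = nx.Graph()
    simple.add_nodes_from(net.nodes())
    if positive_only:
        simple.add_edges_from(
            (a, b)
            for a, b, data in net.edges(data=True)
            if data.get("sign", "+") != "-" and data.get("rho", 1.0) >= 0
        )
    else:
        simple.add_edges_from(net.edges())

    if simple.number_of_edges() == 0:
        warnings.warn("edgeless network: every node becomes its own module")
        communities = [{node} for node in sorted(simple.nodes())]
        q = 0.0
    elif algorithm == "greedy":
        communities = [
            set(c)
            for c in nx.community.greedy_modularity_communities(simple)
        ]
        q = nx.community.modularity(simple, communities)
    elif algorithm == "louvain":
        communities = [
            set(c) for c in nx.community.louvain_communities(simple, seed=seed)
        ]
        q = nx.community.modularity(simple, communities)
    else:
        raise ValueError(f"unknown module detection algorithm {algorithm!r}")

    communities.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    partition = {
        node: idx for idx, members in enumerate(communities) for node in members
    }
    return partition, float(q)


def _check_partition(net: nx.Graph, partition: dict) -> None:
    missing = [n for n in net.nodes() if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")


def within_module_z(net: nx.Graph, partition: dict) -> dict:
    """Zi per node: (kappa_i - mean kappa of its module) / population sd."""
    _check_partition(net, partition)
    kappa = {
        node: sum(1 for nb in net.neighbors(node) if partition[nb] == partition[node])
        for node in net.nodes()
    }
    by_module: dict[int, list] = {}
    for node in net.nodes():
        by_module.setdefault(partition[node], []).append(kappa[node])
    stats = {
        module: (float(np.mean(vals)), float(np.std(vals)))  # population sd
        for module, vals in by_module.items()
    }
    zi = {}
    for node in net.nodes():
        mean, sd = stats[partition[node]]
        zi[node] = 0.0 if sd == 0 else (kappa[node] - mean) / sd
    return zi


def participation_coefficient(net: nx.Graph, partition: dict) -> dict:
    """Pi per node: 1 - sum_t (k_it / k_i)^2; isolated nodes get Pi = 0."""
    _check_partition(net, partition)
    pi = {}
    for node in net.nodes():
        k = net.degree(node)
        if k == 0:
            pi[node] = 0.0
            continue
        per_module: dict[int, int] = {}
        for nb in net.neighbors(node):
            t = partition[nb]
            per_module[t] = per_module.get(t, 0) + 1
        pi[node] = 1.0 - sum((kit / k) ** 2 for kit in per_module.values())
    return pi


def classify_roles(
    zi: float, pi: float, z_threshold: float = Z_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> str:
    """Four-way role from (Zi, Pi); strict inequalities at the thresholds."""
    if zi > z_threshold:
        return "network_hub" if pi > p_threshold else "module_hub"
    return "connector" if pi > p_threshold else "peripheral"


def node_roles(
    net: nx.Graph,
    partition: dict,
    taxonomy: pd.Series | None = None,
    z_threshold: float = Z_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Per-node table: degree, module, Zi, Pi, role, keystone flag, phylum."""
    zi = within_module_z(net, partition)
    pi = participation_coefficient(net, partition)
    rows = []
    for node in sorted(net.nodes(), key=str):
        role = classify_roles(zi[node], pi[node], z_threshold, p_threshold)
        lineage = (
            str(taxonomy.loc[node])
            if taxonomy is not None and node in taxonomy.index
            else ""
        )
        rows.append(
            {
                "taxon_id": node,
                "phylum": rank_of(lineage) if lineage else "unidentified",
                "degree": int(net.degree(node)),
                "module": int(partition[node]),
                "Zi": zi[node],
                "Pi": pi[node],
                "role": role,
                "keystone": role != "peripheral",
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def aggregate_by_taxon(
    roles: pd.DataFrame, taxonomy: pd.Series | None = None, rank: str = "phylum"
) -> pd.DataFrame:
    """Counts of connectors / module hubs / network hubs per taxon group.

    Peripheral nodes are excluded (they are not keystone taxa); nodes with
    no annotation fall under "unidentified".
    """
    if taxonomy is not None:
        labels = {
            node: rank_of(taxonomy.loc[node], rank)
            if node in taxonomy.index
            else "unidentified"
            for node in roles.index
        }
    else:
        labels = dict(roles["phylum"]) if "phylum" in roles else {}
    keystone = roles[roles["role"] != "peripheral"]
    counts: dict[str, dict[str, int]] = {}
    for node, row in keystone.iterrows():
        group = labels.get(node, "unidentified")
        counts.setdefault(group, {"connector": 0, "module_hub": 0, "network_hub": 0})
        counts[group][row["role"]] += 1
    out = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    if out.empty:
        out = pd.DataFrame(columns=["connector", "module_hub", "network_hub"])
    out.index.name = rank
    return out.sort_index()


def write_node_report(
    roles: pd.DataFrame,
    path: str | Path,
    z_threshold: float = Z_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> None:
    """Per-node TSV with the thresholds echoed in a comment header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# z_threshold={z_threshold}\tp_threshold={p_threshold}\n")
        roles.to_csv(fh, sep="\t", lineterminator="\n")
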