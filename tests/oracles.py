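"""Independent reference implementations used only as test oracles.

Nothing here shares code with the package: Zi/Pi are recomputed from
first principles with explicit loops, graph centralization by brute
force, and the recursive-path-model ML solution in closed form (the
likelihood of a recursive model with uncorrelated disturbances factorizes
per equation, so equation-wise least squares on S is the exact ML
solution).
"""

from __future__ import annotations

import numpy as np


def naive_zi_pi(edges, nodes, partition):
    """Zi and Pi per node, written out longhand."""
    neighbors = {n: set() for n in nodes}
    for a, b in edges:
        neighbors[a].add(b)
        neighbors[b].add(a)
    zi, pi = {}, {}
    modules = {}
    for n in nodes:
        modules.setdefault(partition[n], []).append(n)
    kappa = {
        n: len([m for m in neighbors[n] if partition[m] == partition[n]])
        for n in nodes
    }
    for n in nodes:
        members = modules[partition[n]]
        vals = [kappa[m] for m in members]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        sd = var**0.5
        zi[n] = 0.0 if sd == 0 else (kappa[n] - mean) / sd
        k = len(neighbors[n])
        if k == 0:
            pi[n] = 0.0
        else:
            per = {}
            for m in neighbors[n]:
                per[partition[m]] = per.get(partition[m], 0) + 1
            pi[n] = 1.0 - sum((c / k) ** 2 for c in per.values())
    return zi, pi


def brute_force_centralization(edges, nodes):
    """Freeman degree centralization, raw and normalized, by enumeration."""
    degree = {n: 0 for n in nodes}
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    d_max = max(degree.values()) if degree else 0
    raw = sum(d_max - d for d in degree.values())
    n = len(nodes)
    norm = raw / ((n - 1) * (n - 2)) if n >= 3 else 0.0
    return raw, norm


def closed_form_sem(variables, paths, S, N):
    """Exact ML fit of a recursive path model from the sample covariance S.

    Returns a dict with path estimates, disturbance variances, F_min,
    chi2 (Wishart multiplier), df, CFI and RMSEA, all from closed-form
    algebra: per-equation OLS and a direct evaluation of the discrepancy.
    """
    idx = {v: i for i, v in enumerate(variables)}
    p = len(variables)
    endo = [v for v in variables if any(e == v for _, e in paths)]
    exo = [v for v in variables if v not in endo]

    estimates = {}
    psi_diag = {}
    B = np.zeros((p, p))
    for y in endo:
        parents = [c for c, e in paths if e == y]
        pi_idx = [idx[c] for c in parents]
        b = np.linalg.solve(S[np.ix_(pi_idx, pi_idx)], S[pi_idx, idx[y]])
        for c, bc in zip(parents, b):
            estimates[(c, y)] = float(bc)
            B[idx[y], idx[c]] = bc
        psi_diag[y] = float(S[idx[y], idx[y]] - S[idx[y], pi_idx] @ b)

    Psi = np.zeros((p, p))
    exo_idx = [idx[v] for v in exo]
    Psi[np.ix_(exo_idx, exo_idx)] = S[np.ix_(exo_idx, exo_idx)]
    for y in endo:
        Psi[idx[y], idx[y]] = psi_diag[y]
    A = np.linalg.inv(np.eye(p) - B)
    Sigma = A @ Psi @ A.T

    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    f_min = float(
        logdet_m + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p
    )
    f_min = max(f_min, 0.0)
    t = len(paths) + len(exo) + len(exo) * (len(exo) - 1) // 2 + len(endo)
    df = p * (p + 1) // 2 - t
    chi2 = (N - 1) * f_min

    f_base = float(np.sum(np.log(np.diag(S))) - logdet_s)
    chi2_b = (N - 1) * f_base
    df_b = p * (p - 1) // 2
    excess = max(chi2 - df, 0.0)
    denom = max(chi2_b - df_b, excess, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    rmsea = 0.0 if df == 0 else float(np.sqrt(excess / (df * (N - 1))))
    return {
        "estimates": estimates,
        "psi": psi_diag,
        "f_min": f_min,
        "chi2": chi2,
        "df": df,
        "cfi": cfi,
        "rmsea": rmsea,
        "implied": Sigma,
    }


def random_recursive_model(rng, p_min=4, p_max=6, edge_prob=0.5):
    """Random acyclic path structure with coefficients, for oracle checks."""
    p = int(rng.integers(p_min, p_max + 1))
    variables = [f"V{i}" for i in range(p)]
    paths = []
    coefs = {}
    for j in range(1, p):
        for i in range(j):
            if rng.random() < edge_prob:
                paths.append((variables[i], variables[j]))
                coefs[(variables[i], variables[j])] = float(
                    rng.uniform(-0.6, 0.6)
                )
    return variables, paths, coefs


def simulate_recursive(variables, coefs, n, rng, disturbance_sd=0.8):
    """Draw n observations from a recursive linear model."""
    data = {}
    endo = {e for _, e in coefs}
    for v in variables:  # variables listed in topological order
        value = rng.normal(0.0, 1.0, size=n) * (
            1.0 if v not in endo else disturbance_sd
        )
        for (c, e), b in coefs.items():
            if e == v:
                value = value + b * data[c]
        data[v] = value
    return data
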