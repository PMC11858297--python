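"""Spearman correlation screen over soil, plant and microbiome variables.

Pairwise-complete tie-corrected Spearman correlations with two-sided
p-values from the t-approximation, Benjamini-Hochberg adjustment over all
variable pairs jointly, and significance stars computed from the raw
p-values (*: p < 0.05, **: p < 0.01, ***: p < 0.001; strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def significance_stars(p: float) -> str:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass
class CorrMatrix:
    """Spearman screen result: rho/p/q/n matrices plus star labels."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format table (var1, var2, n, rho, p, q, stars), upper triangle."""
        variables = list(self.rho.columns)
        rows = []
        for i, a in enumerate(variables):
            for b in variables[i + 1:]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "n": int(self.n.loc[a, b]),
                        "rho": self.rho.loc[a, b],
                        "p": self.p.loc[a, b],
                        "q": self.q.loc[a, b],
                        "stars": self.stars.loc[a, b],
                    }
                )
        return pd.DataFrame(rows, columns=["var1", "var2", "n", "rho", "p", "q", "stars"])

    def write(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, lineterminator="\n")


def spearman_matrix(
    features: pd.DataFrame, variables: list[str] | None = None
) -> CorrMatrix:
    """Pairwise-complete Spearman screen over the requested variables."""
    if variables is None:
        variables = [
            c for c in features.columns
            if pd.api.types.is_numeric_dtype(features[c])
        ]
    missing = [v for v in variables if v not in features.columns]
    if missing:
        raise ValueError(f"unknown variables: {missing}")

    kept = []
    for v in variables:
        if features[v].dropna().nunique() <= 1:
            warnings.warn(f"excluding constant variable {v!r} (correlation undefined)")
        else:
            kept.append(v)
    variables = kept
    k = len(variables)

    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables, dtype=float)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    n = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    for v in variables:
        n.loc[v, v] = int(features[v].notna().sum())

    pairs = []
    pvals = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            mask = features[a].notna() & features[b].notna()
            n_pair = int(mask.sum())
            if n_pair < 4:
                raise ValueError(
                    f"fewer than 4 complete observations for pair ({a}, {b})"
                )
            r, pv = stats.spearmanr(features.loc[mask, a], features.loc[mask, b])
            rho.loc[a, b] = rho.loc[b, a] = float(r)
            p.loc[a, b] = p.loc[b, a] = float(pv)
            n.loc[a, b] = n.loc[b, a] = n_pair
            pairs.append((a, b))
            pvals.append(float(pv))

    q = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    if pairs:
        adjusted = bh_adjust(pvals)
        for (a, b), qv in zip(pairs, adjusted):
            q.loc[a, b] = q.loc[b, a] = float(qv)

    stars = p.map(significance_stars)
    for v in variables:
        stars.loc[v, v] = ""
    return CorrMatrix(rho=rho, p=p, q=q, n=n, stars=stars)
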