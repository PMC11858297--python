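"""Maximum-likelihood path analysis for recursive observed-variable models.

A model is a set of directed paths among observed variables (no latent
constructs, no measurement model).  Under the standard identifiability
convention for recursive path models, exogenous variances and covariances
are free (saturated among exogenous) and endogenous disturbances are
mutually uncorrelated, so the implied covariance is

    Sigma(theta) = (I - B)^-1 Psi (I - B)^-T

with B strictly lower-triangular under a topological ordering and Psi
block-diagonal (free exogenous block, diagonal disturbances).  The fit
minimizes the ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

by quasi-Newton (BFGS) from closed-form starting values: path
coefficients from per-equation least squares on S, variances from sample
moments.  For recursive models these starts are already the ML solution,
so the optimizer serves as verification and polish; chi2 = (N - 1) F_min
by default (Wishart convention; the normal-theory N multiplier is
available behind a flag).

Fit indices:

    GFI   = 1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2]
    CFI   = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)
    RMSEA = sqrt(max(chi2 - df, 0) / (df (N - 1))), 0 when df = 0

with the baseline model fixing all covariances to zero (variances free,
df_b = p (p - 1) / 2).  Standardized coefficients rescale each path by
the model-implied standard deviations of its cause and effect.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

_BIG = 1e10
_NAME = re.compile(r"^[A-Za-z_]\w*$")


@dataclass
class PathModel:
    """Recursive path model over observed variables."""

    variables: list[str]
    paths: list[tuple[str, str]]  # (cause, effect)

    def __post_init__(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.variables)
        graph.add_edges_from(self.paths)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            pretty = " -> ".join([cycle[0][0]] + [e[1] for e in cycle])
            raise ValueError(f"path model contains a cycle: {pretty}")
        self._graph = graph

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def endogenous(self) -> list[str]:
        targets = {e for _, e in self.paths}
        return [v for v in self.variables if v in targets]

    @property
    def exogenous(self) -> list[str]:
        targets = {e for _, e in self.paths}
        return [v for v in self.variables if v not in targets]

    def parents(self, variable: str) -> list[str]:
        return [c for c, e in self.paths if e == variable]

    @property
    def n_free_params(self) -> int:
        n_exo = len(self.exogenous)
        return (
            len(self.paths)
            + n_exo  # exogenous variances
            + n_exo * (n_exo - 1) // 2  # exogenous covariances
            + len(self.endogenous)  # disturbance variances
        )

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_free_params

    def parameter_names(self) -> list[str]:
        names = [f"{c}->{e}" for c, e in self.paths]
        exo = self.exogenous
        names += [f"var({v})" for v in exo]
        names += [
            f"cov({exo[i]},{exo[j]})"
            for i in range(len(exo))
            for j in range(i + 1, len(exo))
        ]
        names += [f"zeta({v})" for v in self.endogenous]
        return names


def parse_model(spec_text: str, variables: list[str] | None = None) -> PathModel:
    """Parse one ``effect ~ cause1 + cause2`` (or ``<-``) statement per line.

    ``#`` starts a comment.  ``variables`` appends extra observed
    variables (exogenous unless named as an effect); an empty spec plus a
    variable list yields the saturated exogenous model.
    """
    seen: list[str] = []
    paths: list[tuple[str, str]] = []

    def note(name: str) -> str:
        if not _NAME.match(name):
            raise ValueError(f"invalid variable name {name!r}")
        if name not in seen:
            seen.append(name)
        return name

    for lineno, raw in enumerate(spec_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "<-" in line:
            lhs, rhs = line.split("<-", 1)
        elif "~" in line:
            lhs, rhs = line.split("~", 1)
        else:
            raise ValueError(f"line {lineno}: expected 'effect ~ causes': {raw!r}")
        effect = note(lhs.strip())
        for cause in rhs.split("+"):
            cause = note(cause.strip())
            if (cause, effect) in paths:
                raise ValueError(f"duplicate path {cause} -> {effect}")
            paths.append((cause, effect))
    for extra in variables or []:
        note(extra)
    if not seen:
        raise ValueError("model defines no variables")
    return PathModel(variables=seen, paths=paths)


def _unpack(model: PathModel, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = model.p
    idx = {v: i for i, v in enumerate(model.variables)}
    B = np.zeros((p, p))
    pos = 0
    for cause, effect in model.paths:
        B[idx[effect], idx[cause]] = theta[pos]
        pos += 1
    Psi = np.zeros((p, p))
    exo = model.exogenous
    for v in exo:
        Psi[idx[v], idx[v]] = theta[pos]
        pos += 1
    for i in range(len(exo)):
        for j in range(i + 1, len(exo)):
            a, b = idx[exo[i]], idx[exo[j]]
            Psi[a, b] = Psi[b, a] = theta[pos]
            pos += 1
    for v in model.endogenous:
        Psi[idx[v], idx[v]] = theta[pos]
        pos += 1
    return B, Psi


def implied_covariance(model: PathModel, theta) -> np.ndarray:
    """Sigma(theta) = (I - B)^-1 Psi (I - B)^-T."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.n_free_params,):
        raise ValueError(
            f"expected {model.n_free_params} parameters, got {theta.shape}"
        )
    B, Psi = _unpack(model, theta)
    eye = np.eye(model.p)
    try:
        A = np.linalg.inv(eye - B)
    except np.linalg.LinAlgError as exc:  # unreachable for acyclic B; guard anyway
        raise ValueError("I - B is singular") from exc
    return A @ Psi @ A.T


def _start_values(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Closed-form starts: per-equation OLS on S, moments for variances."""
    idx = {v: i for i, v in enumerate(model.variables)}
    theta = np.zeros(model.n_free_params)
    pos = len(model.paths)
    coef: dict[tuple[str, str], float] = {}
    for y in model.endogenous:
        parents = model.parents(y)
        pi = [idx[c] for c in parents]
        b = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, idx[y]])
        for c, bc in zip(parents, b):
            coef[(c, y)] = float(bc)
    for k, (cause, effect) in enumerate(model.paths):
        theta[k] = coef[(cause, effect)]
    exo = model.exogenous
    for v in exo:
        theta[pos] = S[idx[v], idx[v]]
        pos += 1
    for i in range(len(exo)):
        for j in range(i + 1, len(exo)):
            theta[pos] = S[idx[exo[i]], idx[exo[j]]]
            pos += 1
    for y in model.endogenous:
        parents = model.parents(y)
        pi = [idx[c] for c in parents]
        b = np.array([coef[(c, y)] for c in parents])
        theta[pos] = S[idx[y], idx[y]] - S[idx[y], pi] @ b
        pos += 1
    return theta


@dataclass
class SemFit:
    """Estimates and goodness-of-fit of one fitted path model."""

    model: PathModel
    theta: np.ndarray
    estimates: dict[str, float]
    std_estimates: dict[str, float]
    implied: pd.DataFrame
    f_min: float
    chi2: float
    df: int
    p_value: float
    gfi: float
    cfi: float
    rmsea: float
    converged: bool
    n_obs: int
    messages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variables": self.model.variables,
            "paths": [f"{c}->{e}" for c, e in self.model.paths],
            "estimates": self.estimates,
            "standardized_estimates": self.std_estimates,
            "f_min": self.f_min,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "gfi": self.gfi,
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "messages": self.messages,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def _discrepancy(Sigma: np.ndarray, S: np.ndarray, logdet_S: float) -> float:
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return _BIG
    try:
        inv = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError:
        return _BIG
    return float(logdet + np.trace(S @ inv) - logdet_S - len(S))


def _gfi(Sigma: np.ndarray, S: np.ndarray) -> float:
    W = np.linalg.inv(Sigma) @ S
    resid = W - np.eye(len(S))
    return float(1.0 - np.trace(resid @ resid) / np.trace(W @ W))


def fit_indices(
    chi2: float, df: int, S: np.ndarray, Sigma: np.ndarray, N: int, multiplier: float
) -> tuple[float, float, float, list[str]]:
    """GFI, CFI and RMSEA for a fitted model (baseline: zero covariances)."""
    messages: list[str] = []
    p = len(S)
    gfi = _gfi(Sigma, S)
    sign, logdet_S = np.linalg.slogdet(S)
    f_baseline = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chi2_b = multiplier * f_baseline
    df_b = p * (p - 1) // 2
    excess = max(chi2 - df, 0.0)
    denom = max(chi2_b - df_b, excess, 0.0)
    if denom == 0.0:
        cfi = 1.0
        if chi2_b <= df_b:
            messages.append("degenerate baseline (chi2_b <= df_b): CFI set to 1")
    else:
        cfi = 1.0 - excess / denom
        if chi2_b <= df_b:
            messages.append("degenerate baseline (chi2_b <= df_b)")
    rmsea = 0.0 if df == 0 else float(np.sqrt(excess / (df * (N - 1))))
    return gfi, cfi, rmsea, messages


def standardize(model: PathModel, theta: np.ndarray) -> dict[str, float]:
    """Standardized path coefficients from the model-implied covariance."""
    Sigma = implied_covariance(model, theta)
    sd = np.sqrt(np.diag(Sigma))
    if (sd <= 0).any():
        bad = [v for v, s in zip(model.variables, sd) if s <= 0]
        raise ValueError(f"zero implied variance for {bad}")
    idx = {v: i for i, v in enumerate(model.variables)}
    out = {}
    for k, (cause, effect) in enumerate(model.paths):
        out[f"{cause}->{effect}"] = float(
            theta[k] * sd[idx[cause]] / sd[idx[effect]]
        )
    return out


def _prepare_S(model: PathModel, S) -> np.ndarray:
    if isinstance(S, pd.DataFrame):
        missing = [v for v in model.variables if v not in S.columns]
        if missing:
            raise ValueError(f"covariance matrix lacks model variables: {missing}")
        S = S.loc[model.variables, model.variables].to_numpy(dtype=float)
    S = np.asarray(S, dtype=float)
    if S.shape != (model.p, model.p):
        raise ValueError(f"expected a {model.p}x{model.p} covariance matrix")
    return 0.5 * (S + S.T)


def fit_ml(
    model: PathModel,
    S,
    N: int,
    chi2_multiplier: str = "wishart",
    gtol: float = 1e-10,
    max_iter: int = 500,
) -> SemFit:
    """Fit the model to a sample covariance S observed on N samples.

    ``chi2_multiplier`` is ``"wishart"`` for chi2 = (N - 1) F_min (the
    convention of most SEM software) or ``"normal"`` for N F_min.
    """
    if N <= model.p:
        raise ValueError(f"need N > p = {model.p} samples, got N = {N}")
    if chi2_multiplier not in ("wishart", "normal"):
        raise ValueError("chi2_multiplier must be 'wishart' or 'normal'")
    mult = float(N - 1 if chi2_multiplier == "wishart" else N)
    S = _prepare_S(model, S)
    messages: list[str] = []

    eigvals = np.linalg.eigvalsh(S)
    if eigvals[0] <= 1e-12 * max(1.0, eigvals[-1]):
        return _fit_degenerate(model, S, N, messages)

    sign, logdet_S = np.linalg.slogdet(S)
    x0 = _start_values(model, S)

    def objective(theta: np.ndarray) -> float:
        Sigma = implied_covariance(model, theta)
        return _discrepancy(Sigma, S, logdet_S)

    result = optimize.minimize(
        objective,
        x0,
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    converged = bool(result.success) or float(
        np.max(np.abs(result.jac))
    ) < 1e-6
    if not converged:
        messages.append(f"optimizer did not converge: {result.message}")
    theta = result.x
    f_min = max(float(result.fun), 0.0)
    return _assemble_fit(model, theta, f_min, S, N, mult, converged, messages)


def _fit_degenerate(
    model: PathModel, S: np.ndarray, N: int, messages: list[str]
) -> SemFit:
    """Singular S: admissible only if the model reproduces S exactly
    (the zero-disturbance limit); otherwise the input is rejected."""
    theta = _start_values(model, S)
    Sigma = implied_covariance(model, theta)
    scale = max(1.0, float(np.abs(S).max()))
    if np.abs(Sigma - S).max() > 1e-8 * scale:
        raise ValueError("sample covariance matrix is not positive-definite")
    messages.append(
        "singular sample covariance reproduced exactly by the model "
        "(zero-disturbance limit); chi2 fixed at 0"
    )
    df = model.df
    estimates = {
        name: float(v) for name, v in zip(model.parameter_names(), theta)
    }
    return SemFit(
        model=model,
        theta=theta,
        estimates=estimates,
        std_estimates=standardize(model, theta),
        implied=pd.DataFrame(Sigma, index=model.variables, columns=model.variables),
        f_min=0.0,
        chi2=0.0,
        df=df,
        p_value=1.0,
        gfi=1.0,
        cfi=1.0,
        rmsea=0.0,
        converged=True,
        n_obs=int(N),
        messages=messages,
    )


def _assemble_fit(
    model: PathModel,
    theta: np.ndarray,
    f_min: float,
    S: np.ndarray,
    N: int,
    mult: float,
    converged: bool,
    messages: list[str],
) -> SemFit:
    Sigma = implied_covariance(model, theta)
    df = model.df
    chi2 = mult * f_min
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    gfi, cfi, rmsea, idx_messages = fit_indices(chi2, df, S, Sigma, N, mult)
    estimates = {
        name: float(v) for name, v in zip(model.parameter_names(), theta)
    }
    return SemFit(
        model=model,
        theta=theta,
        estimates=estimates,
        std_estimates=standardize(model, theta),
        implied=pd.DataFrame(Sigma, index=model.variables, columns=model.variables),
        f_min=f_min,
        chi2=float(chi2),
        df=df,
        p_value=p_value,
        gfi=gfi,
        cfi=cfi,
        rmsea=rmsea,
        converged=converged,
        n_obs=int(N),
        messages=messages + idx_messages,
    )


def fit_from_data(
    model: PathModel, data: pd.DataFrame, n: int | None = None, **kwargs
) -> SemFit:
    """Fit against the sample covariance of a data table (divisor N - 1)."""
    missing = [v for v in model.variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    sub = data[model.variables].dropna()
    S = sub.cov()
    return fit_ml(model, S, N=n if n is not None else len(sub), **kwargs)
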