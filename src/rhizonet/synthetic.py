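"""Synthetic communities and covariates with recoverable ground truth.

Two generators:

* :func:`generate_modular_abundances` draws compositional ASV count tables
  whose latent per-sample intensities are multivariate log-normal with a
  planted module (block-correlation) structure and planted hub taxa, then
  closes each sample to a fixed sequencing depth with a multinomial draw.
* :func:`generate_soil_plant_table` draws soil/plant/microbiome summary
  variables from a known recursive linear path model with Gaussian
  disturbances, so a path-model fitter has an exact answer to recover.

The block correlation is built from an explicit factor-loading matrix
(one global factor shared by all modules plus one factor per module), so
the latent covariance is positive semi-definite by construction:

* a regular taxon of module *m* loads on factor *m* with communality
  ``within_module_corr``; two same-module taxa then correlate at
  ``within_module_corr`` and taxa of different modules at
  ``between_module_corr`` (via the global factor);
* a planted ``module_hub`` gets communality ``min(0.95, within + 0.2)``,
  raising its correlation with every member of its block;
* a planted ``connector`` splits a 0.9 communality budget over two module
  factors, a ``network_hub`` over all of them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from rhizonet import io

ROLES = ("module_hub", "network_hub", "connector")

# Fixed offsets deriving per-stage RNG streams from the one root seed, so
# each stage can be regenerated independently of the others.
_ABUNDANCE_STREAM = 0
_FEATURES_STREAM = 1

#: Demo causal structure for a fertilization-stress scenario: nitrate (NN)
#: and sodium (Na) suppress microbial richness (BC/FC) and network
#: connectivity (BD/FD) directly and via cucumber root growth (RW), while
#: ammonium (AN) aids root growth.  Magnitudes are illustrative defaults.
DEMO_PATHS: dict[tuple[str, str], float] = {
    ("NN", "RW"): -0.40,
    ("AN", "RW"): 0.25,
    ("NN", "BC"): -0.30,
    ("Na", "BC"): -0.35,
    ("RW", "BC"): 0.40,
    ("Na", "FC"): -0.30,
    ("RW", "FC"): 0.35,
    ("NN", "BD"): -0.30,
    ("Mg", "BD"): -0.20,
    ("RW", "BD"): 0.35,
    ("NN", "FD"): -0.25,
    ("RW", "FD"): 0.30,
}

#: Disturbance standard deviations for the endogenous demo variables plus
#: free-floating soil/plant variables kept as exogenous standard normals.
DEMO_DISTURBANCE_SD: dict[str, float] = {
    "RW": 0.8,
    "BC": 0.7,
    "FC": 0.8,
    "BD": 0.75,
    "FD": 0.8,
    # exogenous, listed to pin the full variable set of the screen
    "WC": 0.0,
    "pH": 0.0,
    "EC": 0.0,
    "AN": 0.0,
    "NN": 0.0,
    "K": 0.0,
    "Ca": 0.0,
    "Na": 0.0,
    "Mg": 0.0,
    "DI": 0.0,
    "BP": 0.0,
    "FP": 0.0,
    "FV": 0.0,
}


@dataclass
class ScenarioConfig:
    """Full description of one synthetic study scenario."""

    n_taxa: int = 60
    n_samples: int = 30
    n_modules: int = 3
    hub_spec: list[tuple[int, str]] = field(
        default_factory=lambda: [
            (0, "module_hub"),
            (20, "module_hub"),
            (40, "module_hub"),
            (10, "connector"),
        ]
    )
    within_module_corr: float = 0.7
    between_module_corr: float = 0.05
    sequencing_depth: int = 50_000
    path_coefficients: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEMO_PATHS)
    )
    disturbance_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEMO_DISTURBANCE_SD)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa <= 0 or self.n_samples <= 0 or self.n_modules <= 0:
            raise ValueError("n_taxa, n_samples and n_modules must be positive")
        if not (0.0 < self.within_module_corr < 1.0):
            raise ValueError("within_module_corr must lie in (0, 1)")
        if not (0.0 <= self.between_module_corr < self.within_module_corr):
            raise ValueError(
                "between_module_corr must lie in [0, within_module_corr)"
            )
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        for idx, role in self.hub_spec:
            if not (0 <= idx < self.n_taxa):
                raise ValueError(f"hub index {idx} out of range [0, {self.n_taxa})")
            if role not in ROLES:
                raise ValueError(f"unknown planted role {role!r}")
        _check_acyclic(self.path_coefficients)


@dataclass
class TruthBundle:
    """Ground truth shipped next to a generated fixture."""

    module_assignment: dict[str, int] = field(default_factory=dict)
    planted_roles: dict[str, str] = field(default_factory=dict)
    true_paths: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "module_assignment": self.module_assignment,
            "planted_roles": self.planted_roles,
            "true_paths": [
                [cause, effect, coef]
                for (cause, effect), coef in sorted(self.true_paths.items())
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "TruthBundle":
        payload = json.loads(text)
        return cls(
            module_assignment={
                k: int(v) for k, v in payload["module_assignment"].items()
            },
            planted_roles=dict(payload["planted_roles"]),
            true_paths={
                (cause, effect): float(coef)
                for cause, effect, coef in payload["true_paths"]
            },
        )

    def merged_with(self, other: "TruthBundle") -> "TruthBundle":
        return TruthBundle(
            module_assignment={**self.module_assignment, **other.module_assignment},
            planted_roles={**self.planted_roles, **other.planted_roles},
            true_paths={**self.true_paths, **other.true_paths},
        )


def demo_scenario(seed: int = 0) -> ScenarioConfig:
    """The default study scenario (all defaults, root seed settable)."""
    return ScenarioConfig(seed=seed)


def _check_acyclic(paths: dict[tuple[str, str], float]) -> nx.DiGraph:
    g = nx.DiGraph()
    for (cause, effect), coef in paths.items():
        g.add_edge(cause, effect, coef=float(coef))
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return g
    pretty = " -> ".join([cycle[0][0]] + [e[1] for e in cycle])
    raise ValueError(f"path coefficients contain a cycle: {pretty}")


def _taxon_ids(n: int) -> list[str]:
    return [f"ASV_{i + 1:04d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _loading_matrix(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Build factor loadings L (taxa x (1+M)) and unique sds; PSD cov = LL' + D."""
    m = config.n_modules
    w = config.within_module_corr
    r = config.between_module_corr / w  # module-factor correlation
    modules = np.array([i % m for i in range(config.n_taxa)])
    roles = {idx: role for idx, role in config.hub_spec}

    # basis: column 0 = global factor g, columns 1..M = module-specific parts;
    # module factor f_k = sqrt(r) g + sqrt(1 - r) h_k.
    L = np.zeros((config.n_taxa, 1 + m))
    for i in range(config.n_taxa):
        k = modules[i]
        role = roles.get(i)
        if role == "module_hub":
            comm = min(0.95, w + 0.2)
            L[i, 0] = np.sqrt(comm * r)
            L[i, 1 + k] = np.sqrt(comm * (1.0 - r))
        elif role == "connector":
            targets = [k, (k + 1) % m]
            a = np.sqrt(0.9 / (len(targets) + len(targets) * (len(targets) - 1) * r))
            L[i, 0] = len(targets) * a * np.sqrt(r)
            for t in targets:
                L[i, 1 + t] = a * np.sqrt(1.0 - r)
        elif role == "network_hub":
            a = np.sqrt(0.9 / (m + m * (m - 1) * r))
            L[i, 0] = m * a * np.sqrt(r)
            L[i, 1:] = a * np.sqrt(1.0 - r)
        else:
            L[i, 0] = np.sqrt(w * r)
            L[i, 1 + k] = np.sqrt(w * (1.0 - r))
    unique_sd = np.sqrt(np.clip(1.0 - (L**2).sum(axis=1), 0.0, None))
    return L, unique_sd, {"modules": modules, "roles": roles}


_SYNTH_PHYLA = ("Phylum_A", "Phylum_B", "Phylum_C", "Phylum_D")


def _round_robin_taxonomy(taxa: list[str], modules: np.ndarray) -> pd.Series:
    """Synthetic lineages; phyla cycle round-robin within each module."""
    counters: dict[int, int] = {}
    lineages = []
    for taxon, module in zip(taxa, modules):
        j = counters.get(int(module), 0)
        counters[int(module)] = j + 1
        phylum = _SYNTH_PHYLA[j % len(_SYNTH_PHYLA)]
        lineages.append(
            f"{phylum};Class_{module};Order_{module};Family_{module};{taxon}_genus"
        )
    return pd.Series(lineages, index=taxa, name="lineage")


def generate_modular_abundances(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.Series, TruthBundle]:
    """Draw a taxa x samples count table with planted modules and hubs.

    Returns ``(counts, taxonomy, truth)``.  Column sums equal
    ``config.sequencing_depth`` exactly; the same config and seed always
    yield the identical table.
    """
    config.validate()
    if config.n_samples < 4:
        raise ValueError("n_samples must be >= 4 (downstream correlations undefined)")

    rng = np.random.default_rng(config.seed + _ABUNDANCE_STREAM)
    L, unique_sd, meta = _loading_matrix(config)

    # per-taxon baseline log-abundance: log-normal spread across taxa
    mu = rng.normal(0.0, 1.0, size=config.n_taxa)
    factors = rng.standard_normal((config.n_samples, L.shape[1]))
    noise = rng.standard_normal((config.n_samples, config.n_taxa))
    z = factors @ L.T + noise * unique_sd  # samples x taxa, unit-variance latent
    intensity = np.exp(mu + z)

    counts = np.empty((config.n_taxa, config.n_samples), dtype=np.int64)
    for s in range(config.n_samples):
        probs = intensity[s] / intensity[s].sum()
        counts[:, s] = rng.multinomial(config.sequencing_depth, probs)

    taxa = _taxon_ids(config.n_taxa)
    table = pd.DataFrame(counts, index=taxa, columns=_sample_ids(config.n_samples))
    table.index.name = "taxon_id"
    taxonomy = _round_robin_taxonomy(taxa, meta["modules"])
    truth = TruthBundle(
        module_assignment={t: int(m) for t, m in zip(taxa, meta["modules"])},
        planted_roles={taxa[i]: role for i, role in meta["roles"].items()},
    )
    return table, taxonomy, truth


def generate_soil_plant_table(
    config: ScenarioConfig, n: int
) -> tuple[pd.DataFrame, TruthBundle]:
    """Draw n samples of soil/plant/microbiome summary variables.

    Variables with no incoming path are exogenous standard normals; each
    endogenous variable is the stated linear combination of its parents
    plus a Gaussian disturbance with its configured sd.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    graph = _check_acyclic(config.path_coefficients)

    variables = list(config.disturbance_sd)
    for v in nx.topological_sort(graph) if graph.number_of_nodes() else []:
        if v not in variables:
            variables.append(v)

    rng = np.random.default_rng(config.seed + _FEATURES_STREAM)
    data: dict[str, np.ndarray] = {}
    order = list(nx.topological_sort(graph)) if graph.number_of_nodes() else []
    order += [v for v in variables if v not in order]
    for v in order:
        parents = list(graph.predecessors(v)) if v in graph else []
        if not parents:
            data[v] = rng.normal(0.0, 1.0, size=n)
        else:
            sd = float(config.disturbance_sd.get(v, 1.0))
            value = np.zeros(n)
            for p in parents:
                value += config.path_coefficients[(p, v)] * data[p]
            if sd > 0:
                value = value + rng.normal(0.0, sd, size=n)
            data[v] = value

    table = pd.DataFrame({v: data[v] for v in variables}, index=_sample_ids(n))
    table.index.name = "sample_id"
    truth = TruthBundle(true_paths=dict(config.path_coefficients))
    return table, truth


def write_fixture_bundle(
    directory: str | Path,
    abundance: pd.DataFrame,
    taxonomy: pd.Series,
    metadata: pd.DataFrame,
    truth: TruthBundle,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write the fixture files plus a checksum manifest; returns the manifest."""
    for name, tab in (("abundance", abundance), ("metadata", metadata)):
        if tab is None or len(tab) == 0 or tab.shape[1] == 0:
            raise ValueError(f"refusing to write empty {name} table")
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace it"
        )
    directory.mkdir(parents=True, exist_ok=True)

    io.write_abundance(abundance, directory / "asv_table.tsv")
    io.write_taxonomy(taxonomy, directory / "taxonomy.tsv")
    io.write_metadata(metadata, directory / "metadata.tsv")
    (directory / "truth.json").write_text(truth.to_json(), encoding="utf-8")

    manifest = {
        name: io.sha256_of(directory / name)
        for name in ("asv_table.tsv", "taxonomy.tsv", "metadata.tsv", "truth.json")
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def read_fixture_bundle(
    directory: str | Path, verify: bool = True
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, TruthBundle]:
    """Read a fixture bundle back, verifying manifest checksums by default."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    if verify:
        for name, digest in manifest.items():
            actual = io.sha256_of(directory / name)
            if actual != digest:
                raise ValueError(
                    f"checksum mismatch for {name}: manifest {digest[:12]}..., "
                    f"file {actual[:12]}..."
                )
    abundance = io.read_abundance(directory / "asv_table.tsv")
    taxonomy = io.read_taxonomy(directory / "taxonomy.tsv")
    metadata = io.read_metadata(directory / "metadata.tsv")
    truth = TruthBundle.from_json(
        (directory / "truth.json").read_text(encoding="utf-8")
    )
    return abundance, taxonomy, metadata, truth
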