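"""Config-driven orchestration: diversity -> network -> keystone roles ->
correlation screen -> path model, with a machine-readable run report.

The YAML config echoes every parameter into the run report so a report
alone suffices to reproduce a run.  Stage outputs are deterministic given
(config, seed); wall-clock timings live only in the run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import rhizonet
from rhizonet import diversity, envcorr, io, keystone, network, sem

logger = logging.getLogger("rhizonet")


@dataclass
class PipelineConfig:
    abundance: Path
    taxonomy: Path
    metadata: Path
    outdir: Path
    sem_model: Path | None = None
    sem_n: int | None = None
    min_prevalence: float = 0.2
    min_mean_relabund: float = 0.0
    corr_method: str = "spearman"
    rho_min: float = 0.6
    q_max: float = 0.05
    use_clr: bool = False
    z_threshold: float = keystone.Z_THRESHOLD
    p_threshold: float = keystone.P_THRESHOLD
    corr_variables: list[str] | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        base = Path(path).parent

        def resolve(p):
            return (base / p) if p and not Path(p).is_absolute() else p

        inputs = raw.get("inputs", {})
        cfg = cls(
            abundance=Path(resolve(inputs.get("abundance", "asv_table.tsv"))),
            taxonomy=Path(resolve(inputs.get("taxonomy", "taxonomy.tsv"))),
            metadata=Path(resolve(inputs.get("metadata", "metadata.tsv"))),
            outdir=Path(raw.get("outdir", "out")),
            sem_model=(
                Path(resolve(raw["sem"]["model"]))
                if raw.get("sem", {}).get("model")
                else None
            ),
            sem_n=raw.get("sem", {}).get("n"),
            min_prevalence=raw.get("filter", {}).get("min_prevalence", 0.2),
            min_mean_relabund=raw.get("filter", {}).get("min_mean_relabund", 0.0),
            corr_method=raw.get("network", {}).get("method", "spearman"),
            rho_min=raw.get("network", {}).get("rho_min", 0.6),
            q_max=raw.get("network", {}).get("q_max", 0.05),
            use_clr=raw.get("network", {}).get("clr", False),
            z_threshold=raw.get("roles", {}).get("z_threshold", keystone.Z_THRESHOLD),
            p_threshold=raw.get("roles", {}).get("p_threshold", keystone.P_THRESHOLD),
            corr_variables=raw.get("corr", {}).get("variables"),
            seed=raw.get("seed", 0),
            log_level=raw.get("log_level", "INFO"),
        )
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, value)
        return cfg

    def echo(self) -> dict:
        return {
            "abundance": str(self.abundance),
            "taxonomy": str(self.taxonomy),
            "metadata": str(self.metadata),
            "outdir": str(self.outdir),
            "sem_model": str(self.sem_model) if self.sem_model else None,
            "sem_n": self.sem_n,
            "min_prevalence": self.min_prevalence,
            "min_mean_relabund": self.min_mean_relabund,
            "corr_method": self.corr_method,
            "rho_min": self.rho_min,
            "q_max": self.q_max,
            "use_clr": self.use_clr,
            "z_threshold": self.z_threshold,
            "p_threshold": self.p_threshold,
            "corr_variables": self.corr_variables,
            "seed": self.seed,
        }


def validate_inputs(config: PipelineConfig) -> tuple[list[str], list[str]]:
    """Fail-fast input validation; returns (errors, warnings)."""
    errors: list[str] = []
    warns: list[str] = []
    for label, path in (
        ("abundance table", config.abundance),
        ("taxonomy table", config.taxonomy),
        ("metadata table", config.metadata),
    ):
        if not Path(path).exists():
            errors.append(f"{label} not found: {path}")
    if config.sem_model is not None and not Path(config.sem_model).exists():
        errors.append(f"SEM model spec not found: {config.sem_model}")
    if errors:
        return errors, warns

    abundance = io.read_abundance(config.abundance)
    taxonomy = io.read_taxonomy(config.taxonomy)
    metadata = io.read_metadata(config.metadata)

    missing_meta = [s for s in abundance.columns if s not in metadata.index]
    if missing_meta:
        errors.append(
            f"samples absent from metadata: {missing_meta}"
        )
    extra_meta = [s for s in metadata.index if s not in abundance.columns]
    if extra_meta:
        warns.append(f"metadata rows without abundance columns: {extra_meta}")
    unannotated = [t for t in abundance.index if t not in taxonomy.index]
    if unannotated:
        frac = len(unannotated) / len(abundance)
        warns.append(
            f"{len(unannotated)} / {len(abundance)} taxa "
            f"({frac:.0%}) lack taxonomy annotation"
        )
    if config.sem_model is not None:
        model = sem.parse_model(Path(config.sem_model).read_text(encoding="utf-8"))
        unknown = [v for v in model.variables if v not in metadata.columns]
        if unknown:
            errors.append(f"SEM variables missing from metadata: {unknown}")
    return errors, warns


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the run report (also written to disk)."""
    errors, warns = validate_inputs(config)
    for w in warns:
        logger.warning(w)
    if errors:
        raise ValueError("input validation failed: " + "; ".join(errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": rhizonet.__version__,
        "config": config.echo(),
        "input_checksums": {
            "abundance": io.sha256_of(config.abundance),
            "taxonomy": io.sha256_of(config.taxonomy),
            "metadata": io.sha256_of(config.metadata),
        },
        "stages": {},
        "warnings": warns,
    }

    abundance = io.read_abundance(config.abundance)
    taxonomy = io.read_taxonomy(config.taxonomy)
    metadata = io.read_metadata(config.metadata)
    state: dict = {}
    stage_outputs: dict[str, list[str]] = {}

    def run_stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            outputs = fn()
        except Exception:
            report["stages"][name] = {"status": "failed"}
            _write_report(report, outdir)
            logger.error("stage %s failed; partial outputs retained", name)
            raise
        report["stages"][name] = {
            "status": "ok",
            "outputs": outputs,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        stage_outputs[name] = outputs
        logger.info("stage %s done (%s)", name, ", ".join(outputs))

    def _diversity():
        alpha = diversity.alpha_diversity_table(abundance)
        alpha.to_csv(outdir / "diversity.tsv", sep="\t", lineterminator="\n")
        dm = diversity.bray_curtis(abundance)
        tree = diversity.upgma_tree(dm)
        (outdir / "upgma.nwk").write_text(
            diversity.to_newick(tree), encoding="utf-8"
        )
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            outdir / "bray_curtis.tsv", sep="\t", lineterminator="\n"
        )
        return ["diversity.tsv", "bray_curtis.tsv", "upgma.nwk"]

    def _network():
        filtered = network.filter_taxa(
            abundance, config.min_prevalence, config.min_mean_relabund
        )
        net = network.correlation_network(
            filtered,
            method=config.corr_method,
            rho_min=config.rho_min,
            q_max=config.q_max,
            use_clr=config.use_clr,
            taxonomy=taxonomy,
        )
        network.write_graphml(net, outdir / "network.graphml")
        network.write_edge_list(net, outdir / "edges.tsv")
        network.write_topology_report(net, outdir / "topology.json")
        state["net"] = net
        return ["network.graphml", "edges.tsv", "topology.json"]

    def _keystone():
        net = state["net"]
        partition, q = keystone.detect_modules(net, seed=config.seed)
        roles = keystone.node_roles(
            net,
            partition,
            taxonomy=taxonomy,
            z_threshold=config.z_threshold,
            p_threshold=config.p_threshold,
        )
        keystone.write_node_report(
            roles,
            outdir / "node_roles.tsv",
            z_threshold=config.z_threshold,
            p_threshold=config.p_threshold,
        )
        roles[["Zi", "Pi", "role"]].to_csv(
            outdir / "zipi.tsv", sep="\t", lineterminator="\n"
        )
        summary = keystone.aggregate_by_taxon(roles, taxonomy)
        summary.to_csv(outdir / "keystone_summary.tsv", sep="\t", lineterminator="\n")
        report["modularity_Q"] = q
        return ["node_roles.tsv", "zipi.tsv", "keystone_summary.tsv"]

    def _envcorr():
        corr = envcorr.spearman_matrix(metadata, variables=config.corr_variables)
        corr.write(outdir / "correlations.tsv")
        return ["correlations.tsv"]

    def _sem():
        model = sem.parse_model(
            Path(config.sem_model).read_text(encoding="utf-8")
        )
        fit = sem.fit_from_data(model, metadata, n=config.sem_n)
        fit.write_json(outdir / "sem.json")
        return ["sem.json"]

    run_stage("diversity", _diversity)
    run_stage("network", _network)
    run_stage("keystone", _keystone)
    run_stage("envcorr", _envcorr)
    if config.sem_model is not None:
        run_stage("sem", _sem)

    report["outputs"] = sorted(
        {o for outs in stage_outputs.values() for o in outs}
    )
    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
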