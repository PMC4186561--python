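"""End-to-end pipeline: inputs -> three networks -> reports.

The driver reads the five input datasets, builds the validated network,
optionally runs the promoter PWM scan and injects the predicted TFs into
the gene node set, derives both overlay subnetworks, and writes networks
(SIF + GraphML), per-node neighbor tables, self-adaptation loop lists, a
cross-network comparison report and a JSON run manifest.  Outputs are
deterministic for identical inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

from mirtfnet.analysis import (
    compare_networks,
    find_self_adaptation,
    neighbor_table,
    write_neighbor_table,
)
from mirtfnet.export import write_network
from mirtfnet.network import (
    HeteroRegNet,
    build_validated_network,
    derive_subnetwork,
    validate_layering,
)
from mirtfnet.pwm import (
    parse_transfac_matrices,
    predicted_tfs_for_targets,
    read_promoters_fasta,
    write_hits_tsv,
    scan_promoter,
    THRESHOLD_PROFILES,
)
from mirtfnet.relations import (
    NodeSet,
    read_alias_map,
    read_expansion_map,
    read_node_set,
    read_relation_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and knobs for one pipeline run.

    A config file is a flat ``key = value`` text file with ``#``
    comments; CLI flags override the file, which overrides defaults.
    """

    u1: str = ""
    u2: str = ""
    u3: str = ""
    u4_differential: str = ""
    u4_associated: str = ""
    u5_differential: str = ""
    u5_associated: str = ""
    promoters: str = ""
    matrices: str = ""
    alias_map: str = ""
    expansion_map: str = ""
    profile: str = "high"
    keep_singletons: bool = True
    nodes: tuple[str, ...] = ()
    out_dir: str = "mirtfnet_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        values: dict[str, object] = {}
        known = {f.name: f for f in fields(cls)}
        for lineno, line in enumerate(Path(path).open(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError(f"config {path}:{lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise PipelineError(f"config {path}:{lineno}: unknown key {key!r}")
            if key == "nodes":
                values[key] = tuple(v.strip() for v in raw.split(",") if v.strip())
            elif key == "keep_singletons":
                values[key] = raw.lower() in {"1", "true", "yes"}
            elif key == "seed":
                values[key] = int(raw)
            else:
                values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def validate(self) -> None:
        required = ("u1", "u2", "u3", "u4_differential", "u4_associated",
                    "u5_differential", "u5_associated")
        for name in required:
            value = getattr(self, name)
            if not value:
                raise PipelineError(f"input: missing required path for {name}")
            if not Path(value).exists():
                raise PipelineError(f"input: {name} path does not exist: {value}")
        for name in ("promoters", "matrices", "alias_map", "expansion_map"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise PipelineError(f"input: {name} path does not exist: {value}")
        if self.profile not in THRESHOLD_PROFILES:
            raise PipelineError(f"input: unknown threshold profile {self.profile!r}")


@dataclass
class PipelineResult:
    validated: HeteroRegNet
    differential: HeteroRegNet
    associated: HeteroRegNet
    predicted_tfs: dict[str, set[str]]
    loops: dict[str, list]
    manifest: dict
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the output bundle to ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from importlib.metadata import version as _pkg_version

    try:
        pkg_version = _pkg_version("mirtfnet")
    except Exception:
        pkg_version = "unknown"
    manifest: dict = {
        "version": pkg_version,
        "seed": config.seed,
        "profile": config.profile,
        "inputs": {
            name: getattr(config, name)
            for name in ("u1", "u2", "u3", "u4_differential", "u4_associated",
                         "u5_differential", "u5_associated", "promoters",
                         "matrices", "alias_map", "expansion_map")
            if getattr(config, name)
        },
        "stages": {},
    }

    alias = read_alias_map(config.alias_map) if config.alias_map else None
    expansion = (
        read_expansion_map(config.expansion_map) if config.expansion_map else None
    )

    try:
        u1 = read_relation_table(config.u1, "U1", alias, expansion)
        u2 = read_relation_table(config.u2, "U2", alias, expansion)
        u3 = read_relation_table(config.u3, "U3", alias, expansion)
        genes = read_node_set(config.u4_differential, config.u4_associated,
                              "U4", alias, expansion)
        mirnas = read_node_set(config.u5_differential, config.u5_associated,
                               "U5", alias, expansion)
    except Exception as exc:
        raise PipelineError(f"input: {exc}") from exc
    manifest["stages"]["input"] = {
        "u1_relations": len(u1), "u2_relations": len(u2), "u3_relations": len(u3),
        "genes_differential": len(genes.differential),
        "genes_associated": len(genes.associated),
        "mirnas_differential": len(mirnas.differential),
        "mirnas_associated": len(mirnas.associated),
    }

    try:
        validated = build_validated_network(u1, u2, u3)
    except Exception as exc:
        raise PipelineError(f"build: {exc}") from exc

    predicted: dict[str, set[str]] = {}
    if config.promoters and config.matrices:
        try:
            predicted = _scan_stage(config, u2, validated, out_dir)
        except Exception as exc:
            raise PipelineError(f"scan: {exc}") from exc
        # predicted TFs join the gene sets as associated genes
        predicted_tf_names = sorted(set().union(*predicted.values(), set()))
        genes = genes.with_added(predicted_tf_names, "associated")
        for tf in predicted_tf_names:
            if validated.has_node(tf):
                validated.graph.nodes[tf]["predicted_TF"] = True
        manifest["stages"]["scan"] = {
            "targets_with_hits": len(predicted),
            "predicted_tfs": predicted_tf_names,
        }

    try:
        differential = derive_subnetwork(
            validated, genes, mirnas, "differential", config.keep_singletons
        )
        associated = derive_subnetwork(
            validated, genes, mirnas, "associated", config.keep_singletons
        )
        layering = validate_layering(differential, associated, validated)
    except Exception as exc:
        raise PipelineError(f"derive: {exc}") from exc
    manifest["stages"]["networks"] = {
        net.label: {"nodes": net.n_nodes(), "edges": net.n_edges(),
                    **net.degree_counts()}
        for net in (validated, differential, associated)
    }
    manifest["stages"]["layering"] = layering.summary()

    nets = {"validated": validated, "differential": differential,
            "associated": associated}
    for label, net in nets.items():
        write_network(net, "SIF", out_dir / f"{label}.sif")
        write_network(net, "GraphML", out_dir / f"{label}.graphml")

    loops = {
        label: find_self_adaptation(net) for label, net in nets.items()
    }
    with (out_dir / "self_adaptation_loops.tsv").open("w") as fh:
        fh.write("network\tgene\tmirna\n")
        for label in ("differential", "associated", "validated"):
            for loop in loops[label]:
                fh.write(f"{label}\t{loop.gene}\t{loop.mirna}\n")
    manifest["stages"]["loops"] = {k: len(v) for k, v in loops.items()}

    for node in config.nodes:
        try:
            table = neighbor_table(node, differential, associated, validated)
        except KeyError as exc:
            raise PipelineError(f"analyze: {exc}") from exc
        safe = node.replace("/", "_")
        write_neighbor_table(table, out_dir / f"neighbors_{safe}.tsv")

    report = compare_networks(differential, associated, validated)
    report.write_tsv(out_dir / "comparison.tsv")
    (out_dir / "comparison.txt").write_text(report.to_text() + "\n")
    manifest["stages"]["comparison"] = {
        "gained_in_associated": len(report.gained_in_associated),
        "gained_in_validated": len(report.gained_in_validated),
    }

    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(validated, differential, associated, predicted,
                          loops, manifest, out_dir)


def _scan_stage(config, u2, validated, out_dir: Path) -> dict[str, set[str]]:
    matrices = parse_transfac_matrices(config.matrices)
    promoters = read_promoters_fasta(config.promoters, expected_length=None)
    whitelist = {rec.source for rec in u2}
    predicted = predicted_tfs_for_targets(
        promoters, matrices, whitelist, config.profile
    )
    core_t, matrix_t = THRESHOLD_PROFILES[config.profile]
    hits = []
    for promoter in promoters:
        for pwm in matrices:
            hits.extend(scan_promoter(promoter, pwm, core_t, matrix_t))
    write_hits_tsv(hits, out_dir / "tfbs_hits.tsv")
    return predicted
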