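"""Cross-network analysis: neighbor tables, feedback loops, host genes.

The comparisons mirror how regulatory roles are read off the three-layer
construction: for a node of interest, its predecessors (sources of
in-edges) and successors (targets of out-edges) are listed per network
and compared across layers; mutual-regulation pairs ("self-adaptation
associations", a miRNA targeting a gene that regulates it back) are the
heterotyped 2-cycles of TARGETS + REGULATES edges.  HOSTS edges are kept
out of the predecessor/successor lists and loop detection and reported
separately, since hosting is co-transcription rather than regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from mirtfnet.network import HeteroRegNet, validate_layering

REGULATORY_ETYPES = ("TARGETS", "REGULATES")
NETWORK_ORDER = ("differential", "associated", "validated")

NeighborList = tuple[tuple[str, str], ...]


@dataclass
class PredSuccTable:
    """Per-network predecessor/successor lists of one node.

    Each entry is a (neighbor, etype) pair; lists are deduplicated and
    sorted.  HOSTS relations are carried in the separate ``hosts_in``
    (genes hosting this miRNA) and ``hosts_out`` (miRNAs hosted by this
    gene) sections.
    """

    node: str
    predecessors: dict[str, NeighborList] = field(default_factory=dict)
    successors: dict[str, NeighborList] = field(default_factory=dict)
    hosts_in: dict[str, tuple[str, ...]] = field(default_factory=dict)
    hosts_out: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def in_degree(self, label: str, etype: str | None = None) -> int:
        return sum(
            1 for _, k in self.predecessors[label] if etype is None or k == etype
        )

    def out_degree(self, label: str, etype: str | None = None) -> int:
        return sum(
            1 for _, k in self.successors[label] if etype is None or k == etype
        )


@dataclass(frozen=True)
class SelfAdaptationLoop:
    """A gene and a miRNA that regulate each other.

    Evidence is the pair of edges (miRNA TARGETS gene, gene REGULATES
    miRNA) present in the labelled network.
    """

    gene: str
    mirna: str
    network_label: str

    @property
    def evidence(self) -> tuple[tuple[str, str, str], tuple[str, str, str]]:
        return (
            (self.mirna, self.gene, "TARGETS"),
            (self.gene, self.mirna, "REGULATES"),
        )


def neighbor_table(
    node: str,
    diff: HeteroRegNet,
    assoc: HeteroRegNet,
    validated: HeteroRegNet,
) -> PredSuccTable:
    """Build the three-network predecessor/successor table for ``node``."""
    if not validated.has_node(node):
        raise KeyError(f"node {node!r} not in the validated network")
    table = PredSuccTable(node)
    for label, net in zip(NETWORK_ORDER, (diff, assoc, validated)):
        if net.has_node(node):
            table.predecessors[label] = tuple(
                net.predecessors(node, REGULATORY_ETYPES)
            )
            table.successors[label] = tuple(net.successors(node, REGULATORY_ETYPES))
            table.hosts_in[label] = tuple(
                n for n, _ in net.predecessors(node, ("HOSTS",))
            )
            table.hosts_out[label] = tuple(
                n for n, _ in net.successors(node, ("HOSTS",))
            )
        else:
            table.predecessors[label] = ()
            table.successors[label] = ()
            table.hosts_in[label] = ()
            table.hosts_out[label] = ()
    return table


def write_neighbor_table(table: PredSuccTable, path: str | Path) -> None:
    """Write the table as TSV: three networks x predecessors/successors."""
    labels = NETWORK_ORDER
    columns = [
        [f"{n} ({k})" for n, k in table.predecessors[lab]] for lab in labels
    ] + [[f"{n} ({k})" for n, k in table.successors[lab]] for lab in labels]
    n_rows = max((len(c) for c in columns), default=0)
    with Path(path).open("w") as fh:
        fh.write(f"# node: {table.node}\n")
        fh.write(
            "\t".join(
                [f"predecessors_{lab}" for lab in labels]
                + [f"successors_{lab}" for lab in labels]
            )
            + "\n"
        )
        for i in range(n_rows):
            fh.write(
                "\t".join(c[i] if i < len(c) else "" for c in columns) + "\n"
            )
        if any(table.hosts_in[lab] or table.hosts_out[lab] for lab in labels):
            fh.write("# HOSTS relations\n")
            for lab in labels:
                if table.hosts_in[lab]:
                    fh.write(
                        f"hosted_by_{lab}\t" + ",".join(table.hosts_in[lab]) + "\n"
                    )
                if table.hosts_out[lab]:
                    fh.write(
                        f"hosts_{lab}\t" + ",".join(table.hosts_out[lab]) + "\n"
                    )


def _as_predicate(scope) -> Callable[[str], bool]:
    if scope is None:
        return lambda _: True
    if callable(scope):
        return scope
    if isinstance(scope, str):
        return lambda node: node == scope
    members = set(scope)
    return lambda node: node in members


def find_self_adaptation(
    net: HeteroRegNet, scope=None
) -> list[SelfAdaptationLoop]:
    """Find all heterotyped 2-cycles (mutual gene/miRNA regulation).

    ``scope`` optionally restricts the result to loops touching a node
    that passes the filter (a node id, a collection, or a predicate).
    """
    passes = _as_predicate(scope)
    loops = []
    for gene, mirna, etype in net.edges():
        if etype != "REGULATES":
            continue
        if net.has_edge(mirna, gene, "TARGETS") and (passes(gene) or passes(mirna)):
            loops.append(SelfAdaptationLoop(gene, mirna, net.label))
    loops.sort(key=lambda l: (l.gene, l.mirna))
    return loops


def host_gene_features(
    net: HeteroRegNet,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Hosts encoding >=2 miRNAs, and miRNAs encoded in >=2 hosts."""
    hosts: dict[str, list[str]] = {}
    mirnas: dict[str, list[str]] = {}
    for source, target, etype in net.edges():
        if etype != "HOSTS":
            continue
        hosts.setdefault(source, []).append(target)
        mirnas.setdefault(target, []).append(source)
    multi_mirna_hosts = {h: sorted(ms) for h, ms in hosts.items() if len(ms) >= 2}
    multi_host_mirnas = {m: sorted(hs) for m, hs in mirnas.items() if len(hs) >= 2}
    return multi_mirna_hosts, multi_host_mirnas


@dataclass
class ComparisonReport:
    """Similarities and differences between the three network layers."""

    edge_counts: dict[str, dict[str, int]]
    gained_in_associated: list[tuple[str, str, str]]  # associated \ differential
    gained_in_validated: list[tuple[str, str, str]]  # validated \ associated
    changed_nodes: dict[str, list[str]]  # per layer pair, nodes whose
    # regulatory neighborhood differs between the two layers

    def to_text(self) -> str:
        lines = ["edge counts per network (TARGETS/REGULATES/HOSTS):"]
        for label, counts in self.edge_counts.items():
            lines.append(
                f"  {label}: "
                + " ".join(f"{k}={v}" for k, v in sorted(counts.items()))
            )
        lines.append(
            f"edges gained at associated layer: {len(self.gained_in_associated)}"
        )
        lines.append(
            f"edges gained at validated layer: {len(self.gained_in_validated)}"
        )
        for pair, nodes in self.changed_nodes.items():
            lines.append(f"nodes with changed neighborhoods ({pair}): {len(nodes)}")
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("section\tfield\tvalue\n")
            for label, counts in self.edge_counts.items():
                for etype, n in sorted(counts.items()):
                    fh.write(f"edge_count\t{label}:{etype}\t{n}\n")
            for s, t, k in self.gained_in_associated:
                fh.write(f"gained_associated\t{k}\t{s}->{t}\n")
            for s, t, k in self.gained_in_validated:
                fh.write(f"gained_validated\t{k}\t{s}->{t}\n")
            for pair, nodes in self.changed_nodes.items():
                for node in nodes:
                    fh.write(f"changed_nodes\t{pair}\t{node}\n")


def _neighborhood(net: HeteroRegNet, node: str) -> frozenset:
    if not net.has_node(node):
        return frozenset()
    return frozenset(net.predecessors(node, REGULATORY_ETYPES)) | frozenset(
        ("out", n, k) for n, k in net.successors(node, REGULATORY_ETYPES)
    )


def compare_networks(
    diff: HeteroRegNet, assoc: HeteroRegNet, validated: HeteroRegNet
) -> ComparisonReport:
    """Compare the three layers; raises if the layering is violated."""
    validate_layering(diff, assoc, validated, strict=True)
    edge_counts = {
        label: net.degree_counts()
        for label, net in zip(NETWORK_ORDER, (diff, assoc, validated))
    }
    gained_assoc = sorted(assoc.edge_keys() - diff.edge_keys())
    gained_valid = sorted(validated.edge_keys() - assoc.edge_keys())
    changed: dict[str, list[str]] = {}
    for pair, (lo, hi) in {
        "differential->associated": (diff, assoc),
        "associated->validated": (assoc, validated),
    }.items():
        changed[pair] = sorted(
            node
            for node in hi.nodes()
            if _neighborhood(lo, node) != _neighborhood(hi, node)
        )
    return ComparisonReport(edge_counts, gained_assoc, gained_valid, changed)
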