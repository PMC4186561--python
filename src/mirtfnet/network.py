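"""Heterogeneous regulatory network construction and overlay derivation.

The validated network is the union of all database-supported relations:
``TARGETS`` (miRNA silences/degrades a gene's transcript), ``REGULATES``
(a transcription factor activates or represses a miRNA gene) and
``HOSTS`` (a gene carries a miRNA in its locus; both are co-transcribed).
Overlay subnetworks are induced from it by mapping differential or
disease-associated gene/miRNA sets onto the node set:

* a TARGETS or REGULATES edge survives iff *both* endpoints belong to
  the level's sets;
* a HOSTS edge is keyed on its miRNA only -- the host gene is admitted
  regardless of its own expression status and flagged ``host_gene``
  (a non-differential host of a differential miRNA still matters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from mirtfnet.relations import (
    NODE_CLASS_BY_ETYPE,
    NodeSet,
    RelationSet,
)

NODE_FLAGS = ("differential", "associated", "predicted_TF", "host_gene")
LEVELS = ("differential", "associated")


class ConsistencyError(ValueError):
    """A node is used with two incompatible classes (gene and miRNA)."""


@dataclass
class HeteroRegNet:
    """Typed directed multigraph over gene and miRNA nodes.

    Thin wrapper around a :class:`networkx.MultiDiGraph` whose edge keys
    are the edge types, which makes (source, target, etype) unique by
    construction.  ``label`` identifies which of the three networks this
    is: ``validated``, ``differential`` or ``associated``.
    """

    label: str = "validated"
    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    # -- construction -------------------------------------------------

    def add_node(self, node: str, node_class: str, **flags: bool) -> None:
        if node_class not in {"gene", "miRNA"}:
            raise ValueError(f"unknown node class {node_class!r}")
        existing = self.graph.nodes.get(node)
        if existing is not None and existing["node_class"] != node_class:
            raise ConsistencyError(
                f"node {node!r} used as both {existing['node_class']} "
                f"and {node_class}"
            )
        if existing is None:
            attrs = {f: False for f in NODE_FLAGS}
            attrs["node_class"] = node_class
            self.graph.add_node(node, **attrs)
        for flag, value in flags.items():
            if flag not in NODE_FLAGS:
                raise ValueError(f"unknown node flag {flag!r}")
            if value:
                self.graph.nodes[node][flag] = True
        # differential membership implies associated membership
        if self.graph.nodes[node]["differential"]:
            self.graph.nodes[node]["associated"] = True

    def add_edge(
        self,
        source: str,
        target: str,
        etype: str,
        provenance: Iterable[str] = (),
    ) -> None:
        src_class, tgt_class = NODE_CLASS_BY_ETYPE[etype]
        self.add_node(source, src_class)
        self.add_node(target, tgt_class)
        if etype == "HOSTS":
            self.graph.nodes[source]["host_gene"] = True
        prov = set(provenance)
        if self.graph.has_edge(source, target, key=etype):
            prov |= self.graph.edges[source, target, etype].get("provenance", set())
        self.graph.add_edge(source, target, key=etype, provenance=frozenset(prov))

    # -- queries ------------------------------------------------------

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def node_class(self, node: str) -> str:
        return self.graph.nodes[node]["node_class"]

    def node_flags(self, node: str) -> dict[str, bool]:
        data = self.graph.nodes[node]
        return {f: bool(data[f]) for f in NODE_FLAGS}

    def has_node(self, node: str) -> bool:
        return node in self.graph

    def edges(self) -> Iterator[tuple[str, str, str]]:
        """Iterate (source, target, etype), lexicographic by (etype, s, t)."""
        return iter(
            sorted(self.graph.edges(keys=True), key=lambda e: (e[2], e[0], e[1]))
        )

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {(s, t, k) for s, t, k in self.graph.edges(keys=True)}

    def has_edge(self, source: str, target: str, etype: str) -> bool:
        return self.graph.has_edge(source, target, key=etype)

    def predecessors(
        self, node: str, etypes: Iterable[str] | None = None
    ) -> list[tuple[str, str]]:
        """Sorted (neighbor, etype) pairs over in-edges of ``node``."""
        wanted = None if etypes is None else set(etypes)
        pairs = {
            (s, k)
            for s, _, k in self.graph.in_edges(node, keys=True)
            if wanted is None or k in wanted
        }
        return sorted(pairs)

    def successors(
        self, node: str, etypes: Iterable[str] | None = None
    ) -> list[tuple[str, str]]:
        """Sorted (neighbor, etype) pairs over out-edges of ``node``."""
        wanted = None if etypes is None else set(etypes)
        pairs = {
            (t, k)
            for _, t, k in self.graph.out_edges(node, keys=True)
            if wanted is None or k in wanted
        }
        return sorted(pairs)

    def degree_counts(self) -> dict[str, int]:
        """Edge count per etype."""
        counts = {etype: 0 for etype in NODE_CLASS_BY_ETYPE}
        for _, _, k in self.graph.edges(keys=True):
            counts[k] += 1
        return counts

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_validated_network(
    u1: RelationSet, u2: RelationSet, u3: RelationSet
) -> HeteroRegNet:
    """Combine the three relation sets into the validated network.

    The node set is the union of all relation endpoints and the edge set
    the union of all relations; host-gene sources are flagged.  A symbol
    appearing both as a gene and as a miRNA endpoint raises a
    :class:`ConsistencyError` naming every offender.
    """
    for rs, kind in ((u1, "U1"), (u2, "U2"), (u3, "U3")):
        if rs.kind != kind:
            raise ValueError(f"expected kind {kind}, got {rs.kind}")

    # detect class conflicts up front so the error can list all offenders
    seen: dict[str, str] = {}
    offenders: dict[str, set[str]] = {}
    for rs in (u1, u2, u3):
        src_class, tgt_class = NODE_CLASS_BY_ETYPE[rs.etype]
        for rec in rs:
            for node, cls in ((rec.source, src_class), (rec.target, tgt_class)):
                prev = seen.setdefault(node, cls)
                if prev != cls:
                    offenders.setdefault(node, set()).update({prev, cls})
    if offenders:
        listing = ", ".join(
            f"{n} ({'/'.join(sorted(c))})" for n, c in sorted(offenders.items())
        )
        raise ConsistencyError(f"nodes with conflicting classes: {listing}")

    net = HeteroRegNet(label="validated")
    for rs in (u1, u2, u3):
        for rec in rs:
            net.add_edge(rec.source, rec.target, rec.etype, rec.provenance)
    return net


def derive_subnetwork(
    validated: HeteroRegNet,
    genes: NodeSet,
    mirnas: NodeSet,
    level: str,
    keep_singletons: bool = True,
) -> HeteroRegNet:
    """Induce the overlay subnetwork at ``level`` from the validated one.

    ``keep_singletons`` controls whether level members that end up with
    no retained edge are kept as isolated nodes (they exist in the data
    model even when omitted from drawn figures).
    """
    if validated.label != "validated":
        raise ValueError("derive_subnetwork requires the validated network")
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")

    gene_set = genes.level(level)
    mirna_set = mirnas.level(level)
    net = HeteroRegNet(label=level)

    for source, target, etype in validated.edges():
        if etype == "TARGETS":
            keep = source in mirna_set and target in gene_set
        elif etype == "REGULATES":
            keep = source in gene_set and target in mirna_set
        else:  # HOSTS: keyed on the miRNA endpoint only
            keep = target in mirna_set
        if keep:
            prov = validated.graph.edges[source, target, etype]["provenance"]
            net.add_edge(source, target, etype, prov)

    if keep_singletons:
        for node in sorted(gene_set):
            if not net.has_node(node):
                net.add_node(node, "gene")
        for node in sorted(mirna_set):
            if not net.has_node(node):
                net.add_node(node, "miRNA")

    _apply_membership_flags(net, genes, mirnas)
    return net


def _apply_membership_flags(net: HeteroRegNet, genes: NodeSet, mirnas: NodeSet) -> None:
    for node in net.nodes():
        members = genes if net.node_class(node) == "gene" else mirnas
        if node in members.differential:
            net.graph.nodes[node]["differential"] = True
            net.graph.nodes[node]["associated"] = True
        elif node in members.associated:
            net.graph.nodes[node]["associated"] = True


@dataclass
class LayeringReport:
    """Containment check of the three-network layering.

    The differential network must be contained in the associated one,
    which must be contained in the validated one, both edge-wise and
    (host genes aside) node-wise.
    """

    diff_only_edges: list[tuple[str, str, str]]
    assoc_only_edges: list[tuple[str, str, str]]
    diff_only_nodes: list[str]
    assoc_only_nodes: list[str]

    @property
    def ok(self) -> bool:
        return not (
            self.diff_only_edges
            or self.assoc_only_edges
            or self.diff_only_nodes
            or self.assoc_only_nodes
        )

    def summary(self) -> str:
        if self.ok:
            return "layering ok: differential <= associated <= validated"
        parts = []
        if self.diff_only_edges:
            parts.append(f"{len(self.diff_only_edges)} edges in differential only")
        if self.assoc_only_edges:
            parts.append(f"{len(self.assoc_only_edges)} edges in associated only")
        if self.diff_only_nodes:
            parts.append(f"{len(self.diff_only_nodes)} nodes in differential only")
        if self.assoc_only_nodes:
            parts.append(f"{len(self.assoc_only_nodes)} nodes in associated only")
        return "layering violated: " + "; ".join(parts)


def validate_layering(
    diff: HeteroRegNet,
    assoc: HeteroRegNet,
    validated: HeteroRegNet,
    strict: bool = False,
) -> LayeringReport:
    """Check edge and node containment across the three networks.

    Host genes are exempt from the node containment check (a host enters
    a layer through its miRNA, not through its own membership).  With
    ``strict`` a violation raises instead of just being reported.
    """
    for net, expected in ((diff, "differential"), (assoc, "associated"),
                          (validated, "validated")):
        if net.label != expected:
            raise ValueError(f"expected a {expected} network, got {net.label!r}")

    diff_edges = diff.edge_keys()
    assoc_edges = assoc.edge_keys()
    validated_edges = validated.edge_keys()

    def _non_host_nodes(net: HeteroRegNet) -> set[str]:
        return {n for n in net.graph.nodes if not net.graph.nodes[n]["host_gene"]}

    report = LayeringReport(
        diff_only_edges=sorted(diff_edges - assoc_edges),
        assoc_only_edges=sorted(assoc_edges - validated_edges),
        diff_only_nodes=sorted(_non_host_nodes(diff) - set(assoc.graph.nodes)),
        assoc_only_nodes=sorted(
            n
            for n in _non_host_nodes(assoc)
            if n not in validated.graph and assoc.graph.degree(n) > 0
        ),
    )
    if strict and not report.ok:
        raise ValueError(report.summary())
    return report
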