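"""Network writers: SIF and GraphML with deterministic ordering."""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from mirtfnet.network import NODE_FLAGS, HeteroRegNet


def write_network(net: HeteroRegNet, fmt: str, path: str | Path) -> Path:
    """Write ``net`` to ``path`` in SIF or GraphML form.

    Ordering is lexicographic by (etype, source, target) in both formats
    so identical networks produce byte-identical files.
    """
    path = Path(path)
    fmt = fmt.upper()
    if fmt == "SIF":
        _write_sif(net, path)
    elif fmt == "GRAPHML":
        _write_graphml(net, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return path


def _write_sif(net: HeteroRegNet, path: Path) -> None:
    with path.open("w") as fh:
        for source, target, etype in net.edges():
            fh.write(f"{source}\t{etype}\t{target}\n")


def _ordered_copy(net: HeteroRegNet) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph(label=net.label)
    for node in net.nodes():
        data = net.graph.nodes[node]
        g.add_node(node, node_class=data["node_class"],
                   **{f: bool(data[f]) for f in NODE_FLAGS})
    for source, target, etype in net.edges():
        prov = net.graph.edges[source, target, etype].get("provenance", frozenset())
        g.add_edge(source, target, key=etype, etype=etype,
                   provenance=",".join(sorted(prov)))
    return g


def _write_graphml(net: HeteroRegNet, path: Path) -> None:
    nx.write_graphml(_ordered_copy(net), path)


def read_graphml(path: str | Path) -> HeteroRegNet:
    """Read a GraphML file written by :func:`write_network` back."""
    g = nx.read_graphml(path, force_multigraph=True)
    net = HeteroRegNet(label=g.graph.get("label", "validated"))
    for node, data in g.nodes(data=True):
        net.add_node(node, data["node_class"],
                     **{f: bool(data.get(f, False)) for f in NODE_FLAGS})
    for source, target, _, data in g.edges(keys=True, data=True):
        prov = [p for p in data.get("provenance", "").split(",") if p]
        net.add_edge(source, target, data["etype"], prov)
    return net
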