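"""Loaders for the packaged neighbor-table fixtures.

The fixtures under ``data/tables`` transcribe published per-node
predecessor/successor tables (PTEN, hsa-miR-20a and E2F3) into relation
tables and node-set files; loading one rebuilds the validated network and
both overlays for that node's neighborhood.  See the README next to the
data for what each fixture encodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from mirtfnet.network import (
    HeteroRegNet,
    build_validated_network,
    derive_subnetwork,
)
from mirtfnet.relations import NodeSet, read_node_set, read_relation_table

#: fixture name -> the node whose table it transcribes
FIXTURE_NODES = {
    "pten": "PTEN",
    "mir20a": "hsa-miR-20a",
    "e2f3": "E2F3",
}


@dataclass
class TableFixture:
    """One fixture: input sets plus the three derived networks."""

    name: str
    node: str
    genes: NodeSet
    mirnas: NodeSet
    validated: HeteroRegNet
    differential: HeteroRegNet
    associated: HeteroRegNet


def available_fixtures() -> list[str]:
    return sorted(FIXTURE_NODES)


def fixture_dir(name: str) -> Path:
    if name not in FIXTURE_NODES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {available_fixtures()}"
        )
    return Path(str(resources.files("mirtfnet").joinpath("data", "tables", name)))


def load_table_fixture(name: str, keep_singletons: bool = True) -> TableFixture:
    """Load a packaged fixture and derive its three networks."""
    d = fixture_dir(name)
    u1 = read_relation_table(d / "u1.tsv", "U1")
    u2 = read_relation_table(d / "u2.tsv", "U2")
    u3 = read_relation_table(d / "u3.tsv", "U3")
    genes = read_node_set(
        d / "genes_differential.txt", d / "genes_associated.txt", "U4"
    )
    mirnas = read_node_set(
        d / "mirnas_differential.txt", d / "mirnas_associated.txt", "U5"
    )
    validated = build_validated_network(u1, u2, u3)
    differential = derive_subnetwork(
        validated, genes, mirnas, "differential", keep_singletons
    )
    associated = derive_subnetwork(
        validated, genes, mirnas, "associated", keep_singletons
    )
    return TableFixture(
        name, FIXTURE_NODES[name], genes, mirnas,
        validated, differential, associated,
    )
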