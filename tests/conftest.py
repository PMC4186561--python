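"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from mirtfnet import (
    HeteroRegNet,
    NodeSet,
    RelationRecord,
    RelationSet,
    build_validated_network,
    derive_subnetwork,
    load_table_fixture,
)
from mirtfnet.pwm import make_pwm


# ---------------------------------------------------------------------------
# Oracles (deliberately naive, independent of the library's code paths)


def brute_force_loops(net: HeteroRegNet) -> set[tuple[str, str]]:
    """All (gene, miRNA) pairs with both a TARGETS and a REGULATES edge,
    found by enumerating every node pair."""
    genes = [n for n in net.nodes() if net.node_class(n) == "gene"]
    mirnas = [n for n in net.nodes() if net.node_class(n) == "miRNA"]
    found = set()
    for g in genes:
        for m in mirnas:
            if net.has_edge(m, g, "TARGETS") and net.has_edge(g, m, "REGULATES"):
                found.add((g, m))
    return found


def brute_force_subnetwork_edges(
    validated: HeteroRegNet, gene_set: set, mirna_set: set
) -> set[tuple[str, str, str]]:
    """Edge-retention rule recomputed by plain set arithmetic."""
    kept = set()
    for s, t, k in validated.edge_keys():
        if k == "TARGETS" and s in mirna_set and t in gene_set:
            kept.add((s, t, k))
        elif k == "REGULATES" and s in gene_set and t in mirna_set:
            kept.add((s, t, k))
        elif k == "HOSTS" and t in mirna_set:
            kept.add((s, t, k))
    return kept


def random_relation_sets(
    rng: np.random.Generator,
    n_genes: int = 8,
    n_mirnas: int = 6,
    p: float = 0.25,
) -> tuple[RelationSet, RelationSet, RelationSet]:
    """Small random U1/U2/U3 triples for property tests."""
    genes = [f"G{i}" for i in range(n_genes)]
    mirnas = [f"hsa-miR-t{i}" for i in range(n_mirnas)]
    u1 = RelationSet(
        "U1",
        [
            RelationRecord(m, g, "TARGETS")
            for m in mirnas
            for g in genes
            if rng.random() < p
        ],
    )
    u2 = RelationSet(
        "U2",
        [
            RelationRecord(g, m, "REGULATES")
            for g in genes[: max(2, n_genes // 2)]
            for m in mirnas
            if rng.random() < p
        ],
    )
    u3 = RelationSet(
        "U3",
        [
            RelationRecord(g, m, "HOSTS")
            for g in genes[-2:]
            for m in mirnas
            if rng.random() < p
        ],
    )
    return u1, u2, u3


def random_node_sets(
    rng: np.random.Generator, u1: RelationSet, u2: RelationSet, u3: RelationSet
) -> tuple[NodeSet, NodeSet]:
    genes, mirnas = set(), set()
    for rs in (u1, u2, u3):
        for rec in rs:
            if rec.etype == "TARGETS":
                mirnas.add(rec.source)
                genes.add(rec.target)
            else:
                genes.add(rec.source)
                mirnas.add(rec.target)
    gene_assoc = {g for g in genes if rng.random() < 0.7}
    gene_diff = {g for g in gene_assoc if rng.random() < 0.5}
    mirna_assoc = {m for m in mirnas if rng.random() < 0.7}
    mirna_diff = {m for m in mirna_assoc if rng.random() < 0.5}
    return (
        NodeSet("U4", frozenset(gene_diff), frozenset(gene_assoc)),
        NodeSet("U5", frozenset(mirna_diff), frozenset(mirna_assoc)),
    )


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def pten_fixture():
    return load_table_fixture("pten")


@pytest.fixture(scope="session")
def mir20a_fixture():
    return load_table_fixture("mir20a")


@pytest.fixture(scope="session")
def e2f3_fixture():
    return load_table_fixture("e2f3")


@pytest.fixture
def simple_pwm():
    """8-position matrix with one dominant base per position (consensus
    ACGATACG), strong enough that random 1-kb backgrounds stay silent at
    high thresholds."""
    counts = np.zeros((8, 4))
    for i, base in enumerate("ACGATACG"):
        counts[i, "ACGT".index(base)] = 20.0
    return make_pwm("V$TEST_01", "E2F1", counts)


@pytest.fixture
def tiny_validated():
    """Hand-built validated network used across unit tests."""
    u1 = RelationSet(
        "U1",
        [
            RelationRecord("hsa-miR-19a", "PTEN", "TARGETS"),
            RelationRecord("hsa-miR-21", "PTEN", "TARGETS"),
            RelationRecord("hsa-miR-222", "PTEN", "TARGETS"),
            RelationRecord("hsa-miR-149", "AKT1", "TARGETS"),
        ],
    )
    u2 = RelationSet(
        "U2",
        [
            RelationRecord("PTEN", "hsa-miR-19a", "REGULATES"),
            RelationRecord("PTEN", "hsa-miR-25", "REGULATES"),
            RelationRecord("NFKB1", "hsa-miR-155", "REGULATES"),
        ],
    )
    u3 = RelationSet(
        "U3",
        [
            RelationRecord("RTL1", "hsa-miR-127", "HOSTS"),
            RelationRecord("GPC1", "hsa-miR-149", "HOSTS"),
        ],
    )
    return build_validated_network(u1, u2, u3)


@pytest.fixture
def tiny_node_sets():
    genes = NodeSet("U4", frozenset({"PTEN"}), frozenset({"PTEN", "AKT1", "NFKB1"}))
    mirnas = NodeSet(
        "U5",
        frozenset({"hsa-miR-19a", "hsa-miR-21", "hsa-miR-127"}),
        frozenset(
            {"hsa-miR-19a", "hsa-miR-21", "hsa-miR-127", "hsa-miR-149",
             "hsa-miR-25"}
        ),
    )
    return genes, mirnas


@pytest.fixture
def tiny_layers(tiny_validated, tiny_node_sets):
    genes, mirnas = tiny_node_sets
    diff = derive_subnetwork(tiny_validated, genes, mirnas, "differential")
    assoc = derive_subnetwork(tiny_validated, genes, mirnas, "associated")
    return diff, assoc, tiny_validated
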