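"""Synthetic relation databases, node sets and promoters with ground truth.

The generator emulates the relational structure of the five input
datasets: random bipartite TARGETS (miRNA -> gene) and REGULATES
(TF -> miRNA) relations at configurable densities, HOSTS relations in
which some hosts carry several miRNAs and some miRNAs sit in several
hosts, and two-level node sets (differential inside associated).  A
configurable number of mutual-regulation 2-cycles is planted and
recorded, and planted-loop endpoints are forced into the differential
sets so that the loops survive overlay derivation at every layer.
Promoters are uniform-background sequences with optionally planted
matrix consensus sites.

Everything is a pure function of the configuration and seed: the same
inputs give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from mirtfnet.pwm import PWM, reverse_complement
from mirtfnet.relations import (
    NodeSet,
    RelationRecord,
    RelationSet,
    write_relation_table,
)


class ConfigError(ValueError):
    """The synthetic configuration is internally infeasible."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic regulatory universe.

    Defaults are sized like the study's differential network (tens of
    genes, a few dozen miRNAs, a handful of TFs and hosts) so that the
    derived overlays are small but structurally non-trivial.
    """

    n_genes: int = 60
    n_mirnas: int = 40
    n_tfs: int = 10
    n_hosts: int = 12
    p_targets: float = 0.05
    p_regulates: float = 0.05
    p_hosts: float = 0.08
    frac_differential: float = 0.4
    frac_associated: float = 0.7
    n_planted_loops: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_targets", "p_regulates", "p_hosts",
                     "frac_differential", "frac_associated"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.frac_differential > self.frac_associated:
            raise ConfigError(
                "frac_differential must not exceed frac_associated"
            )
        if self.n_tfs > self.n_genes or self.n_hosts > self.n_genes:
            raise ConfigError("TF/host counts cannot exceed n_genes")
        if self.n_planted_loops > self.n_tfs * self.n_mirnas:
            raise ConfigError(
                f"cannot plant {self.n_planted_loops} loops with only "
                f"{self.n_tfs} TFs x {self.n_mirnas} miRNAs"
            )

    @property
    def genes(self) -> list[str]:
        return [f"SG{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def mirnas(self) -> list[str]:
        return [f"hsa-miR-s{i:03d}" for i in range(1, self.n_mirnas + 1)]

    @property
    def tfs(self) -> list[str]:
        """TFs are the first ``n_tfs`` genes."""
        return self.genes[: self.n_tfs]

    @property
    def hosts(self) -> list[str]:
        """Host genes are the last ``n_hosts`` genes."""
        return self.genes[self.n_genes - self.n_hosts:]


@dataclass
class GroundTruth:
    """What was planted, for exact-recovery checks downstream."""

    planted_loops: list[tuple[str, str]] = field(default_factory=list)
    planted_tfbs: list[tuple[str, str, int, str]] = field(default_factory=list)
    node_labels: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("section\tfields\n")
            for gene, mirna in sorted(self.planted_loops):
                fh.write(f"planted_loop\t{gene}\t{mirna}\n")
            for gene, matrix_id, pos, strand in sorted(self.planted_tfbs):
                fh.write(f"planted_tfbs\t{gene}\t{matrix_id}\t{pos}\t{strand}\n")
            for kind in sorted(self.node_labels):
                for level in sorted(self.node_labels[kind]):
                    members = ",".join(sorted(self.node_labels[kind][level]))
                    fh.write(f"node_set\t{kind}\t{level}\t{members}\n")


def _bernoulli_pairs(
    rng: np.random.Generator,
    sources: Sequence[str],
    targets: Sequence[str],
    p: float,
) -> list[tuple[str, str]]:
    if not sources or not targets or p == 0.0:
        return []
    mask = rng.random((len(sources), len(targets))) < p
    return [
        (sources[i], targets[j]) for i, j in np.argwhere(mask)
    ]


def generate_relation_db(
    cfg: SynthConfig, out_dir: str | Path
) -> tuple[Path, Path, Path, GroundTruth]:
    """Emit u1/u2/u3 TSV files plus the ground truth of what was planted.

    HOSTS relations are drawn at ``p_hosts`` and then patched so that,
    whenever the universe is large enough, at least one host carries two
    miRNAs and at least one miRNA has two hosts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    gt = GroundTruth()

    targets_pairs = set(
        _bernoulli_pairs(rng, cfg.mirnas, cfg.genes, cfg.p_targets)
    )
    regulates_pairs = set(
        _bernoulli_pairs(rng, cfg.tfs, cfg.mirnas, cfg.p_regulates)
    )

    # plant mutual-regulation 2-cycles on distinct (TF, miRNA) pairs
    all_pairs = [(tf, m) for tf in cfg.tfs for m in cfg.mirnas]
    idx = rng.choice(len(all_pairs), size=cfg.n_planted_loops, replace=False)
    for i in sorted(int(j) for j in idx):
        tf, mirna = all_pairs[i]
        targets_pairs.add((mirna, tf))
        regulates_pairs.add((tf, mirna))
        gt.planted_loops.append((tf, mirna))

    hosts_pairs = set(
        _bernoulli_pairs(rng, cfg.hosts, cfg.mirnas, cfg.p_hosts)
    )
    if cfg.n_hosts >= 1 and cfg.n_mirnas >= 2 and cfg.p_hosts > 0:
        hosts_pairs.add((cfg.hosts[0], cfg.mirnas[0]))
        hosts_pairs.add((cfg.hosts[0], cfg.mirnas[1]))
    if cfg.n_hosts >= 2 and cfg.n_mirnas >= 1 and cfg.p_hosts > 0:
        hosts_pairs.add((cfg.hosts[0], cfg.mirnas[0]))
        hosts_pairs.add((cfg.hosts[1], cfg.mirnas[0]))

    paths = []
    for kind, etype, pairs, prov in (
        ("U1", "TARGETS", targets_pairs, "synthetic-targets"),
        ("U2", "REGULATES", regulates_pairs, "synthetic-tf"),
        ("U3", "HOSTS", hosts_pairs, "synthetic-hosts"),
    ):
        rs = RelationSet(
            kind,
            [
                RelationRecord(s, t, etype, frozenset({prov}))
                for (s, t) in sorted(pairs)
            ],
        )
        path = out_dir / f"{kind.lower()}.tsv"
        write_relation_table(rs, path)
        paths.append(path)

    return paths[0], paths[1], paths[2], gt


def _sample_levels(
    rng: np.random.Generator,
    universe: Sequence[str],
    frac_differential: float,
    frac_associated: float,
    forced_differential: set[str],
) -> tuple[frozenset[str], frozenset[str]]:
    n = len(universe)
    n_assoc = int(round(frac_associated * n))
    n_diff = int(round(frac_differential * n))
    forced = sorted(forced_differential)
    rest = [u for u in universe if u not in forced_differential]
    order = [rest[int(i)] for i in rng.permutation(len(rest))]
    associated = set(forced) | set(order[: max(n_assoc - len(forced), 0)])
    # differential drawn inside the associated set, forced members first
    assoc_rest = [u for u in order if u in associated]
    differential = set(forced) | set(assoc_rest[: max(n_diff - len(forced), 0)])
    return frozenset(differential), frozenset(associated)


def generate_node_sets(
    cfg: SynthConfig, gt: GroundTruth, out_dir: str | Path
) -> tuple[tuple[Path, Path], tuple[Path, Path]]:
    """Emit u4 (genes) and u5 (miRNAs) differential/associated files.

    Planted-loop endpoints are forced into the differential sets so the
    planted 2-cycles survive derivation at both overlay levels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)

    forced_genes = {g for g, _ in gt.planted_loops}
    forced_mirnas = {m for _, m in gt.planted_loops}
    gene_diff, gene_assoc = _sample_levels(
        rng, cfg.genes, cfg.frac_differential, cfg.frac_associated, forced_genes
    )
    mirna_diff, mirna_assoc = _sample_levels(
        rng, cfg.mirnas, cfg.frac_differential, cfg.frac_associated, forced_mirnas
    )
    gt.node_labels = {
        "U4": {"differential": gene_diff, "associated": gene_assoc},
        "U5": {"differential": mirna_diff, "associated": mirna_assoc},
    }

    written: list[Path] = []
    for name, members in (
        ("u4_differential", gene_diff),
        ("u4_associated", gene_assoc),
        ("u5_differential", mirna_diff),
        ("u5_associated", mirna_assoc),
    ):
        path = out_dir / f"{name}.txt"
        with path.open("w") as fh:
            fh.write(f"# synthetic node set: {name}\n")
            for member in sorted(members):
                fh.write(member + "\n")
        written.append(path)
    return (written[0], written[1]), (written[2], written[3])


def node_sets_from_ground_truth(gt: GroundTruth) -> tuple[NodeSet, NodeSet]:
    """Build in-memory NodeSets from a generated ground truth."""
    return (
        NodeSet("U4", gt.node_labels["U4"]["differential"],
                gt.node_labels["U4"]["associated"]),
        NodeSet("U5", gt.node_labels["U5"]["differential"],
                gt.node_labels["U5"]["associated"]),
    )


def generate_promoters(
    matrices: Sequence[PWM],
    n_seqs: int,
    plant_rate: float,
    seed: int,
    out_path: str | Path,
    length: int = 1000,
) -> tuple[Path, list[tuple[str, str, int, str]]]:
    """Emit a promoter FASTA with consensus sites planted at ``plant_rate``.

    Backgrounds are i.i.d. uniform over A/C/G/T.  Each planted site
    replaces a window with a matrix's consensus (reverse-complemented on
    the minus strand); the recorded position is the forward-strand start.
    """
    if plant_rate > 0 and not matrices:
        raise ValueError("plant_rate > 0 requires at least one matrix")
    if not 0.0 <= plant_rate <= 1.0:
        raise ValueError("plant_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    planted: list[tuple[str, str, int, str]] = []
    out_path = Path(out_path)
    with out_path.open("w") as fh:
        for i in range(1, n_seqs + 1):
            gene = f"SP{i:04d}"
            seq = rng.choice(list("ACGT"), size=length)
            if matrices and rng.random() < plant_rate:
                pwm = matrices[int(rng.integers(len(matrices)))]
                site = pwm.consensus
                strand = "+" if rng.random() < 0.5 else "-"
                pos = int(rng.integers(0, length - len(site) + 1))
                inserted = site if strand == "+" else reverse_complement(site)
                seq[pos:pos + len(site)] = list(inserted)
                planted.append((gene, pwm.matrix_id, pos, strand))
            fh.write(f">{gene} synthetic promoter\n")
            sequence = "".join(seq)
            for j in range(0, length, 60):
                fh.write(sequence[j:j + 60] + "\n")
    return out_path, planted


def make_config(**overrides) -> SynthConfig:
    """Convenience constructor used by the CLI (validates via dataclass)."""
    return replace(SynthConfig(), **overrides)
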