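"""Parsing and normalization of regulatory relation tables and node sets.

The canonical inputs are five datasets, named after the database extracts
they emulate:

* ``U1`` -- miRNA -> target-gene relations (``TARGETS`` edges),
* ``U2`` -- transcription-factor -> miRNA relations (``REGULATES`` edges),
* ``U3`` -- host-gene -> intronic-miRNA relations (``HOSTS`` edges),
* ``U4`` -- gene node sets (differentially expressed subset of the
  disease-associated set),
* ``U5`` -- miRNA node sets, same two-level structure.

Relation tables are two-column TSV files (header ``source<TAB>target``,
``#`` comments allowed); node sets are one identifier per line.  All
identifiers are normalized on input: gene symbols are upper-cased and
resolved through an optional alias map, miRNA names get a canonical
organism prefix and stem capitalization ("hsa-miR-20a", "hsa-let-7a-1"),
and family names may expand to several paralogs through an expansion map
(e.g. hsa-miR-125b -> hsa-miR-125b-1 and hsa-miR-125b-2).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Edge type implied by each relation-set kind.
ETYPE_BY_KIND = {"U1": "TARGETS", "U2": "REGULATES", "U3": "HOSTS"}

#: (source node class, target node class) required by each edge type.
NODE_CLASS_BY_ETYPE = {
    "TARGETS": ("miRNA", "gene"),
    "REGULATES": ("gene", "miRNA"),
    "HOSTS": ("gene", "miRNA"),
}

ETYPES = frozenset(NODE_CLASS_BY_ETYPE)

_MIRNA_RE = re.compile(
    r"^(?:(?P<org>[A-Za-z]{3,4})-)?(?P<stem>mir|let)(?P<rest>-\S+)?$",
    re.IGNORECASE,
)


class RelationFormatError(ValueError):
    """A relation table or node-set file violates the expected layout."""


def normalize_gene_symbol(raw: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Return the canonical upper-case official symbol for ``raw``.

    Alias resolution is case-insensitive on the alias key; the resolved
    value is itself upper-cased so that normalization is idempotent.
    Symbols absent from the alias map pass through upper-cased (with a
    warning when a non-empty map was supplied), so that unknown genes are
    kept rather than silently dropped.
    """
    symbol = raw.strip()
    if not symbol:
        raise ValueError("empty gene symbol")
    if any(ch.isspace() for ch in symbol):
        raise ValueError(f"gene symbol contains whitespace: {raw!r}")
    if alias_map:
        resolved = alias_map.get(symbol, alias_map.get(symbol.upper()))
        if resolved is not None:
            return resolved.strip().upper()
        logger.warning("gene symbol %r not in alias map; kept as-is", symbol)
    return symbol.upper()


def normalize_mirna_name(
    raw: str,
    organism: str = "hsa",
    expansion: Mapping[str, Iterable[str]] | None = None,
) -> list[str]:
    """Normalize a miRNA token to one or more canonical names.

    The canonical form always carries an organism prefix ("hsa-miR-20a");
    the stem is re-capitalized ("miR"/"let") and the suffix lower-cased,
    so paralog suffixes like "-125b-1" and "-125b-2" stay distinct.  A
    family name present in ``expansion`` is replaced by its listed
    paralogs (each normalized recursively), which mirrors how a precursor
    name maps to several annotated loci.
    """
    token = raw.strip()
    if not token:
        raise ValueError("empty miRNA name")
    m = _MIRNA_RE.match(token)
    if m is None or m.group("rest") is None:
        raise ValueError(f"not a recognizable miRNA name: {raw!r}")
    org = (m.group("org") or organism).lower()
    stem = "let" if m.group("stem").lower() == "let" else "miR"
    name = f"{org}-{stem}{m.group('rest').lower()}"
    if expansion and name in expansion:
        out: list[str] = []
        for paralog in expansion[name]:
            for normalized in normalize_mirna_name(paralog, organism=org):
                if normalized not in out:
                    out.append(normalized)
        return out
    return [name]


@dataclass(frozen=True)
class RelationRecord:
    """One typed directed relation with provenance.

    ``TARGETS`` records run miRNA -> gene; ``REGULATES`` and ``HOSTS``
    records run gene -> miRNA.
    """

    source: str
    target: str
    etype: str
    provenance: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.etype not in ETYPES:
            raise ValueError(f"unknown edge type {self.etype!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.etype)


@dataclass
class RelationSet:
    """A deduplicated collection of relations of one kind (U1/U2/U3)."""

    kind: str
    records: list[RelationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ETYPE_BY_KIND:
            raise ValueError(f"unknown relation-set kind {self.kind!r}")
        expected = ETYPE_BY_KIND[self.kind]
        merged: dict[tuple[str, str, str], frozenset[str]] = {}
        for rec in self.records:
            if rec.etype != expected:
                raise ValueError(
                    f"{self.kind} requires etype {expected}, got {rec.etype}"
                )
            merged[rec.key] = merged.get(rec.key, frozenset()) | rec.provenance
        self.records = [
            RelationRecord(s, t, e, prov)
            for (s, t, e), prov in sorted(merged.items())
        ]

    @property
    def etype(self) -> str:
        return ETYPE_BY_KIND[self.kind]

    def keys(self) -> set[tuple[str, str, str]]:
        return {rec.key for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class NodeSet:
    """Two-level node collection: differential subset of associated set."""

    kind: str
    differential: frozenset[str] = frozenset()
    associated: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in {"U4", "U5"}:
            raise ValueError(f"unknown node-set kind {self.kind!r}")
        self.differential = frozenset(self.differential)
        self.associated = frozenset(self.associated) | self.differential

    def level(self, level: str) -> frozenset[str]:
        if level == "differential":
            return self.differential
        if level == "associated":
            return self.associated
        raise ValueError(f"unknown level {level!r}")

    def with_added(self, members: Iterable[str], level: str = "associated") -> "NodeSet":
        """Return a copy with ``members`` added at the given level."""
        extra = frozenset(members)
        if level == "differential":
            return NodeSet(self.kind, self.differential | extra, self.associated)
        return NodeSet(self.kind, self.differential, self.associated | extra)


def _normalize_endpoint(
    token: str,
    node_class: str,
    alias_map: Mapping[str, str] | None,
    expansion: Mapping[str, Iterable[str]] | None,
    organism: str,
) -> list[str]:
    if node_class == "gene":
        return [normalize_gene_symbol(token, alias_map)]
    return normalize_mirna_name(token, organism=organism, expansion=expansion)


def read_relation_table(
    path: str | Path,
    kind: str,
    alias_map: Mapping[str, str] | None = None,
    expansion: Mapping[str, Iterable[str]] | None = None,
    organism: str = "hsa",
    provenance: str | None = None,
) -> RelationSet:
    """Read a two-column TSV relation table into a :class:`RelationSet`.

    Rows are normalized endpoint-wise; a miRNA endpoint that expands to
    several paralogs yields one record per paralog.  Duplicate relations
    are merged with the union of their provenance labels.
    """
    path = Path(path)
    if kind not in ETYPE_BY_KIND:
        raise ValueError(f"unknown relation-set kind {kind!r}")
    etype = ETYPE_BY_KIND[kind]
    src_class, tgt_class = NODE_CLASS_BY_ETYPE[etype]
    prov = frozenset({provenance or path.stem})

    records: list[RelationRecord] = []
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise RelationFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if not header_seen:
                header_seen = True
                if [f.strip().lower() for f in fields] != ["source", "target"]:
                    raise RelationFormatError(
                        f"{path}:{lineno}: expected header 'source<TAB>target'"
                    )
                continue
            try:
                sources = _normalize_endpoint(
                    fields[0], src_class, alias_map, expansion, organism
                )
                targets = _normalize_endpoint(
                    fields[1], tgt_class, alias_map, expansion, organism
                )
            except ValueError as exc:
                raise RelationFormatError(f"{path}:{lineno}: {exc}") from exc
            for s in sources:
                for t in targets:
                    records.append(RelationRecord(s, t, etype, prov))
    return RelationSet(kind, records)


def write_relation_table(relations: RelationSet, path: str | Path) -> None:
    """Write a relation set back to its TSV form (sorted, deterministic)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#kind={relations.kind}\n")
        fh.write("source\ttarget\n")
        for rec in relations.records:
            fh.write(f"{rec.source}\t{rec.target}\n")


def _read_id_file(
    path: str | Path,
    node_class: str,
    alias_map: Mapping[str, str] | None,
    expansion: Mapping[str, Iterable[str]] | None,
    organism: str,
) -> frozenset[str]:
    out: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if not token:
                continue
            out.update(
                _normalize_endpoint(token, node_class, alias_map, expansion, organism)
            )
    return frozenset(out)


def read_node_set(
    path_diff: str | Path,
    path_assoc: str | Path,
    kind: str,
    alias_map: Mapping[str, str] | None = None,
    expansion: Mapping[str, Iterable[str]] | None = None,
    organism: str = "hsa",
) -> NodeSet:
    """Read differential and associated identifier lists into a NodeSet.

    The associated set is defined to contain the differential set; when
    the files alone violate that containment the differential members are
    united into the associated set and a warning is logged.
    """
    if kind not in {"U4", "U5"}:
        raise ValueError(f"unknown node-set kind {kind!r}")
    node_class = "gene" if kind == "U4" else "miRNA"
    differential = _read_id_file(path_diff, node_class, alias_map, expansion, organism)
    associated = _read_id_file(path_assoc, node_class, alias_map, expansion, organism)
    missing = differential - associated
    if missing:
        logger.warning(
            "%s: %d differential identifiers absent from the associated list; "
            "united into it (e.g. %s)",
            kind,
            len(missing),
            sorted(missing)[0],
        )
    return NodeSet(kind, differential, associated)


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV alias map (alias -> official symbol)."""
    return dict(_read_two_columns(path))


def read_expansion_map(path: str | Path, organism: str = "hsa") -> dict[str, list[str]]:
    """Read a two-column TSV paralog-expansion map (family -> paralog).

    Several rows with the same family name accumulate into one list; keys
    are normalized so lookups hit regardless of the input spelling.
    """
    out: dict[str, list[str]] = {}
    for family, paralog in _read_two_columns(path):
        (key,) = normalize_mirna_name(family, organism=organism)
        out.setdefault(key, []).append(paralog)
    return out


def _read_two_columns(path: str | Path) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not all(fields):
                raise RelationFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            pairs.append((fields[0], fields[1]))
    return pairs
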