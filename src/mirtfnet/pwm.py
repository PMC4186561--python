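"""Position-weight-matrix promoter scanning (Match-style scoring).

Transcription-factor binding sites are predicted by sliding a TRANSFAC
count matrix over 1,000-nt promoter sequences and scoring each window
with the information-weighted, min-max-normalized similarity used by the
Match family of scanners:

* per-position information ``I(i) = sum_b f(i,b) * ln(4 f(i,b))`` with
  frequencies from pseudocount-smoothed counts (zero for a uniform
  column, approaching ln 4 for a fully conserved one);
* window score ``(Current - Min) / (Max - Min)`` where ``Current`` is
  ``sum_i I(i) f(i, w_i)`` and ``Max``/``Min`` take the best/worst base
  per position -- the consensus scores 1.0, the anti-consensus 0.0;
* a candidate must first pass the *core* score (the highest-information
  contiguous 5-position window of the matrix), then the full-matrix
  score.

``N`` in a sequence scores as the worst base at its position; a matrix
whose ``Max`` equals ``Min`` (e.g. fully uniform) scores every window
1.0 as a documented degenerate case.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO, motifs

from mirtfnet.relations import normalize_gene_symbol

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PSEUDOCOUNT = 0.25
DEFAULT_CORE_LENGTH = 5

#: (core_threshold, matrix_threshold) per stringency profile.  The high
#: profile is the default used for TF prediction.
THRESHOLD_PROFILES = {
    "high": (0.95, 0.95),
    "medium": (0.90, 0.85),
    "low": (0.80, 0.75),
}


class MatrixFormatError(ValueError):
    """A TRANSFAC matrix block is malformed."""


@dataclass
class PWM:
    """TRANSFAC-style count matrix with its derived core window."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # positions x 4, A/C/G/T order
    core_start: int = 0
    core_length: int = DEFAULT_CORE_LENGTH

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be a positions x 4 array")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.matrix_id}: negative counts")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError(f"{self.matrix_id}: position with zero column sum")
        self.core_length = min(self.core_length, len(self))
        if not 0 <= self.core_start <= len(self) - self.core_length:
            raise ValueError(f"{self.matrix_id}: core window out of range")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        smoothed = self.counts + PSEUDOCOUNT
        return smoothed / smoothed.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        # ties break toward the earlier base in A,C,G,T order
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=1))

    @property
    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmin(self.frequencies, axis=1))


@dataclass
class PromoterSeq:
    """A promoter sequence labelled with its gene's official symbol."""

    gene: str
    sequence: str
    expected_length: int | None = 1000

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(BASES + "N")
        if bad:
            raise ValueError(
                f"{self.gene}: non-nucleotide characters {sorted(bad)}"
            )
        if self.expected_length is not None and len(self.sequence) != self.expected_length:
            raise ValueError(
                f"{self.gene}: promoter length {len(self.sequence)} != "
                f"expected {self.expected_length}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TFBSHit:
    """One predicted binding site on a promoter.

    ``position`` is the 0-based forward-strand offset of the match start;
    a ``-`` strand hit is reported at the forward-strand start of its
    reverse-complement match.
    """

    gene: str
    matrix_id: str
    position: int
    strand: str
    core_score: float
    matrix_score: float


# ---------------------------------------------------------------------------
# TRANSFAC parsing


def parse_transfac_matrices(path: str | Path) -> list[PWM]:
    """Parse a TRANSFAC flat file into a list of :class:`PWM`.

    Blocks are ID/NA/P0/count rows terminated by ``//``; the TF name is
    taken from the NA line and normalized as a gene symbol.  The core
    window is the maximum-information contiguous window (ties leftmost).
    """
    text = Path(path).read_text()
    blocks: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "//":
            blocks.append("\n".join(current))
            current = []
        elif line.strip():
            current.append(line)
    if any(line.strip() for line in current):
        ident = _block_id(current) or "<unnamed>"
        raise MatrixFormatError(f"matrix block {ident} not terminated by '//'")

    pwms: list[PWM] = []
    for block in blocks:
        lines = block.splitlines()
        ident = _block_id(lines) or "<unnamed>"
        try:
            parsed = motifs.parse(io.StringIO(block + "\n//\n"), "TRANSFAC",
                                  strict=False)
        except Exception as exc:
            raise MatrixFormatError(f"matrix {ident}: {exc}") from exc
        if len(parsed) != 1:
            raise MatrixFormatError(f"matrix {ident}: expected one motif block")
        motif = parsed[0]
        if motif.counts is None or motif.length == 0:
            raise MatrixFormatError(f"matrix {ident}: missing count matrix")
        counts = np.column_stack([list(motif.counts[b]) for b in BASES])
        name = motif.get("NA") or motif.get("ID") or ident
        try:
            pwm = make_pwm(ident, normalize_gene_symbol(name), counts)
        except ValueError as exc:
            raise MatrixFormatError(str(exc)) from exc
        pwms.append(pwm)
    return pwms


def _block_id(lines: Sequence[str]) -> str | None:
    for line in lines:
        if line.startswith(("ID", "AC")):
            parts = line.split(None, 1)
            if len(parts) == 2:
                return parts[1].strip()
    return None


def make_pwm(matrix_id: str, tf_name: str, counts: np.ndarray,
             core_length: int = DEFAULT_CORE_LENGTH) -> PWM:
    """Build a PWM, locating its maximum-information core window."""
    pwm = PWM(matrix_id, tf_name, counts, core_start=0,
              core_length=min(core_length, len(counts)))
    pwm.core_start = _best_core_start(information_vector(pwm), pwm.core_length)
    return pwm


def _best_core_start(info: np.ndarray, core_length: int) -> int:
    window_sums = np.convolve(info, np.ones(core_length), mode="valid")
    # leftmost maximum
    return int(np.argmax(window_sums))


# ---------------------------------------------------------------------------
# Scoring


def information_vector(pwm: PWM) -> np.ndarray:
    """Per-position information content I(i) = sum_b f ln(4 f), in nats."""
    f = pwm.frequencies
    return np.maximum((f * np.log(4.0 * f)).sum(axis=1), 0.0)


def _extended_frequencies(pwm: PWM) -> np.ndarray:
    """Frequencies with a 5th column scoring N as the worst base."""
    f = pwm.frequencies
    return np.column_stack([f, f.min(axis=1)])


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in sequence), dtype=np.intp,
                       count=len(sequence))


def _region_score(info: np.ndarray, fmat: np.ndarray, encoded: np.ndarray) -> float:
    weighted = info[:, None] * fmat
    current = float(weighted[np.arange(len(encoded)), encoded].sum())
    best = float((info * fmat[:, :4].max(axis=1)).sum())
    worst = float((info * fmat[:, :4].min(axis=1)).sum())
    if best == worst:  # degenerate (e.g. fully uniform) matrix
        return 1.0
    return (current - worst) / (best - worst)


def matrix_similarity(pwm: PWM, window: str) -> float:
    """Min-max-normalized score of ``window`` against the full matrix."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(pwm)}"
        )
    return _region_score(information_vector(pwm), _extended_frequencies(pwm),
                         _encode(window.upper()))


def core_similarity(pwm: PWM, window: str) -> float:
    """Score of the core positions of ``window`` (full matrix window)."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != matrix length {len(pwm)}"
        )
    sl = slice(pwm.core_start, pwm.core_start + pwm.core_length)
    return _region_score(information_vector(pwm)[sl],
                         _extended_frequencies(pwm)[sl],
                         _encode(window.upper())[sl])


def _scan_scores(encoded: np.ndarray, info: np.ndarray, fmat: np.ndarray,
                 start: int, length: int) -> np.ndarray:
    """Vectorized min-max scores of every window's [start, start+length)."""
    sl_info = info[start:start + length]
    sl_f = fmat[start:start + length]
    n_windows = len(encoded) - len(info) + 1
    windows = np.lib.stride_tricks.sliding_window_view(
        encoded, len(info))[:n_windows, start:start + length]
    weighted = sl_info[:, None] * sl_f
    current = weighted[np.arange(length), windows].sum(axis=1)
    best = (sl_info * sl_f[:, :4].max(axis=1)).sum()
    worst = (sl_info * sl_f[:, :4].min(axis=1)).sum()
    if best == worst:
        return np.ones(n_windows)
    return (current - worst) / (best - worst)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def scan_promoter(
    seq: PromoterSeq,
    pwm: PWM,
    core_threshold: float = 0.95,
    matrix_threshold: float = 0.95,
    both_strands: bool = True,
) -> list[TFBSHit]:
    """Scan one promoter with one matrix; return hits sorted by position.

    Every offset is scored core-first, matrix-second; only windows that
    pass both thresholds are emitted.  With ``both_strands`` the reverse
    complement is scanned too, and its hits are mapped back to
    forward-strand start coordinates.
    """
    for name, value in (("core", core_threshold), ("matrix", matrix_threshold)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} threshold must be in [0, 1]")
    L = len(pwm)
    if len(seq) < L:
        warnings.warn(
            f"{seq.gene}: sequence ({len(seq)} nt) shorter than matrix "
            f"{pwm.matrix_id} ({L} nt); no scan performed",
            stacklevel=2,
        )
        return []

    info = information_vector(pwm)
    fmat = _extended_frequencies(pwm)
    hits: list[TFBSHit] = []
    strands = [("+", seq.sequence)]
    if both_strands:
        strands.append(("-", reverse_complement(seq.sequence)))
    for strand, sequence in strands:
        encoded = _encode(sequence)
        core = _scan_scores(encoded, info, fmat, pwm.core_start, pwm.core_length)
        candidates = np.flatnonzero(core >= core_threshold)
        if candidates.size == 0:
            continue
        full = _scan_scores(encoded, info, fmat, 0, L)
        for offset in candidates:
            if full[offset] >= matrix_threshold:
                position = (
                    int(offset) if strand == "+" else len(seq) - L - int(offset)
                )
                hits.append(
                    TFBSHit(seq.gene, pwm.matrix_id, position, strand,
                            float(core[offset]), float(full[offset]))
                )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# TF prediction


def predicted_tfs_for_targets(
    promoters: Iterable[PromoterSeq],
    matrices: Sequence[PWM],
    tf_whitelist: Iterable[str],
    profile: str = "high",
) -> dict[str, set[str]]:
    """Predict, per target gene, the TFs with a binding site hit.

    The per-gene TF sets are intersected with ``tf_whitelist`` -- in the
    pipeline, the TFs appearing as sources of the TF->miRNA relation set
    -- because only those can be wired into the network downstream.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    try:
        core_threshold, matrix_threshold = THRESHOLD_PROFILES[profile]
    except KeyError:
        raise ValueError(f"unknown threshold profile {profile!r}") from None
    whitelist = set(tf_whitelist)
    predicted: dict[str, set[str]] = {}
    for promoter in promoters:
        tfs: set[str] = set()
        for pwm in matrices:
            if pwm.tf_name not in whitelist:
                continue
            if scan_promoter(promoter, pwm, core_threshold, matrix_threshold):
                tfs.add(pwm.tf_name)
        if tfs:
            predicted[promoter.gene] = tfs
    return predicted


# ---------------------------------------------------------------------------
# I/O


def read_promoters_fasta(
    path: str | Path, expected_length: int | None = 1000
) -> list[PromoterSeq]:
    """Read promoters from FASTA; the first header token is the gene symbol."""
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        gene = normalize_gene_symbol(record.id.split()[0])
        out.append(PromoterSeq(gene, str(record.seq), expected_length))
    return out


def write_hits_tsv(hits: Iterable[TFBSHit], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tmatrix_id\tposition\tstrand\tcore_score\tmatrix_score\n")
        for h in hits:
            fh.write(
                f"{h.gene}\t{h.matrix_id}\t{h.position}\t{h.strand}\t"
                f"{h.core_score:.6f}\t{h.matrix_score:.6f}\n"
            )
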