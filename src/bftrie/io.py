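"""FASTA/FASTQ ingestion, k-mer counting, index building and batch query.

One input file is one *color*: file i (1-based) contributes color i.
Counting is in-memory and per genome; a k-mer seen fewer than
``min_occurrences`` times in a genome's reads is treated as a sequencing
error and never inserted.  Windows containing non-ACGT characters are
skipped (reads are split at those positions).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

from . import dna
from .colors import resolve
from .serialize import save
from .trie import BFT

logger = logging.getLogger(__name__)

__all__ = ["BuildConfig", "extract_kmers", "count_kmers", "build_index", "batch_query"]

_FASTQ_EXT = {".fq", ".fastq"}
_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn"}


@dataclass
class BuildConfig:
    """Parameters of an index build.

    ``k`` must be a multiple of ``l``; ``inputs`` lists one sequence file
    per color, in color order.
    """

    k: int
    l: int
    c: int = 248
    min_occurrences: int = 1
    graph_mode: bool = True
    bf_bits: int = 128
    bf_hashes: int | None = None
    seed: int = 0
    inputs: list[str] = field(default_factory=list)
    output: str | None = None

    def __post_init__(self):
        if self.k % self.l != 0:
            raise ValueError(f"k={self.k} must be a multiple of l={self.l}")
        if self.min_occurrences < 1:
            raise ValueError("min_occurrences must be >= 1")
        if self.c < 1:
            raise ValueError("capacity c must be positive")


def _open_seq(path: str | Path) -> tuple[TextIO, str]:
    """Open a (possibly gzipped) sequence file, sniffing format by extension."""
    p = Path(path)
    suffixes = p.suffixes
    opener = open
    if suffixes and suffixes[-1] == ".gz":
        opener = lambda f: gzip.open(f, "rt")  # noqa: E731
        suffixes = suffixes[:-1]
    ext = suffixes[-1].lower() if suffixes else ""
    if ext in _FASTQ_EXT:
        fmt = "fastq"
    elif ext in _FASTA_EXT or ext == "":
        fmt = "fasta"
    else:
        raise ValueError(f"unrecognized sequence file extension {ext!r} for {path}")
    return opener(p), fmt


def _iter_sequences(path: str | Path) -> Iterator[str]:
    fh, fmt = _open_seq(path)
    n = 0
    try:
        for record in SeqIO.parse(fh, fmt):
            n += 1
            yield str(record.seq)
    except ValueError as exc:  # malformed record
        raise ValueError(
            f"malformed {fmt} record near record {n + 1} in {path}: {exc}"
        ) from exc
    finally:
        fh.close()


def count_kmers(sequences: Iterable[str], k: int) -> dict[str, int]:
    """Count every length-k window over the ACGT-only stretches of the input."""
    counts: dict[str, int] = {}
    get = counts.get
    for seq in sequences:
        for seg in dna.acgt_segments(seq):
            for i in range(len(seg) - k + 1):
                w = seg[i : i + k]
                counts[w] = get(w, 0) + 1
    return counts


def extract_kmers(
    source: str | Path | Iterable[str], k: int, min_occ: int = 1
) -> Iterator[tuple[str, int]]:
    """Yield (k-mer, count) pairs with count >= min_occ, lexicographically.

    ``source`` is a FASTA/FASTQ path (gzip accepted) or an iterable of
    raw sequence strings.  Emission order is deterministic and
    independent of read order.
    """
    seqs = _iter_sequences(source) if isinstance(source, (str, Path)) else source
    counts = count_kmers(seqs, k)
    for kmer in sorted(counts):
        n = counts[kmer]
        if n >= min_occ:
            yield kmer, n


def build_index(cfg: BuildConfig) -> BFT:
    """Build an index from ``cfg.inputs`` (file i -> color i), compress colors,
    and serialize to ``cfg.output`` when set."""
    if not cfg.inputs:
        raise ValueError("at least one input file is required")
    for f in cfg.inputs:
        if not Path(f).exists():
            raise FileNotFoundError(f"input file not found: {f}")
    t = BFT(
        k=cfg.k, l=cfg.l, c=cfg.c, graph_mode=cfg.graph_mode,
        bf_bits=cfg.bf_bits, bf_hashes=cfg.bf_hashes, seed=cfg.seed,
    )
    for color, path in enumerate(cfg.inputs, start=1):
        n_distinct = 0
        for kmer, _count in extract_kmers(path, cfg.k, cfg.min_occurrences):
            t.insert(kmer, color)
            n_distinct += 1
        logger.info("color %d (%s): %d distinct k-mers kept", color, path, n_distinct)
    from .colors import compress_colors

    compress_colors(t)
    logger.info("index holds %d unique k-mers over %d colors", t.n_kmers, len(cfg.inputs))
    if cfg.output:
        save(t, cfg.output)
        logger.info("index written to %s", cfg.output)
    return t


@dataclass
class QueryRow:
    kmer: str
    valid: bool
    present: bool = False
    colors: list[int] = field(default_factory=list)

    def tsv(self) -> str:
        if not self.valid:
            return f"{self.kmer}\tinvalid\t"
        return f"{self.kmer}\t{1 if self.present else 0}\t" + ",".join(map(str, self.colors))


def batch_query(t: BFT, lines: Iterable[str]) -> Iterator[QueryRow]:
    """Query one k-mer per input line, preserving order.

    Malformed lines (wrong length, non-ACGT) yield rows flagged invalid;
    processing continues.
    """
    for line in lines:
        kmer = line.strip()
        if not kmer:
            continue
        try:
            ref = t.contains(kmer)
        except (ValueError, dna.InvalidBaseError):
            yield QueryRow(kmer, valid=False)
            continue
        if ref is None:
            yield QueryRow(kmer, valid=True, present=False)
        else:
            cs = resolve(ref, t.color_table)
            yield QueryRow(kmer, valid=True, present=True, colors=cs.indices())
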