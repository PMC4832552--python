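"""Synthetic pan-genome generator and exact oracles for testing.

Emulates a bacterial resequencing study at desk scale: one random
reference, per-genome substitution mutations (no indels, so coordinates
stay aligned and the truth table is trivially exact), and uniform
forward-strand reads with substitution sequencing errors.  The ground
truth — which genome contains which k-mer — is computed from the genome
strings themselves, never from the reads, while read-level k-mer counts
let minimum-occurrence filtering be checked independently.

All randomness flows through one integer-seeded ``random.Random``, so a
seed fixes every output byte on every platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from pathlib import Path

__all__ = ["PanGenomeSim", "SimResult", "simulate", "oracle_index", "write_files"]

_BASES = "acgt"


@dataclass(frozen=True)
class PanGenomeSim:
    """Parameters of a simulated pan-genome sequencing study.

    Defaults are the desk-scale preset: a 100 kb reference, 5 genomes at
    0.5% substitution divergence, 20,000 reads of 100 bp per genome
    (20x coverage) with a 0.5% substitution sequencing error rate, and
    k=30 split into length-6 chunks.
    """

    ref_len: int = 100_000
    n_genomes: int = 5
    sub_rate: float = 0.005
    read_len: int = 100
    n_reads: int = 20_000
    err_rate: float = 0.005
    k: int = 30
    l: int = 6
    seed: int = 0

    def __post_init__(self):
        for name in ("sub_rate", "err_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.k % self.l != 0:
            raise ValueError(f"k={self.k} must be a multiple of l={self.l}")

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "PanGenomeSim":
        """Named presets: ``desk`` (default scale) and ``mini`` (test scale)."""
        if name == "desk":
            return cls(seed=seed)
        if name == "mini":
            return cls(
                ref_len=8_000, n_genomes=4, sub_rate=0.005,
                read_len=80, n_reads=1_500, err_rate=0.005,
                k=18, l=6, seed=seed,
            )
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class SimResult:
    """Simulated study: sequences plus the exact k-mer truth table."""

    params: PanGenomeSim
    reference: str
    genomes: list[str]                 # genomes[i] is color i+1
    reads: list[list[str]]             # reads[i] sampled from genomes[i]
    truth: dict[str, set[int]]         # k-mer -> 1-based colors (from genomes)

    def genome_kmers(self, i: int) -> set[str]:
        """Distinct k-mers of genome ``i`` (0-based), from the genome string."""
        g, k = self.genomes[i], self.params.k
        return {g[j : j + k] for j in range(len(g) - k + 1)}

    def read_kmer_counts(self, i: int) -> dict[str, int]:
        """Per-genome k-mer counts over the reads (min_occ filtering oracle)."""
        k = self.params.k
        counts: dict[str, int] = {}
        for r in self.reads[i]:
            for j in range(len(r) - k + 1):
                w = r[j : j + k]
                counts[w] = counts.get(w, 0) + 1
        return counts


def _mutate(rng: random.Random, s: str, rate: float) -> str:
    if rate <= 0.0:
        return s
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice(_BASES.replace(out[i], ""))
    return "".join(out)


def simulate(p: PanGenomeSim) -> SimResult:
    """Generate genomes, reads and the exact truth table for ``p``."""
    rng = random.Random(p.seed)
    reference = "".join(rng.choice(_BASES) for _ in range(p.ref_len))
    genomes = [_mutate(rng, reference, p.sub_rate) for _ in range(p.n_genomes)]
    reads: list[list[str]] = []
    for g in genomes:
        span = len(g) - p.read_len
        gset = []
        for _ in range(p.n_reads):
            pos = rng.randrange(span + 1)
            gset.append(_mutate(rng, g[pos : pos + p.read_len], p.err_rate))
        reads.append(gset)
    truth: dict[str, set[int]] = {}
    for i, g in enumerate(genomes, start=1):
        for j in range(len(g) - p.k + 1):
            truth.setdefault(g[j : j + p.k], set()).add(i)
    return SimResult(p, reference, genomes, reads, truth)


def oracle_index(pairs) -> dict[str, set[int]]:
    """Plain map of k-mer -> color set; ground truth for equivalence tests."""
    idx: dict[str, set[int]] = {}
    for kmer, color in pairs:
        idx.setdefault(kmer, set()).add(color)
    return idx


def write_files(result: SimResult, outdir: str | Path, reads_as_fastq: bool = True) -> dict:
    """Write per-genome FASTA (genomes), FASTQ/FASTA (reads) and a truth TSV.

    Returns the written paths: genome FASTAs, read files (one per color),
    and ``truth.tsv`` mapping k-mer -> comma-separated 1-based colors.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_paths, read_paths = [], []
    for i, g in enumerate(result.genomes, start=1):
        gp = outdir / f"genome_{i}.fa"
        with open(gp, "w") as fh:
            fh.write(f">genome_{i}\n")
            for j in range(0, len(g), 80):
                fh.write(g[j : j + 80] + "\n")
        genome_paths.append(gp)
        if reads_as_fastq:
            rp = outdir / f"reads_{i}.fq"
            with open(rp, "w") as fh:
                for n, r in enumerate(result.reads[i - 1]):
                    fh.write(f"@g{i}_r{n}\n{r}\n+\n{'I' * len(r)}\n")
        else:
            rp = outdir / f"reads_{i}.fa"
            with open(rp, "w") as fh:
                for n, r in enumerate(result.reads[i - 1]):
                    fh.write(f">g{i}_r{n}\n{r}\n")
        read_paths.append(rp)
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("kmer\tcolors\n")
        for kmer in sorted(result.truth):
            fh.write(f"{kmer}\t{','.join(map(str, sorted(result.truth[kmer])))}\n")
    return {"genomes": genome_paths, "reads": read_paths, "truth": truth_path}
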