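# Methods

## The model

`bftrie` stores a colored de Bruijn graph as a burst trie over the DNA
alphabet {a,c,g,t}. A k-mer is packed 2 bits per character (a=0, c=1,
g=2, t=3 — the unique lexicographic mapping, under which the prefix `gt`
occupies 1-based prefix-array slot 12) and split into k/l chunks of
length l; each trie level consumes one chunk, so the maximal vertex
depth is k/l − 1. Vertices hold a list of containers: any number of
compressed containers plus at most one uncompressed container at the
tail.

The structure is *exact*. Bloom filters only route the walk: a filter
hit is always verified against the exact arrays, and the
first-firing-container insertion discipline (a new suffix prefix goes to
the first compressed container whose filter claims it, leaving the
filter unchanged) guarantees that the container a look-up stops on is
the one an insertion would have used. Since filters are only written at
burst time, that stopping container is stable for the life of the index,
which is what makes "stop at the first firing container; a miss there is
a global miss" a sound look-up rule.

Reverse complements are not canonicalized: a k-mer is stored as given.
Reads containing non-ACGT characters are split at those positions during
extraction; ambiguity codes are never stored. Deletion is unsupported by
design.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| k | k-mer length | user-set (CLI) | domain choice; must be a multiple of l |
| l | chunk length per level | user-set | controls trie height k/l and container width 4^l; l ≥ 3 so a split with \|a\| ≥ 1 and \|b\| ≥ 2 exists |
| c | uncompressed capacity | 248 | the value that balanced compression vs. speed in practice at production scale; tests use smaller c to exercise bursts |
| bf_bits (m) | Bloom bits per container | 128 | small enough to be negligible per container, large enough that false-positive routing stays rare |
| bf_hashes (f) | hash count | max(1, round(ln2·m/c)), capped at 4 | the standard optimum for ~c elements in m bits, bounded for flat probe cost |
| min_occurrences | per-genome count filter | 1 | k-mers below it are treated as sequencing errors; dataset-dependent, so user-set in builds |
| resize_factor | re-split trigger | 8 | a container is re-split when its q(μ+1) tail exceeds this multiple of the burst-time uncompressed estimate (c+1)·2l bits; only a space heuristic, never affects answers |
| seed | hash seed | 0 | all filters in one trie share it; equal seeds give bit-identical indexes |

Burst-time split choice: the smallest |a| with |b| ≥ 2 satisfying
m + 2^λ ≤ q(λ−1) for the q distinct prefixes at hand; when no |a|
qualifies (small l or q, e.g. the l=4 toy), |a| = l/2 rounded down,
clamped so |b| ≥ 2. The |b| ≥ 2 floor is structural: graph traversal
needs both variable characters of a rotated prefix inside `suf`.

## Numerical and layout choices

* **Bit arrays** are Python integers (pref, Bloom bits) or small 0/1
  lists (clust): containers hold at most c+1 entries, so word-wise
  popcount on an int and a naive Rank scan beat any succinct structure
  at this scale. `Rank` returns |clust|+1 when the i-th set bit does
  not exist, which doubles as the append position.
* **Hashing** is a splitmix64 double-hashing family
  h_i = hA + i·hB mod m over the 2-bit packing of the hashed
  characters — deterministic and platform-independent. Restricted mode
  hashes only positions 2..l−1 of the probe.
* **Positions** are 1-based in all documented results (cluster indices,
  suf/pref slots); internals are 0-based.
* **Child links**: a compressed container keeps a children array
  parallel to `suf` (order-preserving under insertions and re-splits);
  at maximal depth the entries are the k-mers' color references
  themselves.
* **Re-splitting** (|a|+1/|b|−1) is applied only while
  2^λ′ + qμ′ < 2^λ + qμ strictly holds; sorted order by full prefix is
  split-invariant, so only pref/suf/clust are rebuilt and the Bloom
  filter is untouched (its hashes read interior characters a rotation
  does not move).
* **Ties** never arise in cluster scans: suffix parts within a cluster
  are unique by construction, and duplicate container-level insertion is
  an error by contract (the trie merges colors before it gets there).
* **Color compression** sorts the distinct color sets by count×size
  descending (ties: smaller bit array first, for run-to-run determinism)
  and externalizes a set when a byte-rounded index into the table is
  strictly smaller than the byte-rounded set. This makes the *per-k-mer*
  (in-trie) color storage monotonically non-increasing; the external
  table itself stores each externalized set once and is reported
  separately by `bft info`. Census and rewrite are two passes.
  Compression can be re-run: merging a new color into an externally
  referenced set re-inlines just that k-mer until the next pass.
* **Serialization** is a versioned little-endian binary format (header,
  pre-order vertex dump, color-table appendix) with a bit-exact
  round-trip contract, verified by querying all stored k-mers plus 10^4
  random absent ones after reload.

## The synthetic pan-genome generator

`bftrie.simulate` emulates a bacterial resequencing study: one uniform
random reference, per-genome i.i.d. substitutions (rate 0.005 by
default — typical strain-level divergence), and uniformly placed
forward-strand reads with substitution sequencing errors (rate 0.005).
Substitutions only, no indels: coordinates stay aligned, so the
k-mer→colors truth table computed from the genome strings is exact by
construction, while read-level k-mer counts are exposed separately so
minimum-occurrence filtering can be validated.

What it does **not** emulate: indels and structural variation, coverage
and GC bias, quality-score profiles, reverse-strand reads (the index
does not canonicalize, so strand-mixed input would dilute the truth
table by design), and real genome repeat structure. Passing tests
therefore demonstrate the index's exactness and traversal contracts on
realistic k-mer set sizes and divergence, not robustness to artifacts of
real sequencing chemistry.

Presets: `desk` — 100 kb reference, 5 genomes, 20,000 reads × 100 bp
per genome (20× coverage), k=30, l=6; `mini` — 8 kb reference, 4
genomes, 1,500 reads × 80 bp, k=18, l=6. The test suite and its oracle
comparisons (2×10^4 membership probes, 10^3 traversal probes) run on
the mini preset, a problem size chosen so the whole suite completes in
about a minute on one core; desk-scale runs use the same code paths
with identical rates.

## Known limitations

* Pure-Python throughput is desk-scale: millions of insertions per
  minute, not the hundreds of millions a C implementation reaches.
* No k-mer deletion, no concurrent mutation, no partial (disk-backed)
  loading; the index file is read whole.
* Branching detection recomputes both neighborhoods; the predicate
  (out-degree > 1 or in-degree > 1, selectable per direction) is a
  definition choice exposed on the CLI.
* Non-branching path compaction and color-set entropy coding are out of
  scope.
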