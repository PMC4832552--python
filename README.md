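# bftrie — a Bloom Filter Trie for pan-genome k-mer indexing

Large resequencing projects produce hundreds of highly similar genomes of
one species — a *pan-genome*. A standard abstraction for it is the
**colored de Bruijn graph** (C-DBG): every k-mer (length-k DNA string) is
a vertex annotated with the set of *colors* — the genomes containing it —
and an edge x → x′ exists exactly when x[2..k] = x′[1..k−1], so edges
never need to be stored.

`bftrie` implements the **Bloom Filter Trie** (BFT): an exact,
incremental, alignment-free and reference-free index for such a graph.
It is aimed at people who need to store and query colored k-mer sets —
pan-genome storage, membership queries with genome attribution, and
edge traversal — without references, alignments, or rebuild-from-scratch
updates.

## The data structure

k-mers (k a multiple of a chunk length l) are stored in a burst trie:
each vertex is a list of containers and each trie level consumes one
length-l chunk.

* An **uncompressed container** is a sorted set of up to c
  (suffix, colors) tuples. Exceeding c *bursts* it.
* A burst replaces it with a **compressed container** holding the q
  distinct length-l suffix prefixes through four structures: a Bloom
  filter `quer` (filter before exact work), a bit array `pref` of 2^λ
  slots recording which |a|-character prefixes occur (λ = 2|a|), the
  sorted |b|-character suffix parts `suf`, and a cluster-start bit array
  `clust`. A stored prefix costs m + 2^λ + q(μ+1) bits overall and only
  μ+1 bits at the margin (μ = 2|b|).
* Membership uses three helpers — `HammingWeight(α, pref)` (cluster
  index of prefix slot α), `Rank(i, clust)` (start of cluster i, or
  |clust|+1), and binary search — and is **exact**: every Bloom filter
  hit is verified, and a *new* prefix is inserted into the first
  container whose filter already (wrongly) claims it, recycling the
  false positive so filters never change after their burst.
* In graph mode, suffix prefixes are stored rotated
  (s′ = s[2..l]s[1]) and the filters hash only interior characters, so
  the four possible successors/predecessors of a k-mer resolve inside a
  single container and cluster: successor enumeration touches at most
  1 + k/l − 1 vertices, predecessor enumeration at most 1 + 4(k/l − 1).

## Worked example

Six 12-mers inserted with k=12, l=4, c=5 (rotation off so the layout is
readable): the first five fill the root's uncompressed container and the
sixth, `gcgccaggaatc`, bursts it.

```python
>>> from bftrie.toy_example import build_toy_trie, NEW_SUFFIX_PREFIX
>>> t = build_toy_trie()
>>> cc = t.root.compressed[0]
>>> cc.q                      # distinct suffix prefixes after the burst
4
>>> cc.suf, cc.clust          # 3 clusters for prefixes {ac, gc, gg}
(['at', 'gt', 'gc', 'ta'], [1, 0, 1, 1])
>>> cc.insert(NEW_SUFFIX_PREFIX, None)   # insert suffix prefix "gtat"
InsertRecord(cluster=4, pos=5, new_prefix=True)
>>> cc.suf[4], cc.clust[4]    # suffix part "at" starts a new cluster in slot 5
('at', 1)
```

The prefix `gt` packs to bits 1011 = 11, i.e. 1-based `pref` slot 12;
its Hamming weight over `pref[1..12]` gives cluster index 4, and `Rank`
finds no fourth cluster, returning |clust|+1 = 5 — so suffix part `at`
lands in `suf[5]` with `clust[5] = 1`.

## Command line

```bash
bft simulate --preset mini --seed 3 -o sim/          # synthetic pan-genome
bft build -k 18 -l 6 -c 50 --min-occ 3 -o pan.bft sim/reads_*.fq
bft query pan.bft queries.txt                        # TSV: kmer, present, colors
bft branching pan.bft queries.txt --mode either
bft info pan.bft
```

`build` treats each input FASTA/FASTQ file (gzip accepted) as one color;
k-mers seen fewer than `--min-occ` times in a file are discarded as
sequencing errors. `simulate` writes per-genome FASTA, per-genome FASTQ
reads, and an exact k-mer→colors truth table for validation.

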