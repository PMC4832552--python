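"""A synthetic six-k-mer toy index (k=12, l=4, c=5) used in docs and tests.

The set is constructed — synthetic, not taken from any dataset — so that
the classic burst arithmetic comes out in round numbers:

* the first five 12-mers fit the root's uncompressed container (c=5);
  the sixth insertion overflows it and bursts;
* the six first chunks collapse to q=4 distinct suffix prefixes
  ({acat, acgt, gcgc, ggta}), i.e. four children, grouped into three
  clusters by their 2-character prefixes {ac, gc, gg};
* with the |a|=2, |b|=2 split, every 2-character prefix packs below
  ``gt`` (slot 12), so inserting the new suffix prefix ``gtat``
  exercises the new-prefix path end to end: pref[12] is set, the
  Hamming weight over pref[1..12] gives cluster index 4, Rank finds no
  4th cluster and returns |clust|+1 = 5, and the suffix part ``at``
  lands in suf[5] with clust[5] = 1.

Built in worked-example mode (``graph_mode=False``): the layout is meant
to be read, so prefixes are stored unrotated.
"""

from __future__ import annotations

from .trie import BFT

#: Six 12-mers; the sixth insertion bursts the root container.
TOY_KMERS = [
    "acatgggtacct",
    "acatttcgcaga",
    "acgtcgatgcta",
    "acgtaacctgag",
    "ggtacgcaatgc",
    "gcgccaggaatc",
]

#: Suffix prefix whose insertion into the burst container demonstrates
#: the new-prefix bookkeeping (pref[12], cluster 4, position 5).
NEW_SUFFIX_PREFIX = "gtat"

K, L, C = 12, 4, 5


def build_toy_trie(colors: list[int] | None = None, seed: int = 0) -> BFT:
    """Insert the six toy k-mers (distinct colors by default) and return the trie."""
    t = BFT(k=K, l=L, c=C, graph_mode=False, seed=seed)
    if colors is None:
        colors = list(range(1, len(TOY_KMERS) + 1))
    for kmer, color in zip(TOY_KMERS, colors):
        t.insert(kmer, color)
    return t
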