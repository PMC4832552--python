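"""Trie-level behavior: exact membership, insertion paths, bursts,
incrementality and capacity invariants."""

import random

import pytest

from bftrie import BFT
from bftrie.colors import resolve
from bftrie.toy_example import NEW_SUFFIX_PREFIX, TOY_KMERS, build_toy_trie
from conftest import random_kmer


def test_empty_trie_contains_nothing():
    t = BFT(k=12, l=4, c=5)
    assert t.contains("acgtacgtacgt") is None
    assert len(t) == 0


def test_rejects_invalid_kmers():
    t = BFT(k=12, l=4, c=5)
    with pytest.raises(ValueError):
        t.contains("acgt")  # wrong length
    with pytest.raises(ValueError):
        t.insert("acgtacgtacgn", 1)
    with pytest.raises(ValueError):
        t.insert("acgtacgtacgt", 0)  # colors are 1-based
    with pytest.raises(ValueError):
        BFT(k=13, l=4, c=5)  # k not a multiple of l


def test_toy_burst_fires_on_sixth_insertion():
    """Five suffixes sit in the root's uncompressed container; the sixth
    overflows it and bursts into a compressed container with 4 prefixes."""
    t = BFT(k=12, l=4, c=5, graph_mode=False)
    for kmer in TOY_KMERS[:5]:
        t.insert(kmer, 1)
    assert not t.root.compressed
    assert len(t.root.uncompressed) == 5
    t.insert(TOY_KMERS[5], 1)
    assert len(t.root.compressed) == 1
    assert t.root.uncompressed is None
    cc = t.root.compressed[0]
    assert cc.q == 4
    assert len({s for s, _ in cc.iter_entries()}) == 4
    for kmer in TOY_KMERS:
        assert t.contains(kmer) is not None


def test_toy_new_prefix_insertion_bookkeeping():
    """Inserting the gtat suffix prefix sets pref slot 12 and opens a new
    cluster: index 4, start position 5, suffix part at suf[5], clust[5]=1."""
    cc = build_toy_trie().root.compressed[0]
    assert not (cc.pref >> 11) & 1
    rec = cc.insert(NEW_SUFFIX_PREFIX, None)
    assert (cc.pref >> 11) & 1
    assert rec.new_prefix
    assert rec.cluster == 4
    assert rec.pos == 5
    assert cc.suf[4] == "at"
    assert cc.clust[4] == 1


def test_reinsertion_merges_colors_only():
    t = BFT(k=12, l=4, c=5)
    t.insert("acgtacgtacgt", 1)
    t.insert("acgtacgtacgt", 2)
    assert len(t) == 1
    assert t.colors_of("acgtacgtacgt") == [1, 2]


def test_exactness_against_hash_map_oracle_two_orders(rng):
    """Presence and colors agree with a plain map for 5,000 k-mers inserted
    in two different random orders; absent probes never hit."""
    k = 16
    pairs = []
    oracle = {}
    while len(oracle) < 5000:
        km = random_kmer(rng, k)
        col = rng.randint(1, 6)
        pairs.append((km, col))
        oracle.setdefault(km, set()).add(col)
    for order_seed in (1, 2):
        shuffled = pairs[:]
        random.Random(order_seed).shuffle(shuffled)
        t = BFT(k=k, l=4, c=8, seed=order_seed)
        for km, col in shuffled:
            t.insert(km, col)
        assert len(t) == len(oracle)
        for km, cols in oracle.items():
            assert t.colors_of(km) == sorted(cols)
        misses = 0
        while misses < 5000:
            km = random_kmer(rng, k)
            if km in oracle:
                continue
            assert t.contains(km) is None
            misses += 1


def test_burst_conserves_kmers_and_colors(rng):
    """The (k-mer -> colors) mapping is identical before and after bursts:
    the pre-burst suffix set equals the union of prefix x child suffixes."""
    k, c = 12, 5
    t = BFT(k=k, l=4, c=c, seed=3)
    oracle = {}
    for _ in range(400):
        km = random_kmer(rng, k)
        col = rng.randint(1, 3)
        t.insert(km, col)
        oracle.setdefault(km, set()).add(col)
    reconstructed = {}
    for km, ref in t.iter_kmers():
        assert km not in reconstructed
        reconstructed[km] = set(resolve(ref, t.color_table).indices())
    assert reconstructed == oracle


def test_single_prefix_burst_recurses():
    """c+1 suffixes sharing one first chunk burst into q=1 and an overfull
    child, which bursts in turn."""
    t = BFT(k=12, l=4, c=2, graph_mode=False)
    kmers = ["aaaa" + "acgt" + s for s in ("acgt", "ggca", "ttac")]
    for km in kmers:
        t.insert(km, 1)
    cc = t.root.compressed[0]
    assert cc.q == 1
    child = cc.children[0]
    assert len(child.compressed) == 1  # recursive burst happened
    assert all(t.contains(km) is not None for km in kmers)


def test_no_uncompressed_container_exceeds_capacity_at_rest(rng):
    t = BFT(k=12, l=4, c=4, seed=5)
    for _ in range(600):
        t.insert(random_kmer(rng, 12), 1)
    for v in t.iter_vertices():
        if v.uncompressed is not None:
            assert len(v.uncompressed) <= t.c


def test_incremental_insertion_equals_bulk(rng):
    """Indexing genome A then genome B answers exactly like indexing A∪B."""
    k = 12
    a = {random_kmer(rng, k) for _ in range(300)}
    b = {random_kmer(rng, k) for _ in range(300)}
    incremental = BFT(k=k, l=4, c=5, seed=9)
    for km in sorted(a):
        incremental.insert(km, 1)
    for km in sorted(b):
        incremental.insert(km, 2)
    bulk = {km: {1} for km in a}
    for km in b:
        bulk.setdefault(km, set()).add(2)
    for km, cols in bulk.items():
        assert incremental.colors_of(km) == sorted(cols)
    assert len(incremental) == len(bulk)


def test_resize_triggered_by_post_burst_growth(rng):
    """Many inserts into one container eventually re-split |a|/|b| without
    changing any membership answer."""
    t = BFT(k=8, l=8, c=4, graph_mode=False, bf_bits=8, bf_hashes=1,
            seed=1, resize_factor=1)
    inserted = set()
    while len(inserted) < 3000:
        km = random_kmer(rng, 8)
        if km not in inserted:
            t.insert(km, 1)
            inserted.add(km)
    grown = [cc for v in t.iter_vertices() for cc in v.compressed if cc.la > 8 // 2]
    assert grown, "expected at least one resized container"
    for km in sorted(inserted)[:500]:
        assert t.contains(km) is not None
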