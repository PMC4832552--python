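"""Container algorithms: weight/rank helpers, exact membership, insertion,
cluster canonical form, and the |a|/|b| resize."""

import itertools
import random

import pytest

from bftrie import BloomFilter, CompressedContainer, UncompressedContainer, hamming_weight, rank
from bftrie import dna
from bftrie.containers import choose_split


def make_cc(la=2, lb=2, m=64, terminal=True, seed=0):
    return CompressedContainer(la, lb, BloomFilter(m, 2, seed), terminal=terminal)


def direct_construction(prefixes, la):
    """Oracle: (pref bits, suf, clust) built by grouping on a and sorting."""
    pref = 0
    suf, clust = [], []
    prev_a = None
    for s in sorted(set(prefixes)):
        a, b = s[:la], s[la:]
        pref |= 1 << (dna.prefix_index(a) - 1)
        clust.append(1 if a != prev_a else 0)
        suf.append(b)
        prev_a = a
    return pref, suf, clust


# -- helpers ----------------------------------------------------------------


def test_hamming_weight_empty_and_range():
    assert hamming_weight(5, 0, 16) == 0
    with pytest.raises(ValueError):
        hamming_weight(0, 0, 16)
    with pytest.raises(ValueError):
        hamming_weight(17, 0, 16)


def test_hamming_weight_matches_popcount_oracle(rng):
    for _ in range(200):
        size = rng.choice([4, 16, 64, 256])
        bits = rng.getrandbits(size)
        alpha = rng.randint(1, size)
        naive = sum((bits >> j) & 1 for j in range(alpha))
        assert hamming_weight(alpha, bits, size) == naive


def test_rank_examples_and_scan_oracle(rng):
    assert rank(3, [1, 0, 1, 1]) == 4
    assert rank(4, [1, 0, 1, 1]) == 5  # not found -> |clust|+1
    with pytest.raises(ValueError):
        rank(0, [1])
    for _ in range(200):
        clust = [rng.randint(0, 1) for _ in range(rng.randint(0, 20))]
        total = sum(clust)
        for i in range(1, total + 2):
            positions = [p for p, b in enumerate(clust, 1) if b]
            expected = positions[i - 1] if i <= total else len(clust) + 1
            assert rank(i, clust) == expected


# -- uncompressed container --------------------------------------------------


def test_uc_search_empty():
    uc = UncompressedContainer(5)
    assert uc.search("acgt") == (False, 1)


def test_uc_sortedness_and_search_oracle(rng):
    uc = UncompressedContainer(1000)
    stored = set()
    for _ in range(80):
        s = "".join(rng.choice("acgt") for _ in range(6))
        if s not in stored:
            uc.insert(s, None)
            stored.add(s)
        assert uc.suffixes == sorted(uc.suffixes)
    for _ in range(200):
        s = "".join(rng.choice("acgt") for _ in range(6))
        found, pos = uc.search(s)
        assert found == (s in stored)
        if found:
            assert uc.suffixes[pos - 1] == s
    with pytest.raises(ValueError):
        uc.search("acgtacgt")  # wrong length
    with pytest.raises(ValueError):
        uc.insert(uc.suffixes[0], None)  # duplicate


# -- compressed container ----------------------------------------------------


def test_cc_insert_into_empty_single_cluster():
    cc = make_cc()
    rec = cc.insert("acgt", "x")
    assert (rec.cluster, rec.pos, rec.new_prefix) == (1, 1, True)
    assert cc.q == 1 and cc.clust == [1]
    assert cc.contains("acgt").found


def test_cc_cluster_canonical_form_is_order_independent(rng):
    """(pref, suf, clust) depends only on the stored set, not insertion order."""
    for trial in range(20):
        n = rng.randint(1, 40)
        prefixes = list({"".join(rng.choice("acgt") for _ in range(4)) for _ in range(n)})
        exp_pref, exp_suf, exp_clust = direct_construction(prefixes, la=2)
        for _ in range(3):
            rng.shuffle(prefixes)
            cc = make_cc()
            for s in prefixes:
                cc.insert(s, s)
            assert cc.pref == exp_pref
            assert cc.suf == exp_suf
            assert cc.clust == exp_clust
            assert cc.children == [a + b for a, b in zip(
                [s[:2] for s in sorted(prefixes)], [s[2:] for s in sorted(prefixes)])]


def test_cc_contains_matches_set_oracle(rng):
    universe = ["".join(p) for p in itertools.product("acgt", repeat=4)]
    inserted = set(rng.sample(universe, 50))
    cc = make_cc()
    for s in inserted:
        cc.insert(s, None)
    for s in universe:
        assert cc.contains(s).found == (s in inserted)


def test_cc_bookkeeping_invariants(rng):
    cc = make_cc()
    seen = set()
    for _ in range(60):
        s = "".join(rng.choice("acgt") for _ in range(4))
        if s in seen:
            with pytest.raises(ValueError):
                cc.insert(s, None)
            continue
        cc.insert(s, None)
        seen.add(s)
        assert cc.pref.bit_count() == sum(cc.clust)  # one cluster per prefix
        assert len(cc.suf) == len(cc.clust) == len(cc.children)
        if cc.q:
            assert cc.clust[0] == 1


def test_cc_footprint_formula():
    cc = make_cc(la=2, lb=2, m=64)
    for s in ("acgt", "acta", "ggca"):
        cc.insert(s, None)
    assert cc.footprint_bits() == 64 + 2**4 + 3 * (4 + 1)


def test_cc_entry_enumeration_roundtrip(rng):
    cc = make_cc(la=1, lb=3)
    stored = {"".join(rng.choice("acgt") for _ in range(4)) for _ in range(30)}
    for s in stored:
        cc.insert(s, s)
    entries = list(cc.iter_entries())
    assert [s for s, _ in entries] == sorted(stored)
    assert all(payload == s for s, payload in entries)


# -- resize ------------------------------------------------------------------


def test_resize_noop_when_sparse():
    cc = make_cc(la=1, lb=3)
    cc.insert("acgt", None)
    assert not cc.resize_split()  # 2^lambda' growth dominates for q=1
    assert (cc.la, cc.lb) == (1, 3)


def test_resize_dense_container_shrinks_and_preserves_membership(rng):
    # every length-1 prefix occurs many times: growing |a| pays off
    cc = make_cc(la=1, lb=5, m=16)
    stored = {"".join(rng.choice("acgt") for _ in range(6)) for _ in range(400)}
    for s in stored:
        cc.insert(s, s)
    before = cc.pref_size + cc.q * cc.mu
    assert cc.resize_split()
    after = cc.pref_size + cc.q * cc.mu
    assert after < before
    assert cc.lb >= 2
    for s in stored:
        res = cc.contains(s)
        assert res.found and cc.children[res.pos - 1] == s
    sample = [s for s in ("aaaaaa", "tttttt", "acacac") if s not in stored]
    assert all(not cc.contains(s).found for s in sample)


def test_choose_split_fallback_and_bound():
    # toy geometry: no |a| satisfies the burst inequality -> l//2 fallback
    assert choose_split(4, 6, m=128) == 2
    # large q admits the smallest |a| satisfying m + 2^lambda <= q(lambda-1)
    la = choose_split(9, 249, m=128)
    lam = 2 * la
    assert 128 + 2**lam <= 249 * (lam - 1)
    assert la == 1
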