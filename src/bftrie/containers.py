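"""The two vertex container types of the trie.

An *uncompressed* container is a small sorted set of (suffix, colors)
tuples with capacity ``c``; exceeding the capacity bursts it.  A burst
replaces it with a *compressed* container storing the length-l suffix
prefixes of its tuples through four structures:

``quer``   a Bloom filter over the suffix prefixes (probe before exact work);
``pref``   a bit array of 2^lambda slots recording which |a|-character
           prefixes occur, where lambda = 2|a|;
``suf``    the |b|-character suffix parts, sorted by full suffix prefix;
``clust``  one bit per ``suf`` entry marking cluster starts, a cluster
           being the run of consecutive entries sharing a prefix.

Membership is exact: a Bloom hit is always verified against pref/suf/clust.
All positions in this module's public results are 1-based, matching the
usual presentation of the rank/weight helpers.
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Any, Iterator, NamedTuple

from . import dna
from .bloom import BloomFilter

MIN_SUFFIX_LEN = 2  # |b| >= 2: graph traversal needs both variable characters in suf


def hamming_weight(alpha: int, pref: int, size: int) -> int:
    """Number of 1s in pref[1..alpha] — the cluster index of prefix slot alpha.

    ``pref`` is the bit array as an integer (bit j-1 <-> slot j), ``size``
    its slot count 2^lambda.  Word-wise popcount; the linear bound on this
    helper is an upper bound, not a mandate.
    """
    if not 1 <= alpha <= size:
        raise ValueError(f"alpha {alpha} out of range [1, {size}]")
    return (pref & ((1 << alpha) - 1)).bit_count()


def rank(i: int, clust: list[int]) -> int:
    """Position of the i-th set bit of clust; |clust|+1 when absent.

    Deliberately the naive left-to-right scan: clust holds at most c+1
    bits, and the scan is cheaper than maintaining rank samples.
    """
    if i < 1:
        raise ValueError(f"cluster index must be >= 1, got {i}")
    seen = 0
    for pos, bit in enumerate(clust, start=1):
        seen += bit
        if seen == i:
            return pos
    return len(clust) + 1


class ContainsResult(NamedTuple):
    found: bool
    cluster: int  # cluster index of the prefix (existing or would-be)
    pos: int      # 1-based match position in suf, or the insertion point


class InsertRecord(NamedTuple):
    cluster: int
    pos: int
    new_prefix: bool


class UncompressedContainer:
    """Bounded sorted set of (suffix, color-ref) tuples.

    Sortedness is the container's only index: membership is a binary
    search.  ``capacity`` may be exceeded by exactly one entry,
    transiently, which is the burst trigger handled by the trie.
    """

    __slots__ = ("suffixes", "colors", "capacity")

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.suffixes: list[str] = []
        self.colors: list[Any] = []
        self.capacity = capacity

    def __len__(self) -> int:
        return len(self.suffixes)

    def search(self, s: str) -> tuple[bool, int]:
        """(found, 1-based position) — position is the insertion point on a miss."""
        if self.suffixes and len(s) != len(self.suffixes[0]):
            raise ValueError(
                f"suffix length {len(s)} != stored length {len(self.suffixes[0])}")
        i = bisect_left(self.suffixes, s)
        found = i < len(self.suffixes) and self.suffixes[i] == s
        return found, i + 1

    def insert(self, s: str, color_ref: Any) -> int:
        """Insert a new suffix at its sorted position; returns the 1-based slot.

        Duplicates are the caller's responsibility (re-insertion of an
        existing k-mer only merges colors, at the trie level).
        """
        found, pos = self.search(s)
        if found:
            raise ValueError(f"duplicate suffix {s!r}")
        self.suffixes.insert(pos - 1, s)
        self.colors.insert(pos - 1, color_ref)
        return pos

    def tuples(self) -> Iterator[tuple[str, Any]]:
        return zip(self.suffixes, self.colors)


class CompressedContainer:
    """Burst product: quartet (quer, pref, suf, clust) plus child links.

    ``children[i]`` parallels ``suf[i]``: a child vertex below maximal
    depth, or the color reference of the terminal k-mer when ``terminal``
    (the stored prefix is the whole remaining suffix).

    The container is agnostic of graph-mode rotation: callers hand it the
    storage form of each suffix prefix.  ``quer`` is also managed by the
    caller (burst fills it; later inserts recycle false positives and
    leave it unchanged).
    """

    __slots__ = ("la", "lb", "quer", "pref", "suf", "clust", "children", "terminal")

    def __init__(self, la: int, lb: int, quer: BloomFilter, terminal: bool = False):
        if la < 1 or lb < MIN_SUFFIX_LEN:
            raise ValueError(f"invalid split |a|={la}, |b|={lb} (|b| >= {MIN_SUFFIX_LEN})")
        self.la = la
        self.lb = lb
        self.quer = quer
        self.pref = 0                       # int bitmask over 4^la slots
        self.suf: list[str] = []
        self.clust: list[int] = []
        self.children: list[Any] = []
        self.terminal = terminal

    # -- derived quantities -------------------------------------------------

    @property
    def l(self) -> int:
        return self.la + self.lb

    @property
    def q(self) -> int:
        return len(self.suf)

    @property
    def lam(self) -> int:
        """lambda: bit length of the prefix part a."""
        return 2 * self.la

    @property
    def mu(self) -> int:
        """mu: bit length of the suffix part b."""
        return 2 * self.lb

    @property
    def pref_size(self) -> int:
        return 1 << self.lam

    def footprint_bits(self) -> int:
        """m + 2^lambda + q(mu+1): the container's substring storage cost."""
        return self.quer.m + self.pref_size + self.q * (self.mu + 1)

    def _split(self, s_pref: str) -> tuple[str, str]:
        if len(s_pref) != self.l:
            raise ValueError(f"suffix prefix length {len(s_pref)} != l={self.l}")
        return s_pref[: self.la], s_pref[self.la :]

    # -- exact membership ---------------------------------------------------

    def contains(self, s_pref: str) -> ContainsResult:
        """Exact membership of a (storage-form) suffix prefix.

        On a miss the returned position is the 1-based slot where the
        entry would be inserted, and ``cluster`` the prefix's cluster
        index (would-be index when the prefix itself is absent).
        """
        a, b = self._split(s_pref)
        alpha = dna.prefix_index(a)
        if not (self.pref >> (alpha - 1)) & 1:
            w = hamming_weight(alpha, self.pref, self.pref_size)
            return ContainsResult(False, w, rank(w + 1, self.clust))
        i = hamming_weight(alpha, self.pref, self.pref_size)
        pos = rank(i, self.clust)
        j = pos
        while j <= self.q and (j == pos or self.clust[j - 1] == 0):
            bj = self.suf[j - 1]
            if bj == b:
                return ContainsResult(True, i, j)
            if bj > b:
                return ContainsResult(False, i, j)
            j += 1
        return ContainsResult(False, i, j)

    # -- insertion ----------------------------------------------------------

    def insert(self, s_pref: str, payload: Any) -> InsertRecord:
        """Insert a (storage-form) suffix prefix with its child/color payload.

        quer is untouched: at burst time the caller fills it, and any
        later insertion lands here precisely because quer already claims
        the prefix (false-positive recycling).
        """
        a, b = self._split(s_pref)
        alpha = dna.prefix_index(a)
        if not (self.pref >> (alpha - 1)) & 1:
            # new prefix: record it, then locate the new cluster's start
            self.pref |= 1 << (alpha - 1)
            i = hamming_weight(alpha, self.pref, self.pref_size)
            pos = rank(i, self.clust)
            self.suf.insert(pos - 1, b)
            self.clust.insert(pos - 1, 1)
            self.children.insert(pos - 1, payload)
            return InsertRecord(i, pos, True)
        i = hamming_weight(alpha, self.pref, self.pref_size)
        pos_cluster = rank(i, self.clust)
        j = pos_cluster
        while j <= self.q and (j == pos_cluster or self.clust[j - 1] == 0):
            bj = self.suf[j - 1]
            if bj == b:
                raise ValueError(f"duplicate suffix prefix {s_pref!r}")
            if bj > b:
                break
            j += 1
        pos = j
        if pos == pos_cluster:
            # b is the new lexicographically smallest of its cluster
            self.clust.insert(pos - 1, 1)
            self.clust[pos] = 0
        else:
            self.clust.insert(pos - 1, 0)
        self.suf.insert(pos - 1, b)
        self.children.insert(pos - 1, payload)
        return InsertRecord(i, pos, False)

    # -- enumeration & resizing ---------------------------------------------

    def iter_entries(self) -> Iterator[tuple[str, Any]]:
        """Yield (storage-form suffix prefix, payload) in sorted order."""
        alphas = []
        p = self.pref
        slot = 0
        while p:
            low = p & -p
            alphas.append(low.bit_length())
            p ^= low
        cluster = -1
        for j in range(self.q):
            if self.clust[j] == 1:
                cluster += 1
            a = dna.decode(alphas[cluster] - 1, self.la)
            yield a + self.suf[j], self.children[j]

    def resize_split(self) -> bool:
        """Grow |a| (shrink |b|) while 2^lambda' + q*mu' strictly shrinks.

        Sorted order by full suffix prefix is split-invariant, so only
        pref/suf/clust are recomputed; children keep their order and quer
        is untouched (its hashes read only interior characters, which a
        resize does not move).  Returns True if a resize happened.
        """
        changed = False
        while self.lb - 1 >= MIN_SUFFIX_LEN:
            la2, lb2 = self.la + 1, self.lb - 1
            if (1 << (2 * la2)) + self.q * (2 * lb2) >= self.pref_size + self.q * self.mu:
                break
            entries = list(self.iter_entries())
            self.la, self.lb = la2, lb2
            self.pref = 0
            self.suf = []
            self.clust = []
            new_children = []
            prev_a = None
            for s_pref, payload in entries:
                a, b = s_pref[:la2], s_pref[la2:]
                self.pref |= 1 << (dna.prefix_index(a) - 1)
                self.clust.append(1 if a != prev_a else 0)
                self.suf.append(b)
                new_children.append(payload)
                prev_a = a
            self.children = new_children
            changed = True
        return changed


def choose_split(l: int, q: int, m: int) -> int:
    """Burst-time prefix length |a| for ``q`` suffix prefixes and BF size ``m``.

    Smallest |a| with |b| >= 2 whose footprint satisfies
    m + 2^lambda <= q(lambda - 1); when no |a| does (small l or q), fall
    back to |a| = l//2 clamped so |b| >= 2.
    """
    for la in range(1, l - MIN_SUFFIX_LEN + 1):
        lam = 2 * la
        if m + (1 << lam) <= q * (lam - 1):
            return la
    return max(1, min(l // 2, l - MIN_SUFFIX_LEN))
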