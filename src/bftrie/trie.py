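"""The Bloom Filter Trie: an exact, incremental index of colored k-mers.

A trie vertex is a list of containers — zero or more compressed, plus at
most one uncompressed at the tail.  Each level consumes one length-l
chunk of the k-mer: a chunk found in a compressed container leads to the
child vertex holding the rest; a k-mer whose chunk fires no container's
Bloom filter lives whole in the vertex's uncompressed container until a
burst pushes it down.

Look-ups are exact despite the Bloom filters: a filter hit is always
verified against the container's pref/suf/clust arrays, and insertions
respect the *first-firing-container* discipline — a new suffix prefix
goes into the first compressed container whose filter (wrongly) claims
it, recycling the false positive, so the container a look-up stops on is
the container an insertion would have used.  Filters never change after
their burst, which makes that stopping container stable over the life of
the index.

In ``graph_mode`` (the default) suffix prefixes are stored left-rotated
and the filters hash only interior characters, so the four possible
de Bruijn successors/predecessors of any k-mer resolve inside a single
container — the basis of edge traversal without stored edges.
"""

from __future__ import annotations

from typing import Any, Iterator, Optional

from . import dna
from .bloom import BloomFilter, default_num_hashes
from .colors import ColorSet, ColorTable, ExternalRef, resolve
from .containers import (
    CompressedContainer,
    UncompressedContainer,
    choose_split,
)

__all__ = ["BFT", "Vertex"]


class Vertex:
    """A trie vertex: compressed containers plus at most one uncompressed."""

    __slots__ = ("compressed", "uncompressed")

    def __init__(self) -> None:
        self.compressed: list[CompressedContainer] = []
        self.uncompressed: Optional[UncompressedContainer] = None


class BFT:
    """Bloom Filter Trie over k-mers with per-genome color annotations.

    Parameters
    ----------
    k : k-mer length; must be a multiple of ``l``.
    l : chunk length consumed per trie level (>= 3).
    c : uncompressed-container capacity; exceeding it bursts.
    graph_mode : store rotated prefixes + restricted hashing, enabling
        single-container successor/predecessor traversal.  Turn off only
        to inspect the unrotated container layout.
    bf_bits, bf_hashes : Bloom filter geometry for burst-created
        containers; ``bf_hashes=None`` derives the count from bf_bits/c.
    seed : hash seed shared by every filter in the trie.
    resize_factor : a compressed container is re-split when its
        q(mu+1) tail cost exceeds this multiple of the burst-time
        uncompressed cost estimate (c+1) * 2l bits.
    """

    def __init__(
        self,
        k: int,
        l: int,
        c: int = 248,
        graph_mode: bool = True,
        bf_bits: int = 128,
        bf_hashes: int | None = None,
        seed: int = 0,
        resize_factor: int = 8,
    ):
        if l < 3:
            raise ValueError("chunk length l must be >= 3")
        if k < l or k % l != 0:
            raise ValueError(f"k={k} must be a positive multiple of l={l}")
        if c < 1:
            raise ValueError("capacity c must be positive")
        self.k = k
        self.l = l
        self.c = c
        self.graph_mode = graph_mode
        self.bf_bits = bf_bits
        self.bf_hashes = bf_hashes if bf_hashes is not None else default_num_hashes(bf_bits, c)
        self.seed = seed
        self.resize_factor = resize_factor
        self.root = Vertex()
        self.n_kmers = 0
        self.color_table: Optional[ColorTable] = None

    # -- basic properties ---------------------------------------------------

    @property
    def height_max(self) -> int:
        return self.k // self.l - 1

    def __len__(self) -> int:
        return self.n_kmers

    def _storage_form(self, s_pref: str) -> str:
        return dna.rotate_prefix(s_pref) if self.graph_mode else s_pref

    def _new_filter(self) -> BloomFilter:
        return BloomFilter(self.bf_bits, self.bf_hashes, self.seed, restricted=self.graph_mode)

    def _check(self, x: str) -> str:
        x = dna.validate(x)
        if len(x) != self.k:
            raise ValueError(f"k-mer length {len(x)} != k={self.k}")
        return x

    # -- look-up ------------------------------------------------------------

    def first_firing(self, v: Vertex, s_pref: str) -> Optional[CompressedContainer]:
        """First compressed container of ``v`` whose filter claims ``s_pref``.

        The filters are probed with the unrotated prefix (restricted
        hashing reads its interior); this is the container any look-up or
        insertion of ``s_pref`` stops on.
        """
        for cc in v.compressed:
            if cc.quer.may_contain(s_pref):
                return cc
        return None

    def contains(self, x: str) -> Optional[Any]:
        """Color reference of k-mer ``x``, or None when absent.

        Exact: never a false positive (Bloom hits are verified) and never
        a false negative.
        """
        x = self._check(x)
        ref, _ = self._descend(self.root, x)
        return ref

    def __contains__(self, x: str) -> bool:
        return self.contains(x) is not None

    def colors_of(self, x: str) -> Optional[list[int]]:
        """Sorted 1-based color indices of ``x``, or None when absent."""
        ref = self.contains(x)
        if ref is None:
            return None
        return resolve(ref, self.color_table).indices()

    def _descend(self, v: Vertex, xsuf: str) -> tuple[Optional[Any], int]:
        """Walk ``xsuf`` down from vertex ``v``; (color ref | None, vertices visited)."""
        visited = 0
        while True:
            visited += 1
            s_pref = xsuf[: self.l]
            cc = self.first_firing(v, s_pref)
            if cc is not None:
                res = cc.contains(self._storage_form(s_pref))
                if not res.found:
                    # cannot be in any later container: insertion would
                    # have recycled this very filter hit
                    return None, visited
                if cc.terminal:
                    return cc.children[res.pos - 1], visited
                v = cc.children[res.pos - 1]
                xsuf = xsuf[self.l :]
                continue
            uc = v.uncompressed
            if uc is None:
                return None, visited
            found, pos = uc.search(xsuf)
            return (uc.colors[pos - 1], visited) if found else (None, visited)

    # -- insertion ----------------------------------------------------------

    def insert(self, x: str, i_color: int) -> None:
        """Insert k-mer ``x`` with color ``i_color``.

        Re-inserting a present k-mer only merges the color into its set.
        The look-up's stopping container receives new material: the first
        filter-firing compressed container (false-positive recycling), or
        the vertex's uncompressed container, created on demand and burst
        on overflow.
        """
        x = self._check(x)
        if i_color < 1:
            raise ValueError(f"color index must be >= 1, got {i_color}")
        v = self.root
        xsuf = x
        while True:
            s_pref = xsuf[: self.l]
            cc = self.first_firing(v, s_pref)
            if cc is not None:
                stored = self._storage_form(s_pref)
                res = cc.contains(stored)
                if res.found:
                    if cc.terminal:
                        self._merge_color(cc.children, res.pos - 1, i_color)
                        return
                    v = cc.children[res.pos - 1]
                    xsuf = xsuf[self.l :]
                    continue
                # absent: this container recycles the false positive
                if cc.terminal:
                    cc.insert(stored, ColorSet.of(i_color))
                else:
                    child = Vertex()
                    child.uncompressed = UncompressedContainer(self.c)
                    child.uncompressed.insert(xsuf[self.l :], ColorSet.of(i_color))
                    cc.insert(stored, child)
                self.n_kmers += 1
                self._maybe_resize(cc)
                return
            uc = v.uncompressed
            if uc is None:
                uc = v.uncompressed = UncompressedContainer(self.c)
            found, pos = uc.search(xsuf)
            if found:
                self._merge_color(uc.colors, pos - 1, i_color)
                return
            uc.insert(xsuf, ColorSet.of(i_color))
            self.n_kmers += 1
            if len(uc) > self.c:
                self._burst(v, uc)
            return

    def _merge_color(self, slots: list[Any], idx: int, i_color: int) -> None:
        ref = slots[idx]
        if isinstance(ref, ExternalRef):
            cs = resolve(ref, self.color_table).copy()
            cs.add(i_color)
            slots[idx] = cs  # inline again; the next compression re-tables it
        else:
            ref.add(i_color)

    def _maybe_resize(self, cc: CompressedContainer) -> None:
        if cc.q * (cc.mu + 1) > self.resize_factor * (self.c + 1) * 2 * self.l:
            cc.resize_split()

    # -- burst --------------------------------------------------------------

    def _burst(self, v: Vertex, uc: UncompressedContainer) -> None:
        """Replace an overflowing uncompressed container by a compressed one.

        Each stored suffix s splits into a length-l prefix (inserted into
        the new container and its Bloom filter) and the remaining suffix
        (moved, with its colors, into the matching child's uncompressed
        container).  At maximal depth the suffixes *are* the prefixes and
        colors attach to the container entries directly.  The k-mer set
        and color mapping are preserved exactly; an overfull child bursts
        recursively.
        """
        suffix_len = len(uc.suffixes[0])
        terminal = suffix_len == self.l
        groups: dict[str, list[tuple[str, Any]]] = {}
        for s, ref in uc.tuples():
            groups.setdefault(s[: self.l], []).append((s[self.l :], ref))
        la = choose_split(self.l, len(groups), self.bf_bits)
        cc = CompressedContainer(la, self.l - la, self._new_filter(), terminal=terminal)
        overfull: list[Vertex] = []
        for s_pref, items in groups.items():
            cc.quer.insert(s_pref)
            if terminal:
                (_, ref), = items
                cc.insert(self._storage_form(s_pref), ref)
            else:
                child = Vertex()
                child.uncompressed = UncompressedContainer(self.c)
                for ssuf, ref in items:
                    child.uncompressed.insert(ssuf, ref)
                cc.insert(self._storage_form(s_pref), child)
                if len(child.uncompressed) > self.c:
                    overfull.append(child)
        v.uncompressed = None
        v.compressed.append(cc)
        for child in overfull:
            self._burst(child, child.uncompressed)

    # -- enumeration --------------------------------------------------------

    def iter_kmers(self) -> Iterator[tuple[str, Any]]:
        """Yield every stored (k-mer, color reference)."""
        yield from self._iter_vertex(self.root, "")

    def _iter_vertex(self, v: Vertex, prefix: str) -> Iterator[tuple[str, Any]]:
        for cc in v.compressed:
            for stored, payload in cc.iter_entries():
                s_pref = dna.unrotate_prefix(stored) if self.graph_mode else stored
                if cc.terminal:
                    yield prefix + s_pref, payload
                else:
                    yield from self._iter_vertex(payload, prefix + s_pref)
        if v.uncompressed is not None:
            for s, ref in v.uncompressed.tuples():
                yield prefix + s, ref

    def iter_color_slots(self) -> Iterator[tuple[list[Any], int]]:
        """Yield (slot list, index) for every color-annotation slot."""
        stack = [self.root]
        while stack:
            v = stack.pop()
            for cc in v.compressed:
                if cc.terminal:
                    for i in range(len(cc.children)):
                        yield cc.children, i
                else:
                    stack.extend(cc.children)
            if v.uncompressed is not None:
                for i in range(len(v.uncompressed.colors)):
                    yield v.uncompressed.colors, i

    # -- diagnostics --------------------------------------------------------

    def iter_vertices(self) -> Iterator[Vertex]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            for cc in v.compressed:
                if not cc.terminal:
                    stack.extend(cc.children)

    def stats(self) -> dict[str, int]:
        """Structural summary: vertex/container counts and bit footprints."""
        n_vertices = n_cc = n_uc = 0
        container_bits = 0
        for v in self.iter_vertices():
            n_vertices += 1
            for cc in v.compressed:
                n_cc += 1
                container_bits += cc.footprint_bits()
            if v.uncompressed is not None:
                n_uc += 1
                container_bits += sum(2 * len(s) for s in v.uncompressed.suffixes)
        return {
            "k": self.k,
            "l": self.l,
            "c": self.c,
            "n_kmers": self.n_kmers,
            "n_vertices": n_vertices,
            "n_compressed_containers": n_cc,
            "n_uncompressed_containers": n_uc,
            "container_bits": container_bits,
        }
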