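"""Binary on-disk format for the index.

Layout: a fixed header (magic, version, k/l/c, Bloom geometry, seed,
counts), a pre-order dump of the vertex tree, then the color-table
appendix.  The round trip is bit-exact: writing and re-reading an index
yields identical answers to every query.
"""

from __future__ import annotations

import struct
from typing import Any, BinaryIO

from .bloom import BloomFilter
from .colors import ColorSet, ColorTable, ExternalRef
from .containers import CompressedContainer, UncompressedContainer
from .trie import BFT, Vertex

MAGIC = b"BFTI"
VERSION = 1

_HEADER = struct.Struct("<4sBBHHIIBQQI")
# magic, version, flags, k, l, c, bf_bits, bf_hashes, seed, n_kmers, resize_factor


def _w_bits(fh: BinaryIO, bits: int, nbits: int) -> None:
    nbytes = (nbits + 7) // 8
    fh.write(bits.to_bytes(nbytes, "little"))


def _r_bits(fh: BinaryIO, nbits: int) -> int:
    nbytes = (nbits + 7) // 8
    return int.from_bytes(fh.read(nbytes), "little")


def _w_colorset(fh: BinaryIO, cs: ColorSet) -> None:
    raw = cs.bits.to_bytes((cs.bits.bit_length() + 7) // 8 or 1, "little")
    fh.write(struct.pack("<I", len(raw)))
    fh.write(raw)


def _r_colorset(fh: BinaryIO) -> ColorSet:
    (n,) = struct.unpack("<I", fh.read(4))
    return ColorSet(int.from_bytes(fh.read(n), "little"))


def _w_colorref(fh: BinaryIO, ref: Any) -> None:
    if isinstance(ref, ExternalRef):
        fh.write(b"\x01")
        fh.write(struct.pack("<I", ref.index))
    else:
        fh.write(b"\x00")
        _w_colorset(fh, ref)


def _r_colorref(fh: BinaryIO) -> Any:
    tag = fh.read(1)
    if tag == b"\x01":
        (idx,) = struct.unpack("<I", fh.read(4))
        return ExternalRef(idx)
    return _r_colorset(fh)


def _w_str(fh: BinaryIO, s: str) -> None:
    b = s.encode("ascii")
    fh.write(struct.pack("<H", len(b)))
    fh.write(b)


def _r_str(fh: BinaryIO) -> str:
    (n,) = struct.unpack("<H", fh.read(2))
    return fh.read(n).decode("ascii")


def _w_vertex(fh: BinaryIO, v: Vertex) -> None:
    fh.write(struct.pack("<H", len(v.compressed)))
    for cc in v.compressed:
        _w_cc(fh, cc)
    if v.uncompressed is None:
        fh.write(b"\x00")
    else:
        fh.write(b"\x01")
        uc = v.uncompressed
        fh.write(struct.pack("<I", len(uc)))
        for s, ref in uc.tuples():
            _w_str(fh, s)
            _w_colorref(fh, ref)


def _r_vertex(fh: BinaryIO, t: BFT) -> Vertex:
    v = Vertex()
    (ncc,) = struct.unpack("<H", fh.read(2))
    for _ in range(ncc):
        v.compressed.append(_r_cc(fh, t))
    if fh.read(1) == b"\x01":
        (n,) = struct.unpack("<I", fh.read(4))
        uc = UncompressedContainer(t.c)
        for _ in range(n):
            s = _r_str(fh)
            uc.suffixes.append(s)
            uc.colors.append(_r_colorref(fh))
        v.uncompressed = uc
    return v


def _w_cc(fh: BinaryIO, cc: CompressedContainer) -> None:
    fh.write(struct.pack("<BBB", cc.la, cc.lb, 1 if cc.terminal else 0))
    _w_bits(fh, cc.quer.bits, cc.quer.m)
    _w_bits(fh, cc.pref, cc.pref_size)
    fh.write(struct.pack("<I", cc.q))
    for b in cc.suf:
        _w_str(fh, b)
    clust_bits = 0
    for j, bit in enumerate(cc.clust):
        clust_bits |= bit << j
    _w_bits(fh, clust_bits, cc.q)
    for child in cc.children:
        if cc.terminal:
            _w_colorref(fh, child)
        else:
            _w_vertex(fh, child)


def _r_cc(fh: BinaryIO, t: BFT) -> CompressedContainer:
    la, lb, term = struct.unpack("<BBB", fh.read(3))
    quer = BloomFilter(t.bf_bits, t.bf_hashes, t.seed, restricted=t.graph_mode)
    quer.bits = _r_bits(fh, quer.m)
    cc = CompressedContainer(la, lb, quer, terminal=bool(term))
    cc.pref = _r_bits(fh, cc.pref_size)
    (q,) = struct.unpack("<I", fh.read(4))
    cc.suf = [_r_str(fh) for _ in range(q)]
    clust_bits = _r_bits(fh, q)
    cc.clust = [(clust_bits >> j) & 1 for j in range(q)]
    cc.children = [
        _r_colorref(fh) if term else _r_vertex(fh, t) for _ in range(q)
    ]
    return cc


def save(t: BFT, path: str) -> None:
    """Serialize the index to ``path``."""
    with open(path, "wb") as fh:
        flags = 1 if t.graph_mode else 0
        fh.write(
            _HEADER.pack(
                MAGIC, VERSION, flags, t.k, t.l, t.c,
                t.bf_bits, t.bf_hashes, t.seed, t.n_kmers, t.resize_factor,
            )
        )
        _w_vertex(fh, t.root)
        table = t.color_table
        fh.write(struct.pack("<I", len(table) if table else 0))
        if table:
            for cs in table.external:
                _w_colorset(fh, cs)


def load(path: str) -> BFT:
    """Reconstruct an index written by :func:`save`."""
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER.size)
        magic, version, flags, k, l, c, bf_bits, bf_hashes, seed, n_kmers, rf = _HEADER.unpack(raw)
        if magic != MAGIC:
            raise ValueError(f"not an index file (bad magic {magic!r})")
        if version != VERSION:
            raise ValueError(f"unsupported index version {version}")
        t = BFT(
            k=k, l=l, c=c, graph_mode=bool(flags & 1),
            bf_bits=bf_bits, bf_hashes=bf_hashes, seed=seed, resize_factor=rf,
        )
        t.root = _r_vertex(fh, t)
        t.n_kmers = n_kmers
        (ntab,) = struct.unpack("<I", fh.read(4))
        if ntab:
            t.color_table = ColorTable([_r_colorset(fh) for _ in range(ntab)])
    return t
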