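"""2-bit DNA codec and the k-mer chunking used throughout the trie.

Every string handled by the index is over the DNA alphabet ``{a,c,g,t}``,
so a character fits in two bits.  The codec fixes the lexicographic mapping
a=0, c=1, g=2, t=3: with it the two-character prefix ``gt`` packs to the
bits ``1011`` = 11, i.e. the 1-based prefix-array slot 12 — the convention
the compressed-container layout relies on.

A k-mer of length ``k`` (``k`` a multiple of the chunk length ``l``) is
split into ``k/l`` consecutive chunks of length ``l``; each trie level
consumes one chunk.
"""

from __future__ import annotations

from typing import Iterator

_CODE = {"a": 0, "c": 1, "g": 2, "t": 3}
_BASE = "acgt"

__all__ = [
    "encode_base",
    "decode_base",
    "encode",
    "decode",
    "prefix_index",
    "chunk",
    "rotate_prefix",
    "unrotate_prefix",
    "InvalidBaseError",
]


class InvalidBaseError(ValueError):
    """A character outside {a,c,g,t} (case-insensitive) was encountered.

    ``position`` is the 0-based offset of the offending character.
    """

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(f"invalid DNA character {char!r} at position {position}")


def encode_base(ch: str) -> int:
    """Return the 2-bit code of one DNA character (a=0, c=1, g=2, t=3)."""
    try:
        return _CODE[ch.lower()]
    except KeyError:
        raise InvalidBaseError(ch, 0) from None


def decode_base(code: int) -> str:
    """Inverse of :func:`encode_base`."""
    if not 0 <= code <= 3:
        raise ValueError(f"2-bit code out of range: {code}")
    return _BASE[code]


def encode(s: str) -> int:
    """Pack a DNA string into an integer, 2 bits per character, MSB first.

    MSB-first packing makes integer order equal lexicographic order for
    equal-length strings, which the prefix bit array depends on.
    """
    v = 0
    for i, ch in enumerate(s):
        c = _CODE.get(ch.lower())
        if c is None:
            raise InvalidBaseError(ch, i)
        v = (v << 2) | c
    return v


def decode(v: int, length: int) -> str:
    """Unpack ``length`` characters from a 2-bit-packed integer."""
    out = []
    for shift in range(2 * (length - 1), -2, -2):
        out.append(_BASE[(v >> shift) & 3])
    return "".join(out)


def prefix_index(a: str) -> int:
    """1-based index of prefix ``a`` in a bit array of 2^(2|a|) slots.

    The concatenated 2-bit codes of ``a`` are read as an integer and
    shifted to 1-based: ``prefix_index("gt") == 12``, ``"aa" -> 1``,
    ``"tt" -> 4^|a|``.  Strictly increasing in lexicographic order.
    """
    if not a:
        raise ValueError("empty prefix")
    return encode(a) + 1


def chunk(x: str, l: int) -> list[str]:
    """Split a k-mer into its k/l consecutive length-``l`` chunks."""
    if len(x) % l != 0:
        raise ValueError(f"length {len(x)} is not a multiple of chunk length {l}")
    return [x[i : i + l] for i in range(0, len(x), l)]


def rotate_prefix(s_pref: str) -> str:
    """Left-rotate a suffix prefix by one character: s[2..l]s[1].

    This is the storage transform of graph mode: it moves the character
    that varies between the four de Bruijn predecessors of a k-mer out of
    the leading position, so that all four land in one cluster.
    """
    if len(s_pref) < 3:
        raise ValueError(f"suffix prefix too short to rotate: {s_pref!r}")
    return s_pref[1:] + s_pref[0]


def unrotate_prefix(s_rot: str) -> str:
    """Inverse of :func:`rotate_prefix`."""
    if len(s_rot) < 3:
        raise ValueError(f"suffix prefix too short: {s_rot!r}")
    return s_rot[-1] + s_rot[:-1]


def validate(s: str) -> str:
    """Lower-case ``s`` and reject anything outside {a,c,g,t}."""
    t = s.lower()
    for i, ch in enumerate(t):
        if ch not in _CODE:
            raise InvalidBaseError(ch, i)
    return t


def acgt_segments(s: str) -> Iterator[str]:
    """Yield the maximal runs of ACGT characters in ``s`` (lower-cased).

    Reads containing N or IUPAC ambiguity codes are split at those
    positions during k-mer extraction; ambiguous k-mers are never stored.
    """
    t = s.lower()
    start = None
    for i, ch in enumerate(t):
        if ch in _CODE:
            if start is None:
                start = i
        else:
            if start is not None:
                yield t[start:i]
                start = None
    if start is not None:
        yield t[start:]
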