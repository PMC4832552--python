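"""Color sets — per-k-mer genome membership — and their deduplication.

Each input genome gets a 1-based *color* index; the color set of a k-mer
is the bit array recording which genomes contain it.  In a pan-genome most
k-mers share one of a handful of color sets (the core genome shares them
all), so identical sets are stored once in an external table and replaced
in the trie by an index whenever the index is cheaper than the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ColorSet:
    """Growable bit array of genome-membership flags (1-based color indices)."""

    __slots__ = ("bits",)

    def __init__(self, bits: int = 0):
        self.bits = bits

    @classmethod
    def of(cls, *colors: int) -> "ColorSet":
        cs = cls()
        for i in colors:
            cs.add(i)
        return cs

    def add(self, i_color: int) -> None:
        """Record color ``i_color``; idempotent, other bits untouched."""
        if i_color < 1:
            raise ValueError(f"color index must be >= 1, got {i_color}")
        self.bits |= 1 << (i_color - 1)

    def __contains__(self, i_color: int) -> bool:
        return i_color >= 1 and (self.bits >> (i_color - 1)) & 1 == 1

    def indices(self) -> list[int]:
        """Sorted 1-based color indices present in the set."""
        out, b, i = [], self.bits, 1
        while b:
            if b & 1:
                out.append(i)
            b >>= 1
            i += 1
        return out

    @property
    def width(self) -> int:
        """Highest color index present (trailing zeros trimmed)."""
        return self.bits.bit_length()

    def size_bits(self) -> int:
        """Storage cost in bits, byte-rounded (minimum one byte)."""
        return 8 * max(1, math.ceil(self.width / 8))

    def copy(self) -> "ColorSet":
        return ColorSet(self.bits)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ColorSet) and self.bits == other.bits

    def __hash__(self) -> int:
        return hash(self.bits)

    def __len__(self) -> int:
        return self.bits.bit_count()

    def __repr__(self) -> str:
        return f"ColorSet({self.indices()})"


class ExternalRef:
    """Reference to a deduplicated color set by its ColorTable position."""

    __slots__ = ("index",)

    def __init__(self, index: int):
        self.index = index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExternalRef) and self.index == other.index

    def __repr__(self) -> str:
        return f"ExternalRef({self.index})"


#: A color annotation slot holds either an inline ColorSet or an ExternalRef.
ColorRef = "ColorSet | ExternalRef"


def index_cost_bits(table_size: int) -> int:
    """Bits charged for an index into a table of ``table_size`` entries.

    ceil(log2) of the addressable range, rounded up to a whole byte.
    """
    return 8 * max(1, math.ceil(math.ceil(math.log2(table_size + 1)) / 8)) if table_size else 8


@dataclass
class ColorTable:
    """External array of deduplicated color sets."""

    external: list[ColorSet] = field(default_factory=list)

    def deref(self, ref) -> ColorSet:
        """Resolve a ColorRef to its ColorSet (inline refs pass through)."""
        if isinstance(ref, ExternalRef):
            return self.external[ref.index]
        return ref

    def __len__(self) -> int:
        return len(self.external)


def resolve(ref, table: "ColorTable | None") -> ColorSet:
    """Dereference ``ref`` with or without a table (inline-only tries)."""
    if isinstance(ref, ExternalRef):
        if table is None:
            raise ValueError("external color reference but no color table")
        return table.external[ref.index]
    return ref


def compress_colors(t) -> ColorTable:
    """Deduplicate color sets shared by many k-mers into an external table.

    Census pass: collect the distinct color sets in the trie with the
    number of k-mers carrying each.  Candidates are visited in decreasing
    order of total size (count x set size, ties broken by smaller bit
    array) and appended to the table whenever the byte-rounded index that
    would replace them is strictly smaller than the set itself.  Rewrite
    pass: every inline occurrence of a tabled set becomes an ExternalRef.

    Lossless by construction; the per-k-mer color storage in the trie
    never increases.  Re-runnable after further insertions (existing
    external refs are resolved against the old table first).
    """
    old_table = t.color_table
    census: dict[int, int] = {}
    for slots, i in t.iter_color_slots():
        cs = resolve(slots[i], old_table)
        census[cs.bits] = census.get(cs.bits, 0) + 1

    order = sorted(
        census.items(),
        key=lambda kv: (-(kv[1] * ColorSet(kv[0]).size_bits()), kv[0]),
    )
    table = ColorTable()
    mapping: dict[int, int] = {}
    for bits, _count in order:
        cs = ColorSet(bits)
        if index_cost_bits(len(table) + 1) < cs.size_bits():
            mapping[bits] = len(table.external)
            table.external.append(cs)

    for slots, i in t.iter_color_slots():
        cs = resolve(slots[i], old_table)
        idx = mapping.get(cs.bits)
        slots[i] = ExternalRef(idx) if idx is not None else cs

    t.color_table = table
    return table


def color_footprint_bits(t) -> tuple[int, int]:
    """(in-trie color bits, external table bits) for the current trie state."""
    inline = 0
    table = t.color_table
    n = len(table) if table else 0
    for slots, i in t.iter_color_slots():
        ref = slots[i]
        if isinstance(ref, ExternalRef):
            inline += index_cost_bits(n)
        else:
            inline += ref.size_bits()
    table_bits = sum(cs.size_bits() for cs in table.external) if table else 0
    return inline, table_bits
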