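"""Colored de Bruijn graph semantics on top of the trie.

Edges are never stored: k-mer x has an edge to x' exactly when
x[2..k] = x'[1..k-1], so successors and predecessors are recomputed from
the index on demand.  The naive route is four independent look-ups per
direction; the trie's graph mode does better:

* the four successors x[2..k]c share every chunk but the last, hence one
  root-to-leaf path — at most 1 + height_max vertices;
* the four predecessors c x[1..k-1] diverge only in their first chunk.
  Rotation stores that chunk as x[1..l-1]c, so all four sit consecutively
  in one cluster of one root container (the restricted hashes ignore the
  varying character), and only the surviving candidates walk on — at
  most 1 + 4 * height_max vertices.

Every result is verified exactly; the Bloom filters only steer the walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

from . import dna
from .trie import BFT, Vertex

ALPHABET = "acgt"

__all__ = ["Neighborhood", "successors", "predecessors", "neighborhood", "is_branching"]


@dataclass
class Neighborhood:
    """Immediate graph neighborhood of a k-mer, with traversal instrumentation."""

    kmer: str
    successors: list[tuple[str, Any]] = field(default_factory=list)
    predecessors: list[tuple[str, Any]] = field(default_factory=list)
    visited_successors: int = 0
    visited_predecessors: int = 0


def _require_graph_mode(t: BFT) -> None:
    if not t.graph_mode:
        raise ValueError("graph traversal requires a trie built in graph mode")


def successors(t: BFT, x: str) -> tuple[list[tuple[str, Any]], int]:
    """Present successors of ``x`` with their color refs, and vertices visited.

    Walks the single path shared by all four candidates; at the terminal
    vertex the candidates differ only in their last character, which the
    rotated layout keeps inside one container.
    """
    _require_graph_mode(t)
    x = t._check(x)
    base = x[1:]
    out: list[tuple[str, Any]] = []
    v: Optional[Vertex] = t.root
    depth = 0
    visited = 1
    while True:
        rem = t.k - depth * t.l
        if rem > t.l:
            chunk = base[depth * t.l : depth * t.l + t.l]  # common to all candidates
            cc = t.first_firing(v, chunk)
            if cc is not None:
                res = cc.contains(t._storage_form(chunk))
                if not res.found:
                    return out, visited
                v = cc.children[res.pos - 1]
                depth += 1
                visited += 1
                continue
            uc = v.uncompressed
            if uc is not None:
                for c2 in ALPHABET:
                    s = base[depth * t.l :] + c2
                    found, pos = uc.search(s)
                    if found:
                        out.append((base + c2, uc.colors[pos - 1]))
            return out, visited
        # terminal level: candidates are chunks differing in the last character
        head = base[depth * t.l :]  # length l-1
        cc = t.first_firing(v, head + ALPHABET[0])  # hash ignores the last char
        if cc is not None:
            for c2 in ALPHABET:
                res = cc.contains(t._storage_form(head + c2))
                if res.found:
                    out.append((base + c2, cc.children[res.pos - 1]))
        elif v.uncompressed is not None:
            for c2 in ALPHABET:
                found, pos = v.uncompressed.search(head + c2)
                if found:
                    out.append((base + c2, v.uncompressed.colors[pos - 1]))
        return out, visited


def predecessors(t: BFT, x: str) -> tuple[list[tuple[str, Any]], int]:
    """Present predecessors of ``x`` with their color refs, and vertices visited.

    The four candidates share one root container and cluster thanks to
    prefix rotation; below the root each surviving candidate walks its
    own (fully determined) path.
    """
    _require_graph_mode(t)
    x = t._check(x)
    base = x[: t.k - 1]
    out: list[tuple[str, Any]] = []
    visited = 1
    if t.k == t.l:
        # single-level trie: the candidates are whole stored prefixes
        cc = t.first_firing(t.root, ALPHABET[0] + base)
        if cc is not None:
            for c1 in ALPHABET:
                res = cc.contains(t._storage_form(c1 + base))
                if res.found:
                    out.append((c1 + base, cc.children[res.pos - 1]))
        elif t.root.uncompressed is not None:
            for c1 in ALPHABET:
                found, pos = t.root.uncompressed.search(c1 + base)
                if found:
                    out.append((c1 + base, t.root.uncompressed.colors[pos - 1]))
        return out, visited
    # candidate z = c1 + base has first chunk c1 + base[1..l-1]
    tail = base[: t.l - 1]
    rest = base[t.l - 1 :]  # common remaining suffix below the root
    cc = t.first_firing(t.root, ALPHABET[0] + tail)  # hash ignores the first char
    if cc is not None:
        for c1 in ALPHABET:
            res = cc.contains(t._storage_form(c1 + tail))
            if not res.found:
                continue
            child = cc.children[res.pos - 1]
            if cc.terminal:
                out.append((c1 + base, child))
                continue
            ref, sub_visited = t._descend(child, rest)
            visited += sub_visited
            if ref is not None:
                out.append((c1 + base, ref))
    elif t.root.uncompressed is not None:
        for c1 in ALPHABET:
            found, pos = t.root.uncompressed.search(c1 + base)
            if found:
                out.append((c1 + base, t.root.uncompressed.colors[pos - 1]))
    return out, visited


def neighborhood(t: BFT, x: str) -> Neighborhood:
    """Full successor/predecessor neighborhood of ``x``."""
    succ, vs = successors(t, x)
    pred, vp = predecessors(t, x)
    return Neighborhood(dna.validate(x), succ, pred, vs, vp)


def is_branching(t: BFT, x: str, mode: str = "either") -> bool:
    """Whether the graph vertex of present k-mer ``x`` branches.

    ``mode``: "out" (>1 successor), "in" (>1 predecessor), or "either".
    Raises for an absent k-mer.
    """
    if t.contains(x) is None:
        raise KeyError(f"k-mer not in trie: {x}")
    if mode not in ("out", "in", "either"):
        raise ValueError(f"unknown branching mode {mode!r}")
    if mode in ("out", "either"):
        if len(successors(t, x)[0]) > 1:
            return True
    if mode in ("in", "either"):
        if len(predecessors(t, x)[0]) > 1:
            return True
    return False
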