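"""Pseudoknotted RNA secondary structures and their crossing topology.

A structure is a set of base pairs ``(i, j)`` (1-based, ``i < j``) over a
sequence; pairs may cross.  The admissible class is that of *1-structures*:
structures in which every connected component of the helix conflict graph,
viewed as a chord diagram, has topological genus exactly 1.  This covers the
four elementary pseudoknot motifs — H-type, kissing hairpin (K-type), and the
rarer L- and M-types — and, of course, all crossing-free structures (genus 0).

The genus of a chord diagram with a single backbone is computed by boundary
tracing of the fattened diagram::

    g = (c - b + 1) / 2

where ``c`` is the number of chords and ``b`` the number of boundary
components of the thickened surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Sequence as TSequence

__all__ = [
    "Sequence",
    "Structure",
    "Helix",
    "PKClass",
    "MIN_HAIRPIN",
    "CANONICAL_PAIRS",
    "BRACKET_PAGES",
    "parse_structure",
    "write_structure",
    "decompose_helices",
    "conflict_graph",
    "conflict_components",
    "genus",
    "is_one_structure",
    "classify_pk",
    "classify_components",
    "pairs_cross",
]

#: canonical Watson-Crick plus wobble pairs
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: minimum number of unpaired nucleotides enclosed by a hairpin-closing pair
MIN_HAIRPIN = 3

#: bracket pages for extended dot-bracket notation, in assignment order
BRACKET_PAGES = ["()", "[]", "{}", "<>"]

_OPENERS = {page[0]: k for k, page in enumerate(BRACKET_PAGES)}
_CLOSERS = {page[1]: k for k, page in enumerate(BRACKET_PAGES)}

#: canonical shadow words of the four genus-1 pseudoknot component types
SHADOW_WORDS = {
    "ABAB": "H",
    "ABACBC": "K",
    "ABCABC": "L",
    "ABCADBCD": "M",
}


@dataclass(frozen=True)
class Sequence:
    """An RNA sequence over the alphabet {A, C, G, U}; positions are 1-based."""

    residues: str
    id: str = "seq"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - set("ACGU")
        if bad:
            raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} out of range 1..{len(self.residues)}")
        return self.residues[i - 1]

    def can_pair(self, i: int, j: int) -> bool:
        return (self[i], self[j]) in CANONICAL_PAIRS


def _normalize_pairs(pairs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    out = sorted((min(i, j), max(i, j)) for i, j in pairs)
    return tuple(out)


@dataclass(frozen=True)
class Structure:
    """A set of base pairs, possibly crossing, stored sorted by the 5' index.

    The constructor enforces the purely combinatorial invariants (each index
    paired at most once, hairpin constraint).  Chemistry (canonical pairs) is
    checked when the structure is bound to a sequence, and membership in the
    1-structure class is a separate predicate (:func:`is_one_structure`) so
    that invalid candidates can be examined.
    """

    pairs: tuple[tuple[int, int], ...]

    def __init__(self, pairs: Iterable[tuple[int, int]] = ()):  # noqa: D107
        object.__setattr__(self, "pairs", _normalize_pairs(pairs))
        seen: set[int] = set()
        for i, j in self.pairs:
            if i < 1:
                raise ValueError(f"position {i} is not 1-based")
            if j - i < MIN_HAIRPIN + 1:
                raise ValueError(f"pair ({i},{j}) violates the hairpin constraint")
            if i in seen or j in seen:
                raise ValueError(f"position paired twice in {self.pairs}")
            seen.update((i, j))

    @property
    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.pairs)

    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.update((i, j))
        return out

    def add(self, i: int, j: int) -> "Structure":
        return Structure(self.pairs + ((min(i, j), max(i, j)),))

    def remove(self, i: int, j: int) -> "Structure":
        p = (min(i, j), max(i, j))
        if p not in self.pair_set:
            raise ValueError(f"pair {p} not in structure")
        return Structure(tuple(q for q in self.pairs if q != p))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.pairs)

    def __lt__(self, other: "Structure") -> bool:
        return self.pairs < other.pairs

    def check_canonical(self, seq: Sequence) -> None:
        n = len(seq)
        for i, j in self.pairs:
            if j > n:
                raise ValueError(f"pair ({i},{j}) outside sequence of length {n}")
            if not seq.can_pair(i, j):
                raise ValueError(
                    f"noncanonical pair {seq[i]}{i}-{seq[j]}{j}"
                )


@dataclass(frozen=True)
class Helix:
    """A maximal stack of consecutively nested pairs (i+k, j-k), k = 0..len-1.

    Named after its outermost pair, h_i^j, following the helix representation
    used for metastable structures (e.g. h5^21 for the helix whose outermost
    pair is (5, 21)).
    """

    outer: tuple[int, int]
    length: int

    @property
    def inner(self) -> tuple[int, int]:
        i, j = self.outer
        return (i + self.length - 1, j - self.length + 1)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        i, j = self.outer
        return tuple((i + k, j - k) for k in range(self.length))

    def __lt__(self, other: "Helix") -> bool:
        return (self.outer, self.length) < (other.outer, other.length)

    def embraces(self, other: "Helix") -> bool:
        """True if this helix's outermost pair strictly encloses ``other``."""
        i, j = self.outer
        a, b = other.outer
        return i < a and b < j


PKClass = str  # "N" or a sorted composite over {"H", "K", "L", "M"}, e.g. "HK"


def pairs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """Two pairs cross (interleave) iff i < i' < j < j'."""
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


def parse_structure(text: str, n: int | None = None) -> Structure:
    """Parse extended dot-bracket notation (pages ``()``, ``[]``, ``{}``, ``<>``).

    ``n`` may be given to cross-check the expected length.
    """
    if n is not None and len(text) != n:
        raise ValueError(f"structure length {len(text)} != sequence length {n}")
    stacks: list[list[int]] = [[] for _ in BRACKET_PAGES]
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in _OPENERS:
            stacks[_OPENERS[ch]].append(pos)
        elif ch in _CLOSERS:
            page = _CLOSERS[ch]
            if not stacks[page]:
                raise ValueError(f"unbalanced '{ch}' at position {pos}")
            pairs.append((stacks[page].pop(), pos))
        else:
            raise ValueError(f"unexpected character {ch!r} at position {pos}")
    for page, stack in enumerate(stacks):
        if stack:
            raise ValueError(
                f"unbalanced '{BRACKET_PAGES[page][0]}' opened at {stack[-1]}"
            )
    return Structure(pairs)


def write_structure(s: Structure, n: int) -> str:
    """Render a structure as extended dot-bracket text.

    Bracket pages are assigned by greedy coloring of the helix crossing graph
    in order of the helices' outer pairs, which uses the minimal number of
    pages for every 1-structure (at most 3).  More than 4 mutually conflicting
    page demands signal a non-1-structure input.
    """
    helices = decompose_helices(s)
    colors: dict[Helix, int] = {}
    for h in helices:
        used = {
            colors[g]
            for g in helices
            if g in colors and pairs_cross(h.outer, g.outer)
        }
        page = 0
        while page in used:
            page += 1
        if page >= len(BRACKET_PAGES):
            raise ValueError("structure needs more bracket pages than supported")
        colors[h] = page
    out = ["."] * n
    for h in helices:
        op, cl = BRACKET_PAGES[colors[h]]
        for i, j in h.pairs:
            if j > n:
                raise ValueError(f"pair ({i},{j}) outside length {n}")
            out[i - 1] = op
            out[j - 1] = cl
    return "".join(out)


def decompose_helices(s: Structure) -> list[Helix]:
    """Split a structure into maximal stacks of consecutively nested pairs."""
    pair_set = s.pair_set
    helices: list[Helix] = []
    for i, j in s.pairs:
        if (i - 1, j + 1) in pair_set:
            continue  # not the outermost pair of its stack
        length = 1
        while (i + length, j - length) in pair_set and (j - length) - (
            i + length
        ) >= MIN_HAIRPIN + 1:
            length += 1
        helices.append(Helix((i, j), length))
    helices.sort()
    return helices


def conflict_graph(s: Structure):
    """Helices as vertices, crossings (on outer pairs) as edges.

    Returns a :class:`networkx.Graph`; isolated helices are isolated vertices.
    """
    import networkx as nx

    helices = decompose_helices(s)
    g = nx.Graph()
    g.add_nodes_from(helices)
    for a in range(len(helices)):
        for b in range(a + 1, len(helices)):
            if pairs_cross(helices[a].outer, helices[b].outer):
                g.add_edge(helices[a], helices[b])
    return g


def conflict_components(s: Structure) -> list[list[Helix]]:
    """Connected components of the conflict graph, sorted, without networkx.

    Kept dependency-free because this sits on the hot path of landscape moves.
    """
    helices = decompose_helices(s)
    m = len(helices)
    adj: list[list[int]] = [[] for _ in range(m)]
    for a in range(m):
        for b in range(a + 1, m):
            if pairs_cross(helices[a].outer, helices[b].outer):
                adj[a].append(b)
                adj[b].append(a)
    seen = [False] * m
    comps: list[list[Helix]] = []
    for start in range(m):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(helices[v] for v in comp))
    comps.sort(key=lambda c: c[0].outer)
    return comps


def _chords_of(obj) -> tuple[tuple[int, int], ...]:
    chords = obj.pairs if isinstance(obj, Structure) else _normalize_pairs(obj)
    # compactify to endpoint ranks: genus depends only on the endpoint order,
    # and ranked keys make the genus cache effective across structures
    endpoints = sorted(p for ch in chords for p in ch)
    rank = {p: r for r, p in enumerate(endpoints, start=1)}
    return tuple(sorted((rank[i], rank[j]) for i, j in chords))


@lru_cache(maxsize=200_000)
def _genus_cached(chords: tuple[tuple[int, int], ...]) -> int:
    c = len(chords)
    if c == 0:
        return 0
    # Rank endpoints along the backbone: only their order matters.
    endpoints = sorted(p for ch in chords for p in ch)
    rank = {p: r for r, p in enumerate(endpoints, start=1)}
    partner: dict[int, int] = {}
    for i, j in chords:
        partner[rank[i]] = rank[j]
        partner[rank[j]] = rank[i]
    m = 2 * c
    # Boundary tracing of the fattened one-backbone diagram.  Each endpoint k
    # has a left flank (k, 'a') and a right flank (k, 'b').  Boundary arcs:
    #   - exposed backbone segment between consecutive endpoints: (k,'b')-(k+1,'a')
    #   - around both ends of the backbone (under the bottom): (m,'b')-(1,'a')
    #   - the two sides of each fattened chord i<j: (i,'a')-(j,'b'), (i,'b')-(j,'a')
    # Every flank point has degree 2; the number of boundary components is the
    # number of cycles of this arc system.
    backbone_next: dict[tuple[int, str], tuple[int, str]] = {}
    for k in range(1, m):
        backbone_next[(k, "b")] = (k + 1, "a")
        backbone_next[(k + 1, "a")] = (k, "b")
    backbone_next[(m, "b")] = (1, "a")
    backbone_next[(1, "a")] = (m, "b")
    chord_next: dict[tuple[int, str], tuple[int, str]] = {}
    for i in range(1, m + 1):
        j = partner[i]
        if i < j:
            chord_next[(i, "a")] = (j, "b")
            chord_next[(j, "b")] = (i, "a")
            chord_next[(i, "b")] = (j, "a")
            chord_next[(j, "a")] = (i, "b")
    # Each flank point has exactly one backbone arc and one chord arc; a
    # boundary component alternates the two, so walk alternating maps and
    # count the cycles of the resulting 2-regular graph.
    visited: set[tuple[int, str]] = set()
    b = 0
    for start in backbone_next:
        if start in visited:
            continue
        b += 1
        node = start
        use_chord = False
        while True:
            visited.add(node)
            node = chord_next[node] if use_chord else backbone_next[node]
            use_chord = not use_chord
            if node == start:
                break
    return (c - b + 1) // 2


def genus(obj) -> int:
    """Topological genus of a chord diagram (a Structure or iterable of pairs).

    Computed as ``g = (c - b + 1) / 2`` with ``b`` boundary components found
    by tracing the fattened one-backbone diagram.  Nested or empty diagrams
    have genus 0; each elementary pseudoknot motif has genus 1.
    """
    return _genus_cached(_chords_of(obj))


def is_one_structure(s: Structure) -> bool:
    """True iff every crossing component, reduced to one chord per helix,
    has genus exactly 1 (crossing-free structures are trivially admissible)."""
    for comp in conflict_components(s):
        if len(comp) < 2:
            continue
        if genus(tuple(h.outer for h in comp)) != 1:
            return False
    return True


def _compactify(chords: TSequence[tuple[int, int]]) -> list[tuple[int, int]]:
    endpoints = sorted(p for ch in chords for p in ch)
    rank = {p: r for r, p in enumerate(endpoints, start=1)}
    return sorted((rank[i], rank[j]) for i, j in chords)


def _collapse_stacks(chords: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse adjacent-nested chord pairs (a,b),(a+1,b-1) until none remain.

    On compactified diagrams such a pair has identical crossing sets, so the
    reduction preserves both the crossing pattern and the genus.
    """
    chords = _compactify(chords)
    changed = True
    while changed:
        changed = False
        chord_set = set(chords)
        for a, b in chords:
            if (a + 1, b - 1) in chord_set:
                chords = _compactify([c for c in chords if c != (a + 1, b - 1)])
                changed = True
                break
    return chords


def _shadow_word(chords: list[tuple[int, int]]) -> str:
    """Word of first-occurrence chord labels along the backbone, e.g. 'ABAB'."""
    chords = _compactify(chords)
    label: dict[tuple[int, int], str] = {}
    letters = "ABCDEFGH"
    opening = {i: ch for ch in chords for i in [ch[0]]}
    word = []
    pos_to_chord: dict[int, tuple[int, int]] = {}
    for ch in chords:
        pos_to_chord[ch[0]] = ch
        pos_to_chord[ch[1]] = ch
    for pos in sorted(pos_to_chord):
        ch = pos_to_chord[pos]
        if ch not in label:
            label[ch] = letters[len(label)]
        word.append(label[ch])
    del opening
    return "".join(word)


def classify_components(s: Structure) -> list[PKClass]:
    """Pseudoknot type (H/K/L/M) of each crossing component of size > 1.

    Each component is reduced to its shadow — one chord per helix, stacks
    collapsed — and matched against the four canonical genus-1 words.
    """
    types: list[PKClass] = []
    for comp in conflict_components(s):
        if len(comp) < 2:
            continue
        shadow = _collapse_stacks([h.outer for h in comp])
        word = _shadow_word(shadow)
        if word not in SHADOW_WORDS:
            raise ValueError(
                f"crossing component with shadow {word!r} is not genus 1"
            )
        types.append(SHADOW_WORDS[word])
    return types


def classify_pk(s: Structure) -> PKClass:
    """Composite pseudoknot class of a structure: 'N' if crossing-free,
    otherwise the sorted concatenation of its component types (e.g. 'HK')."""
    types = classify_components(s)
    if not types:
        return "N"
    return "".join(sorted(set(types)))
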