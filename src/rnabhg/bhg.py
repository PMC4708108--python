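"""Basin hopping graphs: direct-path saddle estimation and exact flooding.

The basin hopping graph (BHG) has local minima as nodes; an edge carries the
saddle height S(x, y) of an energetically favorable direct transition between
the two basins.  Saddles between non-adjacent minima are minimax path values
over the graph.  Two variants are supported: the full graph over 1-structures
(``psi``) and the crossing-free pruning (``0``) in which pseudoknotted minima
are removed and every adjacency is re-estimated with the move universe
restricted to non-crossing additions.

Saddle estimation follows the findpath strategy: a breadth-limited best-first
search over moves that strictly decrease the base-pair distance to the
target, keeping the ``width`` lowest-peak partial paths per distance level,
followed by iterative refinement that gradient-walks every path structure and
splits the problem at newly discovered intermediate minima.

For small sequences :func:`flood_exact` computes the exact minima and
pairwise saddle heights by processing the enumerated ensemble in order of
increasing energy with union-find basin merging; it serves as the validation
oracle for the heuristic and also yields the barrier tree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .energy import EnergyParams, energy
from .landscape import (
    EnsembleIndex,
    LocalMinimum,
    can_add_pair,
    enumerate_ensemble,
    gradient_walk,
)
from .structures import Sequence, Structure, classify_pk

__all__ = [
    "DirectPath",
    "SaddleEstimate",
    "BasinHoppingGraph",
    "FloodResult",
    "findpath_pk",
    "estimate_saddle",
    "build_bhg",
    "prune_to_bhg0",
    "flood_exact",
    "compare_saddles",
    "bp_distance",
]

EPS = 1e-9


def bp_distance(x: Structure, y: Structure) -> int:
    """Number of pairs present in exactly one of the two structures."""
    return len(x.pair_set ^ y.pair_set)


@dataclass(frozen=True)
class DirectPath:
    """A move path x -> ... -> y; ``direct`` means the energy profile is
    non-decreasing up to the peak and non-increasing after it."""

    structures: tuple[Structure, ...]
    energies: tuple[float, ...]

    @property
    def peak(self) -> float:
        return max(self.energies)

    @property
    def peak_structure(self) -> Structure:
        return self.structures[int(np.argmax(self.energies))]

    @property
    def direct(self) -> bool:
        k = int(np.argmax(self.energies))
        up = all(
            self.energies[i] <= self.energies[i + 1] + EPS for i in range(k)
        )
        down = all(
            self.energies[i] >= self.energies[i + 1] - EPS
            for i in range(k, len(self.energies) - 1)
        )
        return up and down

    def reversed(self) -> "DirectPath":
        return DirectPath(self.structures[::-1], self.energies[::-1])

    def __len__(self) -> int:
        return len(self.structures)


@dataclass(frozen=True)
class SaddleEstimate:
    height: float
    witness: DirectPath
    status: str  # "heuristic" | "exact"
    new_lms: frozenset = frozenset()


def _beam_search(
    x: Structure,
    y: Structure,
    seq: Sequence,
    p: EnergyParams,
    width: int,
    allow_pk: bool,
    enforce_direct: bool,
) -> DirectPath | None:
    removes = tuple(sorted(x.pair_set - y.pair_set))
    adds = tuple(sorted(y.pair_set - x.pair_set))
    d = len(removes) + len(adds)
    e0 = energy(seq, x, p)
    # state: (peak, cur_e, descending, structure, path)
    beam = [(e0, e0, False, x, (x,))]
    for _ in range(d):
        nxt: dict[tuple, tuple] = {}
        for peak, cur_e, desc, s, path in beam:
            pair_set = s.pair_set
            moves = []
            for q in removes:
                if q in pair_set:
                    moves.append(("remove", q))
            occupied = s.paired_positions()
            for q in adds:
                if q in pair_set:
                    continue
                if q[0] in occupied or q[1] in occupied:
                    continue
                if can_add_pair(s, q[0], q[1], seq, allow_pk=allow_pk):
                    moves.append(("add", q))
            for kind, q in moves:
                t = s.add(*q) if kind == "add" else s.remove(*q)
                e = energy(seq, t, p)
                if enforce_direct and desc and e > cur_e + EPS:
                    continue
                new_desc = desc or (e < cur_e - EPS)
                cand = (max(peak, e), e, new_desc, t, path + (t,))
                key = (t.pairs, new_desc)
                old = nxt.get(key)
                if old is None or (cand[0], cand[4]) < (old[0], old[4]):
                    nxt[key] = cand
        if not nxt:
            return None
        beam = sorted(nxt.values(), key=lambda c: (c[0], c[1], c[4]))[:width]
    beam = [c for c in beam if c[3].pair_set == y.pair_set]
    if not beam:
        return None
    best = min(beam, key=lambda c: (c[0], c[4]))
    path = best[4]
    return DirectPath(path, tuple(energy(seq, s, p) for s in path))


def findpath_pk(
    x: Structure,
    y: Structure,
    seq: Sequence,
    p: EnergyParams,
    width: int = 16,
    allow_pk: bool = True,
) -> DirectPath:
    """Near-optimal direct refolding path between two 1-structures.

    Only moves that decrease the base-pair distance to ``y`` are considered,
    so every returned path has exactly d(x, y) moves.  The search is run at
    doubling beam widths up to ``width`` and the lowest-peak result is kept,
    which makes the returned peak non-increasing in ``width``.  Paths with a
    monotone up-then-down profile are preferred; if none survives the beam,
    the unconstrained best path is returned.
    """
    if x.pair_set == y.pair_set:
        e = energy(seq, x, p)
        return DirectPath((x,), (e,))
    widths = []
    w = 1
    while w < width:
        widths.append(w)
        w *= 2
    widths.append(width)
    best: DirectPath | None = None
    for w in widths:
        cand = _beam_search(x, y, seq, p, w, allow_pk, enforce_direct=False)
        if cand is not None and (
            best is None
            or (cand.peak, cand.structures) < (best.peak, best.structures)
        ):
            best = cand
    if best is None:  # unreachable: removals are always valid moves
        raise RuntimeError("no path found")
    if not best.direct:
        # among equal-peak paths prefer one with a monotone up-down profile
        for w in widths:
            cand = _beam_search(x, y, seq, p, w, allow_pk, enforce_direct=True)
            if cand is not None and cand.peak <= best.peak + EPS:
                best = cand
                break
    return best


def _concat(a: DirectPath, b: DirectPath) -> DirectPath:
    assert a.structures[-1].pair_set == b.structures[0].pair_set
    return DirectPath(
        a.structures + b.structures[1:], a.energies + b.energies[1:]
    )


def estimate_saddle(
    x: Structure,
    y: Structure,
    seq: Sequence,
    p: EnergyParams,
    width: int = 16,
    rounds: int = 3,
    allow_pk: bool = True,
    _memo: dict | None = None,
    _walk_cache: dict | None = None,
) -> SaddleEstimate:
    """Iteratively refined saddle estimate between two local minima.

    Every structure on the findpath result is gradient-walked; a newly found
    minimum z splits the problem into (x, z) and (z, y), recursively up to
    ``rounds`` levels, and is admitted whenever it strictly lowers the
    composite saddle.  The estimate is symmetric in its arguments and
    non-increasing in ``rounds``.
    """
    memo = {} if _memo is None else _memo
    walks = {} if _walk_cache is None else _walk_cache

    def key_of(a: Structure, b: Structure, depth: int):
        ka, kb = sorted((a.pairs, b.pairs))
        return (ka, kb, depth)

    def walk(s: Structure) -> Structure:
        return gradient_walk(s, seq, p, allow_pk=allow_pk, _cache=walks)

    def rec(a: Structure, b: Structure, depth: int) -> SaddleEstimate:
        if a.pair_set == b.pair_set:
            e = energy(seq, a, p)
            return SaddleEstimate(e, DirectPath((a,), (e,)), "heuristic")
        if (a.pairs, b.pairs) > (b.pairs, a.pairs):
            est = rec(b, a, depth)
            return SaddleEstimate(
                est.height, est.witness.reversed(), est.status, est.new_lms
            )
        k = key_of(a, b, depth)
        if k in memo:
            return memo[k]
        path = findpath_pk(a, b, seq, p, width=width, allow_pk=allow_pk)
        height = path.peak
        witness = path
        new_lms: set[Structure] = set()
        if depth > 0:
            seen: set = set()
            zs = []
            for s in path.structures:
                z = walk(s)
                if z.pairs in seen:
                    continue
                seen.add(z.pairs)
                if z.pair_set != a.pair_set and z.pair_set != b.pair_set:
                    zs.append(z)
            zs.sort(key=lambda z: (energy(seq, z, p), z.pairs))
            for z in zs:
                if energy(seq, z, p) >= height - EPS:
                    continue
                left = rec(a, z, depth - 1)
                right = rec(z, b, depth - 1)
                comp = max(left.height, right.height)
                if comp < height - EPS:
                    height = comp
                    witness = _concat(left.witness, right.witness)
                    new_lms |= {z} | set(left.new_lms) | set(right.new_lms)
        est = SaddleEstimate(height, witness, "heuristic", frozenset(new_lms))
        memo[k] = est
        return est

    return rec(x, y, rounds)


@dataclass
class BasinHoppingGraph:
    """Local minima as nodes; edges weighted by direct saddle heights.

    ``graph`` is a networkx Graph on integer node ids; node attribute ``lm``
    holds the :class:`LocalMinimum`, edge attributes ``saddle`` (kcal/mol)
    and ``witness`` (the DirectPath realizing it).
    """

    graph: nx.Graph
    lms: list[LocalMinimum]
    variant: str  # "psi" | "0"
    seq: Sequence
    params: EnergyParams
    _closure: np.ndarray | None = field(default=None, repr=False)

    def index_of(self, s: Structure) -> int:
        for k, lm in enumerate(self.lms):
            if lm.structure.pair_set == s.pair_set:
                return k
        raise KeyError("structure is not a node of this BHG")

    def saddle_matrix(self) -> np.ndarray:
        """Minimax saddle heights between all node pairs (inf if disconnected)."""
        if self._closure is None:
            n = len(self.lms)
            d = np.full((n, n), np.inf)
            for k, lm in enumerate(self.lms):
                d[k, k] = lm.energy
            for a, b, data in self.graph.edges(data=True):
                d[a, b] = d[b, a] = min(d[a, b], data["saddle"])
            for k in range(n):
                d = np.minimum(d, np.maximum(d[:, [k]], d[[k], :]))
            self._closure = d
        return self._closure

    def saddle(self, a: int, b: int) -> float:
        return float(self.saddle_matrix()[a, b])

    def minimax_path(self, a: int, b: int) -> list[int]:
        """Node sequence of a minimax (bottleneck-optimal) path a -> b."""
        bound = self.saddle(a, b)
        if not math.isfinite(bound):
            raise nx.NetworkXNoPath(f"nodes {a} and {b} are disconnected")
        sub = nx.Graph(
            (u, v)
            for u, v, dd in self.graph.edges(data=True)
            if dd["saddle"] <= bound + EPS
        )
        sub.add_nodes_from([a, b])
        return nx.shortest_path(sub, a, b)

    def witness_structures(self, a: int, b: int) -> list[Structure]:
        """Structures along the stored witness paths of a minimax route."""
        out: list[Structure] = []
        nodes = self.minimax_path(a, b)
        for u, v in zip(nodes, nodes[1:]):
            w: DirectPath = self.graph.edges[u, v]["witness"]
            if w.structures[0].pair_set != self.lms[u].structure.pair_set:
                w = w.reversed()
            out.extend(w.structures if not out else w.structures[1:])
        return out or [self.lms[a].structure]


def _nearest_pairs(lms: list[LocalMinimum]) -> set[tuple[int, int]]:
    out: set[tuple[int, int]] = set()
    for i, lm in enumerate(lms):
        best = None
        for j, other in enumerate(lms):
            if i == j:
                continue
            d = bp_distance(lm.structure, other.structure)
            key = (d, other.structure.pairs)
            if best is None or key < best[0]:
                best = (key, j)
        if best is not None:
            i2, j2 = sorted((i, best[1]))
            out.add((i2, j2))
    return out


def build_bhg(
    lms: list[LocalMinimum],
    seq: Sequence,
    p: EnergyParams,
    width: int = 16,
    rounds: int = 3,
    k_lowest: int = 50,
    allow_pk: bool = True,
    max_sweeps: int = 3,
) -> BasinHoppingGraph:
    """Assemble a BHG from a local-minimum set.

    Saddles are estimated for all pairs among the ``k_lowest`` lowest minima
    plus every minimum's nearest neighbor by base-pair distance; minima
    discovered during estimation are added and wired in (up to
    ``max_sweeps`` discovery sweeps).  A candidate edge (x, y) is dropped if
    a third minimum z with f(z) < S(x, y) routes the transition at no higher
    saddle — the direct transition is then not energetically favorable.
    """
    nodes: dict[tuple, LocalMinimum] = {
        lm.structure.pairs: lm for lm in lms
    }
    memo: dict = {}
    walks: dict = {}
    estimates: dict[tuple[tuple, tuple], SaddleEstimate] = {}

    def est_key(a: Structure, b: Structure):
        return tuple(sorted((a.pairs, b.pairs)))

    for _ in range(max_sweeps):
        ordered = sorted(nodes.values(), key=lambda lm: (lm.energy, lm.structure))
        low = ordered[:k_lowest]
        wanted: set[tuple[tuple, tuple]] = set()
        for a, b in itertools.combinations(low, 2):
            wanted.add(est_key(a.structure, b.structure))
        for i, j in _nearest_pairs(ordered):
            wanted.add(est_key(ordered[i].structure, ordered[j].structure))
        pending = [k for k in wanted if k not in estimates]
        discovered: set[Structure] = set()
        for ka, kb in pending:
            a, b = Structure(ka), Structure(kb)
            est = estimate_saddle(
                a, b, seq, p, width=width, rounds=rounds,
                allow_pk=allow_pk, _memo=memo, _walk_cache=walks,
            )
            estimates[(ka, kb)] = est
            discovered |= set(est.new_lms)
        new = False
        for z in discovered:
            if z.pairs not in nodes:
                nodes[z.pairs] = LocalMinimum(
                    z, energy(seq, z, p), classify_pk(z), 0
                )
                new = True
        if not new:
            break

    ordered = sorted(nodes.values(), key=lambda lm: (lm.energy, lm.structure))
    index = {lm.structure.pairs: k for k, lm in enumerate(ordered)}
    n = len(ordered)
    smat = np.full((n, n), np.inf)
    for k, lm in enumerate(ordered):
        smat[k, k] = lm.energy
    cand_edges: dict[tuple[int, int], SaddleEstimate] = {}
    for (ka, kb), est in estimates.items():
        if ka not in index or kb not in index:
            continue
        i, j = sorted((index[ka], index[kb]))
        if est.height < smat[i, j]:
            smat[i, j] = smat[j, i] = est.height
            cand_edges[(i, j)] = est
    closure = smat.copy()
    for k in range(n):
        closure = np.minimum(closure, np.maximum(closure[:, [k]], closure[[k], :]))

    g = nx.Graph()
    for k, lm in enumerate(ordered):
        g.add_node(k, lm=lm)
    energies = np.array([lm.energy for lm in ordered])
    for (i, j), est in cand_edges.items():
        s_ij = est.height
        # The edge is dropped when its own witness path rides through a third,
        # strictly lower basin that routes the transition at no higher saddle:
        # the direct transition is then not an elementary basin hop.
        interior = set()
        for s in est.witness.structures[1:-1]:
            z = gradient_walk(s, seq, p, allow_pk=allow_pk, _cache=walks)
            if z.pairs in index:
                interior.add(index[z.pairs])
        dominated = False
        for z in interior - {i, j}:
            if energies[z] < s_ij - EPS and (
                max(closure[i, z], closure[z, j]) <= s_ij + EPS
            ):
                dominated = True
                break
        if not dominated:
            g.add_edge(i, j, saddle=round(est.height, 2), witness=est.witness)
    return BasinHoppingGraph(
        g, ordered, "psi" if allow_pk else "0", seq, p
    )


def prune_to_bhg0(
    bhg_psi: BasinHoppingGraph,
    seq: Sequence,
    p: EnergyParams,
    width: int = 16,
    rounds: int = 3,
    k_lowest: int = 50,
) -> BasinHoppingGraph:
    """Remove pseudoknotted minima and re-estimate every adjacency with the
    move universe restricted to non-crossing additions."""
    pk_free = [lm for lm in bhg_psi.lms if lm.pk_class == "N"]
    return build_bhg(
        pk_free, seq, p, width=width, rounds=rounds,
        k_lowest=k_lowest, allow_pk=False,
    )


@dataclass
class FloodResult:
    """Exact minima, pairwise saddle heights and barrier tree of a landscape."""

    lms: list[LocalMinimum]
    saddles: np.ndarray  # minimal saddle height between LM pairs; diag = f(lm)
    merges: list[tuple[int, int, float]]  # (absorbed lm, surviving lm, height)
    ensemble: EnsembleIndex

    def index_of(self, s: Structure) -> int:
        for k, lm in enumerate(self.lms):
            if lm.structure.pair_set == s.pair_set:
                return k
        raise KeyError("not an exact local minimum")

    def barrier_tree_text(self) -> str:
        lines = ["# lm  merges_into  saddle_height"]
        for child, parent, h in self.merges:
            lines.append(f"{child:4d}  {parent:4d}  {h:10.2f}")
        return "\n".join(lines) + "\n"

    def to_bhg(self) -> BasinHoppingGraph:
        """Exact-saddle graph over the flooded minima.

        Edges are the barrier-tree merge events, whose minimax closure
        reproduces the exact pairwise saddle heights (flooding processes
        levels in ascending order, so the tree is ultrametric).
        """
        g = nx.Graph()
        for k, lm in enumerate(self.lms):
            g.add_node(k, lm=lm)
        for child, parent, h in self.merges:
            g.add_edge(child, parent, saddle=round(float(h), 2), witness=None)
        bhg = BasinHoppingGraph(
            g, list(self.lms), "exact", self.ensemble.seq, self.ensemble.params
        )
        bhg._closure = self.saddles.copy()
        return bhg


def flood_exact(
    seq: Sequence,
    p: EnergyParams,
    ceiling: float | None = None,
    allow_pk: bool = True,
    max_n: int = 30,
    ensemble: EnsembleIndex | None = None,
) -> FloodResult:
    """Exact landscape flooding (oracle).

    Enumerated structures are processed by increasing energy; basins are
    merged with union-find, recording the merge energy as the exact minimal
    saddle height between every pair of minima joined at that level.
    """
    if len(seq) > max_n:
        raise ValueError(f"flooding guarded to n <= {max_n}")
    ens = ensemble or enumerate_ensemble(
        seq, p, ceiling=ceiling, allow_pk=allow_pk, max_n=max_n
    )
    structures = ens.structures
    E = ens.energies
    idx = {s.pairs: k for k, s in enumerate(structures)}
    m = len(structures)

    # single-move adjacency inside the ensemble: s minus one pair
    adj: list[list[int]] = [[] for _ in range(m)]
    for k, s in enumerate(structures):
        for q in s.pairs:
            t = idx.get(s.remove(*q).pairs)
            if t is not None:
                adj[k].append(t)
                adj[t].append(k)

    parent = list(range(m))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    lms: list[LocalMinimum] = []
    basin_lms: dict[int, list[int]] = {}  # root -> lm ids in that basin
    saddle: dict[tuple[int, int], float] = {}
    merges: list[tuple[int, int, float]] = []

    for k in range(m):  # structures are sorted by (energy, lex)
        processed = [t for t in adj[k] if t < k]
        roots = sorted({find(t) for t in processed})
        groups = [basin_lms.pop(r) for r in roots]
        if not any(E[t] < E[k] - EPS for t in processed):
            s = structures[k]
            lms.append(LocalMinimum(s, float(E[k]), classify_pk(s)))
            groups.append([len(lms) - 1])
        # every pair of basins joined here meets at exactly this energy level
        for ga, gb in itertools.combinations(groups, 2):
            for a in ga:
                for b in gb:
                    saddle.setdefault((min(a, b), max(a, b)), float(E[k]))
        merged = list(itertools.chain.from_iterable(groups))
        if len(groups) > 1:
            keep = min(merged, key=lambda a: (lms[a].energy, lms[a].structure))
            for g_ in groups:
                if keep in g_:
                    continue
                child = min(g_, key=lambda a: (lms[a].energy, lms[a].structure))
                merges.append((child, keep, float(E[k])))
        for r in roots:
            parent[r] = k
        basin_lms[k] = merged

    n = len(lms)
    smat = np.full((n, n), np.inf)
    for a in range(n):
        smat[a, a] = lms[a].energy
    for (a, b), h in saddle.items():
        smat[a, b] = smat[b, a] = h
    return FloodResult(lms, smat, merges, ens)


def compare_saddles(bhg_psi: BasinHoppingGraph, bhg_0: BasinHoppingGraph):
    """Per-pair saddle comparison between the full and the pruned graph.

    For every pair of crossing-free minima present in both graphs, reports
    S0 - Spsi (kcal/mol), the relative change in percent, and the composite
    pseudoknot class of the structures on the psi witness path ('N' if the
    path is entirely crossing-free).
    """
    import pandas as pd

    common: list[tuple[int, int]] = []
    for k0, lm in enumerate(bhg_0.lms):
        try:
            kpsi = bhg_psi.index_of(lm.structure)
        except KeyError:
            continue
        common.append((kpsi, k0))
    rows = []
    for (ia, a0), (ib, b0) in itertools.combinations(common, 2):
        s_psi = bhg_psi.saddle(ia, ib)
        s_0 = bhg_0.saddle(a0, b0)
        if not (math.isfinite(s_psi) and math.isfinite(s_0)):
            continue
        classes: set[str] = set()
        try:
            for s in bhg_psi.witness_structures(ia, ib):
                c = classify_pk(s)
                if c != "N":
                    classes.update(c)
        except (nx.NetworkXNoPath, TypeError):
            pass
        rows.append(
            {
                "lm_i": ia,
                "lm_j": ib,
                "S_psi": round(s_psi, 2),
                "S_0": round(s_0, 2),
                "delta": round(s_0 - s_psi, 2),
                "delta_pct": round(
                    100.0 * (s_0 - s_psi) / abs(s_0), 2
                ) if s_0 != 0 else 0.0,
                "pk_classes": "".join(sorted(classes)) or "N",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lm_i", "lm_j", "S_psi", "S_0", "delta", "delta_pct", "pk_classes"],
    )
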