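"""Move set, gradient walks and ensemble enumeration on 1-structure landscapes.

Adjacency is the single base-pair move: two structures are neighbors iff they
differ by adding or removing exactly one pair, with additions constrained to
stay inside the 1-structure class (and, in the crossing-free restricted
universe used for the pruned graph, to cross nothing).

The class of 1-structures is closed under pair removal, which makes subset
backtracking a complete enumerator and guarantees that every structure is
connected to the open chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .energy import EnergyParams, energy
from .structures import (
    MIN_HAIRPIN,
    Sequence,
    Structure,
    classify_pk,
    genus,
    pairs_cross,
)

__all__ = [
    "Move",
    "LocalMinimum",
    "EnsembleIndex",
    "candidate_pairs",
    "can_add_pair",
    "neighbors",
    "neighbor_moves",
    "apply_move",
    "gradient_walk",
    "enumerate_ensemble",
    "sample_minima",
    "lm_composition",
]

ENUMERATION_GUARD = 40  # refuse exhaustive enumeration beyond this length


@dataclass(frozen=True)
class Move:
    """A single base-pair change; applying then reverting is the identity."""

    kind: str  # "add" | "remove"
    pair: tuple[int, int]

    def inverse(self) -> "Move":
        return Move("remove" if self.kind == "add" else "add", self.pair)


@dataclass(frozen=True)
class LocalMinimum:
    """A structure with no single-move neighbor of strictly lower energy."""

    structure: Structure
    energy: float
    pk_class: str
    count: int = 0


@dataclass
class EnsembleIndex:
    """All 1-structures of a sequence within an energy ceiling above the MFE."""

    seq: Sequence
    structures: list[Structure]
    energies: np.ndarray
    ceiling: float | None
    params: EnergyParams
    mfe_index: int = 0

    @property
    def mfe(self) -> float:
        return float(self.energies[self.mfe_index])

    @property
    def mfe_structure(self) -> Structure:
        return self.structures[self.mfe_index]

    def boltzmann_probabilities(self) -> np.ndarray:
        w = np.exp(-(self.energies - self.energies.min()) / self.params.RT)
        return w / w.sum()

    def index_of(self, s: Structure) -> int:
        return self._lookup()[s]

    def __len__(self) -> int:
        return len(self.structures)

    def _lookup(self) -> dict:
        if not hasattr(self, "_lookup_cache"):
            self._lookup_cache = {s: k for k, s in enumerate(self.structures)}
        return self._lookup_cache


@lru_cache(maxsize=64)
def candidate_pairs(residues: str) -> tuple[tuple[int, int], ...]:
    """All canonical pairs (i, j) with j - i > MIN_HAIRPIN, 1-based, sorted."""
    seq = Sequence(residues)
    n = len(seq)
    out = []
    for i in range(1, n + 1):
        for j in range(i + MIN_HAIRPIN + 1, n + 1):
            if seq.can_pair(i, j):
                out.append((i, j))
    return tuple(out)


def can_add_pair(
    s: Structure, i: int, j: int, seq: Sequence, allow_pk: bool = True
) -> bool:
    """True iff adding (i, j) yields a valid structure in the working class.

    Validity of the union is decided locally: only the conflict-graph
    component that absorbs the new pair can change, so only its genus needs
    rechecking.
    """
    if i > j:
        i, j = j, i
    if j - i < MIN_HAIRPIN + 1 or j > len(seq):
        return False
    if not seq.can_pair(i, j):
        return False
    occupied = s.paired_positions()
    if i in occupied or j in occupied:
        return False
    if not allow_pk:
        return not any(pairs_cross((i, j), q) for q in s.pairs)
    # Only the chord-crossing component absorbing (i, j) changes, and the
    # genus of a chord component equals the genus of its helix shadow, so a
    # local chord-level genus check decides 1-structure membership.
    comp = _chord_component((i, j), s.pairs)
    if len(comp) == 1:
        return True
    return genus(comp) == 1


def _chord_component(
    new: tuple[int, int], pairs: tuple[tuple[int, int], ...]
) -> list[tuple[int, int]]:
    comp = [new]
    in_comp = {new}
    frontier = [new]
    remaining = list(pairs)
    while frontier:
        ch = frontier.pop()
        rest = []
        for q in remaining:
            if pairs_cross(ch, q):
                in_comp.add(q)
                comp.append(q)
                frontier.append(q)
            else:
                rest.append(q)
        remaining = rest
    return comp


def neighbor_moves(s: Structure, seq: Sequence, allow_pk: bool = True) -> list[Move]:
    """All valid single-pair moves, removals first, then additions, each in
    lexicographic (i, j) order (the gradient-walk tie-break order)."""
    moves = [Move("remove", p) for p in s.pairs]
    occupied = s.paired_positions()
    for i, j in candidate_pairs(seq.residues):
        if i in occupied or j in occupied:
            continue
        if can_add_pair(s, i, j, seq, allow_pk=allow_pk):
            moves.append(Move("add", (i, j)))
    return moves


def apply_move(s: Structure, m: Move) -> Structure:
    return s.add(*m.pair) if m.kind == "add" else s.remove(*m.pair)


def neighbors(s: Structure, seq: Sequence, allow_pk: bool = True) -> list[Structure]:
    """All structures one valid move away; the relation is symmetric."""
    return [apply_move(s, m) for m in neighbor_moves(s, seq, allow_pk=allow_pk)]


def gradient_walk(
    s0: Structure,
    seq: Sequence,
    p: EnergyParams,
    allow_pk: bool = True,
    _cache: dict | None = None,
) -> Structure:
    """Steepest descent to a local minimum.

    At each step the lowest-energy neighbor is taken; ties are broken
    deterministically (removals before additions, then lexicographic by
    (i, j)), so the result is independent of iteration order.  An optional
    cache maps already-resolved structures to their minima.
    """
    cur = s0
    cur_e = energy(seq, cur, p)
    trail = []
    while True:
        if _cache is not None and cur in _cache:
            cur = _cache[cur]
            break
        trail.append(cur)
        best = None
        for m in neighbor_moves(cur, seq, allow_pk=allow_pk):
            nb = apply_move(cur, m)
            e = energy(seq, nb, p)
            key = (e, 0 if m.kind == "remove" else 1, m.pair)
            if best is None or key < best[0]:
                best = (key, nb)
        if best is None or best[0][0] >= cur_e:
            break
        cur, cur_e = best[1], best[0][0]
    if _cache is not None:
        for s in trail:
            _cache[s] = cur
    return cur


def enumerate_ensemble(
    seq: Sequence,
    p: EnergyParams,
    ceiling: float | None = 10.0,
    allow_pk: bool = True,
    max_n: int = ENUMERATION_GUARD,
) -> EnsembleIndex:
    """Complete list of 1-structures with energy <= MFE + ceiling.

    ``ceiling=None`` keeps the whole ensemble.  Guarded against sequences
    longer than ``max_n``: the state space grows exponentially.
    """
    if len(seq) > max_n:
        raise ValueError(
            f"refusing exhaustive enumeration for n={len(seq)} > {max_n}"
        )
    cands = candidate_pairs(seq.residues)
    m = len(cands)
    # bitsets over candidate indices: which candidates cross / block which
    cross = [0] * m
    blocked = [0] * m
    for a in range(m):
        for b in range(a + 1, m):
            if pairs_cross(cands[a], cands[b]):
                cross[a] |= 1 << b
                cross[b] |= 1 << a
            if set(cands[a]) & set(cands[b]):
                blocked[a] |= 1 << b
                blocked[b] |= 1 << a

    structures: list[Structure] = []
    chosen: list[int] = []

    def component_ok(k: int, mask: int) -> bool:
        crossing = cross[k] & mask
        if not crossing:
            return True
        comp_mask = 1 << k
        frontier = crossing
        while frontier:
            comp_mask |= frontier
            nxt = 0
            f = frontier
            while f:
                low = f & -f
                nxt |= cross[low.bit_length() - 1] & mask
                f ^= low
            frontier = nxt & ~comp_mask
        comp = []
        cm = comp_mask
        while cm:
            low = cm & -cm
            comp.append(cands[low.bit_length() - 1])
            cm ^= low
        return genus(comp) == 1

    def backtrack(start: int, mask: int, forbidden: int) -> None:
        structures.append(Structure([cands[k] for k in chosen]))
        for k in range(start, m):
            bit = 1 << k
            if forbidden & bit:
                continue
            if allow_pk:
                if not component_ok(k, mask):
                    continue
            elif cross[k] & mask:
                continue
            chosen.append(k)
            backtrack(k + 1, mask | bit, forbidden | blocked[k])
            chosen.pop()

    backtrack(0, 0, 0)
    energies = np.array([energy(seq, s, p) for s in structures])
    order = sorted(range(len(structures)), key=lambda k: (energies[k], structures[k]))
    structures = [structures[k] for k in order]
    energies = energies[order]
    if ceiling is not None:
        keep = energies <= energies[0] + ceiling + 1e-9
        structures = [s for s, ok in zip(structures, keep) if ok]
        energies = energies[keep]
    return EnsembleIndex(seq, structures, energies, ceiling, p, mfe_index=0)


def _mcmc_sample(
    seq: Sequence,
    p: EnergyParams,
    n_samples: int,
    rng: np.random.Generator,
    allow_pk: bool,
    burn_in: int = 1000,
    thin: int = 10,
) -> list[Structure]:
    """Metropolis MCMC over the single-pair move set, started at the open
    chain; burn-in then thinned draws approximate the Boltzmann ensemble."""
    cur = Structure()
    cur_e = energy(seq, cur, p)
    out: list[Structure] = []
    steps = burn_in + thin * n_samples
    for step in range(steps):
        moves = neighbor_moves(cur, seq, allow_pk=allow_pk)
        if moves:
            m = moves[rng.integers(len(moves))]
            nb = apply_move(cur, m)
            nb_e = energy(seq, nb, p)
            # account for asymmetric neighborhood sizes to keep detailed balance
            back = len(neighbor_moves(nb, seq, allow_pk=allow_pk))
            ratio = math.exp(-(nb_e - cur_e) / p.RT) * len(moves) / back
            if rng.random() < min(1.0, ratio):
                cur, cur_e = nb, nb_e
        if step >= burn_in and (step - burn_in) % thin == 0:
            out.append(cur)
    return out


def sample_minima(
    seq: Sequence,
    p: EnergyParams,
    n_samples: int,
    seed: int,
    ceiling: float | None = 10.0,
    allow_pk: bool = True,
    max_enum_n: int = ENUMERATION_GUARD,
    ensemble: EnsembleIndex | None = None,
) -> list[LocalMinimum]:
    """Boltzmann-weighted local-minimum discovery.

    Draws ``n_samples`` structures proportionally to exp(-f/RT) — exactly,
    from the enumerated ensemble when the sequence is short enough, otherwise
    by Metropolis MCMC — gradient-walks each to its minimum, and accumulates
    discovery counts.  The MFE structure's minimum is always included.
    Restricted to the ceiling window above the MFE when given.
    """
    rng = np.random.default_rng(seed)
    cache: dict = {}
    hits: dict[Structure, int] = {}

    if len(seq) <= max_enum_n:
        if ensemble is None:
            ensemble = enumerate_ensemble(
                seq, p, ceiling=ceiling, allow_pk=allow_pk, max_n=max_enum_n
            )
        probs = ensemble.boltzmann_probabilities()
        draws = (
            rng.choice(len(ensemble), size=n_samples, p=probs)
            if n_samples
            else []
        )
        starts = [ensemble.structures[k] for k in draws]
        mfe_struct = ensemble.mfe_structure
    else:
        starts = _mcmc_sample(seq, p, n_samples, rng, allow_pk)
        mfe_struct = min(
            (gradient_walk(s, seq, p, allow_pk=allow_pk, _cache=cache) for s in starts),
            key=lambda s: (energy(seq, s, p), s),
            default=Structure(),
        )
    for s in starts:
        lm = gradient_walk(s, seq, p, allow_pk=allow_pk, _cache=cache)
        hits[lm] = hits.get(lm, 0) + 1
    anchor = gradient_walk(mfe_struct, seq, p, allow_pk=allow_pk, _cache=cache)
    hits.setdefault(anchor, 0)

    floor = energy(seq, anchor, p)
    out = []
    for s, count in hits.items():
        e = energy(seq, s, p)
        if ceiling is not None and e > floor + ceiling + 1e-9:
            continue
        out.append(LocalMinimum(s, e, classify_pk(s), count))
    out.sort(key=lambda lm: (lm.energy, lm.structure))
    return out


def lm_composition(lms: list[LocalMinimum]):
    """Fractions of local minima per pseudoknot class; sums to 1."""
    import pandas as pd

    if not lms:
        raise ValueError("empty local-minimum set")
    classes = pd.Series([lm.pk_class for lm in lms])
    return classes.value_counts(normalize=True).sort_index()
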