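import itertools

import pytest

from rnabhg.energy import EnergyParams
from rnabhg.landscape import enumerate_ensemble
from rnabhg.structures import Sequence, pairs_cross


@pytest.fixture(scope="session")
def params():
    return EnergyParams()


@pytest.fixture(scope="session")
def hairpin_seq():
    return Sequence("GGGAAAACCC", "hairpin")


@pytest.fixture(scope="session")
def two_basin_seq():
    return Sequence("GGGAAAACCCAAAAGGG", "two_basin")


@pytest.fixture(scope="session")
def h_type_seq():
    return Sequence("GGGAACUCAACCCAAGAG", "h_type")


@pytest.fixture(scope="session")
def two_basin_ensemble(two_basin_seq, params):
    return enumerate_ensemble(two_basin_seq, params, ceiling=None)


@pytest.fixture(scope="session")
def h_type_ensemble(h_type_seq, params):
    return enumerate_ensemble(h_type_seq, params, ceiling=None)


# ---------------------------------------------------------------------------
# independent oracles, shared across test modules


def genus_permutation_oracle(chords) -> int:
    """Genus via the permutation-cycle (surface gluing / Euler) formula:
    close the backbone into a circle, faces = cycles of (chord involution
    composed with the rotation), genus from the Euler characteristic."""
    chords = [tuple(sorted(c)) for c in chords]
    c = len(chords)
    if c == 0:
        return 0
    eps = sorted(p for ch in chords for p in ch)
    rank = {p: r for r, p in enumerate(eps)}
    m = 2 * c
    alpha = list(range(m))
    for i, j in chords:
        alpha[rank[i]], alpha[rank[j]] = rank[j], rank[i]
    perm = [alpha[(k + 1) % m] for k in range(m)]
    seen = [False] * m
    faces = 0
    for s in range(m):
        if seen[s]:
            continue
        faces += 1
        k = s
        while not seen[k]:
            seen[k] = True
            k = perm[k]
    return (c - faces + 1) // 2


def chord_components(pairs):
    pairs = list(pairs)
    n = len(pairs)
    adj = [[] for _ in range(n)]
    for a in range(n):
        for b in range(a + 1, n):
            if pairs_cross(pairs[a], pairs[b]):
                adj[a].append(b)
                adj[b].append(a)
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(pairs[v])
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


def one_structure_oracle(pairs) -> bool:
    """Brute force: every crossing component must have genus exactly 1,
    computed by the independent permutation-cycle oracle."""
    for comp in chord_components(pairs):
        if len(comp) == 1:
            continue
        if any(
            pairs_cross(a, b) for a, b in itertools.combinations(comp, 2)
        ) and genus_permutation_oracle(comp) != 1:
            return False
    return True


def all_matchings(points):
    """All perfect matchings of an even point set (chord diagrams)."""
    points = list(points)
    if not points:
        yield []
        return
    a = points[0]
    for idx in range(1, len(points)):
        b = points[idx]
        rest = points[1:idx] + points[idx + 1 :]
        for m in all_matchings(rest):
            yield [(a, b)] + m


def diagram_of_word(word):
    """Chord diagram from a letter word, e.g. 'ABAB' -> [(1,3),(2,4)]."""
    pos = {}
    for k, ch in enumerate(word, 1):
        pos.setdefault(ch, []).append(k)
    return [tuple(v) for v in pos.values()]


def exact_lm_table(ensemble, seq, params):
    """All exact local minima of a fully enumerated landscape, via the
    subset adjacency (each structure's neighbors are itself minus a pair)."""
    idx = {s.pairs: k for k, s in enumerate(ensemble.structures)}
    E = ensemble.energies
    is_lm = [True] * len(ensemble)
    for k, s in enumerate(ensemble.structures):
        for q in s.pairs:
            t = idx[s.remove(*q).pairs]
            if E[t] < E[k] - 1e-9:
                is_lm[k] = False
            elif E[k] < E[t] - 1e-9:
                is_lm[t] = False
    return [
        (float(E[k]), ensemble.structures[k])
        for k in range(len(ensemble))
        if is_lm[k]
    ]
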