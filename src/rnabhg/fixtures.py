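"""Designed short sequences that make every landscape algorithm testable.

Each fixture kind arranges complementary blocks so that the intended folding
pattern is energetically reachable:

* ``pk_free``   — a single stable hairpin (optionally two nested ones).
* ``two_basin`` — two hairpins competing for a shared middle block, giving
  two separated basins connected near the open chain.
* ``h_type``    — two interleaved complementary block pairs whose joint
  structure is an H-type pseudoknot.
* ``k_type``    — three block pairs in the kissing-hairpin arrangement
  (A B A' C B' C'), yielding a K-type local minimum.
* ``pk_shortcut`` — two crossing 3-pair GC helices evaluated with a reduced
  H-penalty (beta_H = 4 kcal/mol, ordering invariant preserved) so that the
  cheapest refolding path between the two hairpin minima passes through the
  pseudoknotted intermediate; with the default penalty, which exceeds any
  single-move stacking gain, no enumerable-scale landscape can exhibit such
  a shortcut.

Expected properties are computed by the exhaustive oracles at build time
(``annotate=True``), never hand-written.  Same seed, same fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyParams
from .landscape import enumerate_ensemble, neighbors
from .structures import Sequence, Structure, classify_pk

__all__ = ["Fixture", "generate_fixtures", "qss_ring_model", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("pk_free", "two_basin", "h_type", "k_type", "pk_shortcut")


@dataclass(frozen=True)
class Fixture:
    seq: Sequence
    kind: str
    params: EnergyParams
    expected: dict = field(default_factory=dict, compare=False)


def _pk_free(rng: np.random.Generator) -> str:
    stem = rng.integers(2, 4)  # 2 or 3 base pairs
    loop = rng.integers(4, 7)
    tail = rng.integers(0, 3)
    return "G" * stem + "A" * loop + "C" * stem + "A" * tail


def _two_basin(rng: np.random.Generator) -> str:
    stem = rng.integers(2, 4)
    l1 = rng.integers(4, 6)
    l2 = rng.integers(4, 6)
    return "G" * stem + "A" * l1 + "C" * stem + "A" * l2 + "G" * stem


def _h_type(rng: np.random.Generator) -> str:
    l1 = rng.integers(1, 3)
    l2 = rng.integers(1, 3)
    l3 = rng.integers(1, 3)
    a = "A"
    return (
        "GGG" + a * l1 + "CUC" + a * l2 + "CCC" + a * l3 + "GAG"
    )


def _k_type(rng: np.random.Generator) -> str:
    # A=GC, B=GGG, A'=GC, C=CG, B'=CCC, C'=CG with single-A linkers;
    # the optional extra linker after B' shifts registers deterministically
    l = rng.integers(1, 3)
    return "GC" + "A" + "GGG" + "A" * l + "GC" + "A" + "CG" + "A" + "CCC" + "A" * l + "CG"


def _pk_shortcut(rng: np.random.Generator) -> str:
    l = rng.integers(1, 3)
    return "GGG" + "A" * l + "GCG" + "A" * l + "CCC" + "A" * l + "CGC"


_BUILDERS = {
    "pk_free": _pk_free,
    "two_basin": _two_basin,
    "h_type": _h_type,
    "k_type": _k_type,
    "pk_shortcut": _pk_shortcut,
}


def _annotate(seq: Sequence, p: EnergyParams, ceiling: float) -> dict:
    ens = enumerate_ensemble(seq, p, ceiling=None)
    emap = {s.pairs: e for s, e in zip(ens.structures, ens.energies)}
    lms = []
    for s, e in zip(ens.structures, ens.energies):
        if all(
            emap[t.pairs] >= e - 1e-9 for t in neighbors(s, seq)
        ):
            lms.append((float(e), s))
    mfe = ens.mfe
    window = [(e, s) for e, s in lms if e <= mfe + ceiling + 1e-9]
    classes = sorted({classify_pk(s) for _, s in window})
    return {
        "n_states": len(ens),
        "mfe": mfe,
        "mfe_class": classify_pk(ens.mfe_structure),
        "n_lms": len(lms),
        "n_lms_window": len(window),
        "classes_window": classes,
    }


def qss_ring_model(n_core: int = 10):
    """Designed 20-state kinetic fixture for quasi-steady-state reduction.

    Ten deep "core" minima sit on a ring; consecutive cores are connected
    through high-energy, degree-2 intermediate minima (the textbook QSS
    situation: the intermediates carry negligible population on every time
    scale).  Cores additionally get direct high-saddle chords so that the
    degree criterion unambiguously selects the intermediates for
    elimination.  Returns ``(model, protected)`` where ``protected`` holds
    the lowest core and core 0 (the start state).

    The states carry synthetic placeholder structures; only their energies
    and the generator matter.
    """
    import math as _math

    from .kinetics import RateModel
    from .landscape import LocalMinimum as _LM

    p = EnergyParams()
    RT = p.RT
    n = 2 * n_core
    energies = [0.0] * n
    for k in range(n_core):
        energies[k] = -6.0 + 0.1 * k  # cores
        energies[n_core + k] = 1.0 + 0.05 * k  # intermediates
    edges = []
    for k in range(n_core):
        m = n_core + k
        s = energies[m] + 0.5
        edges.append((k, m, s))
        edges.append((m, (k + 1) % n_core, s))
        # direct chord: raises core degrees above the intermediates'
        edges.append((k, (k + 2) % n_core, 3.0))
    import numpy as _np

    R = _np.zeros((n, n))
    for a, b, s in edges:
        R[a, b] += p.r0 * _math.exp(-(s - energies[a]) / RT)
        R[b, a] += p.r0 * _math.exp(-(s - energies[b]) / RT)
    _np.fill_diagonal(R, 0.0)
    _np.fill_diagonal(R, -R.sum(axis=1))
    states = [
        _LM(Structure([(1, 5 + k)]), energies[k], "N") for k in range(n)
    ]
    model = RateModel(states, R, p)
    protected = {int(_np.argmin(energies)), 0}
    return model, protected


def generate_fixtures(
    kind: str,
    n: int,
    seed: int,
    annotate: bool = False,
    ceiling: float = 10.0,
) -> list[Fixture]:
    """Deterministically generate ``n`` designed fixtures of one kind.

    Sequences are guarded to at most 40 nt (they are all far shorter); with
    ``annotate=True`` the expected landscape properties are computed by the
    exhaustive enumeration oracle and attached.
    """
    if kind not in _BUILDERS:
        raise ValueError(f"unknown fixture kind {kind!r}; use one of {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    params = (
        EnergyParams(beta_H=4.0) if kind == "pk_shortcut" else EnergyParams()
    )
    out: list[Fixture] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        residues = _BUILDERS[kind](rng)
        if len(residues) > 40:
            continue
        if residues in seen:
            continue
        seen.add(residues)
        seq = Sequence(residues, f"{kind}_{len(out)}")
        expected = _annotate(seq, params, ceiling) if annotate else {}
        out.append(Fixture(seq, kind, params, expected))
    return out
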