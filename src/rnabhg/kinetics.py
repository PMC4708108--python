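"""Folding kinetics as continuous-time Markov chains on basin hopping graphs.

On the coarse-grained graph the rate out of minimum y toward an adjacent
minimum x follows the Arrhenius law over the connecting saddle::

    r(y -> x) = r0 * exp(-(S(x, y) - f(y)) / RT)

with r0 = 1 defining the time unit.  On the full (microscopic) landscape the
Metropolis rule r(x -> y) = r0 * min{1, exp(-(f(y) - f(x)) / RT)} applies to
single base-pair moves.  Both generators satisfy detailed balance with
respect to the Boltzmann distribution of their state energies, which is used
for a numerically robust symmetrized propagator p(t) = p(0) exp(tR).

State-space reduction follows the quasi-steady-state idea: low-degree (then
high-energy) minima are eliminated one at a time, redistributing their flux

    r'(a -> b) += r(a -> q) * r(q -> b) / sum_c r(q -> c)

which is exactly the Schur complement of the generator and therefore
preserves reversibility and the restricted equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from .bhg import BasinHoppingGraph
from .energy import EnergyParams
from .landscape import EnsembleIndex, LocalMinimum, enumerate_ensemble
from .structures import Sequence, Structure, classify_pk

__all__ = [
    "RateModel",
    "PopulationSeries",
    "rate_matrix",
    "metropolis_rate_matrix",
    "microscopic_model",
    "propagate",
    "default_time_grid",
    "equilibrium_time",
    "qss_reduce",
    "aggregate_to_basins",
]

EPS = 1e-12


@dataclass
class RateModel:
    """A CTMC over landscape states.

    Row-vector convention: populations evolve as ``p'(t) = p(t) R``, so the
    off-diagonal entry ``R[y, x]`` is the rate from state y to state x and
    each row sums to zero.
    """

    states: list[LocalMinimum]
    R: np.ndarray
    params: EnergyParams

    def __post_init__(self) -> None:
        n = len(self.states)
        if self.R.shape != (n, n):
            raise ValueError("generator shape does not match state count")

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.states])

    def outflow(self) -> np.ndarray:
        """Total exit rate lambda_x of every state."""
        return -np.diag(self.R)

    def equilibrium(self) -> np.ndarray:
        """Boltzmann distribution over the model's states."""
        e = self.energies
        w = np.exp(-(e - e.min()) / self.params.RT)
        return w / w.sum()

    def index_of(self, s: Structure) -> int:
        for k, lm in enumerate(self.states):
            if lm.structure.pair_set == s.pair_set:
                return k
        raise KeyError("structure is not a state of this model")

    def degrees(self) -> np.ndarray:
        off = self.R - np.diag(np.diag(self.R))
        return ((off > 0) | (off.T > 0)).sum(axis=1)


@dataclass
class PopulationSeries:
    """State probabilities on a time grid (times in r0^-1 units)."""

    times: np.ndarray
    populations: np.ndarray  # shape (len(times), n_states)
    states: list[LocalMinimum]

    def column(self, k: int) -> np.ndarray:
        return self.populations[:, k]


def rate_matrix(bhg: BasinHoppingGraph, p: EnergyParams) -> RateModel:
    """Arrhenius generator over a BHG (rates over edge saddle heights).

    Raises if an edge saddle lies below either endpoint energy, which would
    produce a rate > r0 and violate the saddle definition.
    """
    n = len(bhg.lms)
    R = np.zeros((n, n))
    f = np.array([lm.energy for lm in bhg.lms])
    RT = p.RT
    for x, y, data in bhg.graph.edges(data=True):
        s = data["saddle"]
        if s < max(f[x], f[y]) - 1e-6:
            raise ValueError(
                f"edge saddle {s} below endpoint energies ({f[x]}, {f[y]})"
            )
        s = max(s, max(f[x], f[y]))  # clamp rounding noise
        R[y, x] = p.r0 * math.exp(-(s - f[y]) / RT)
        R[x, y] = p.r0 * math.exp(-(s - f[x]) / RT)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    return RateModel(list(bhg.lms), R, p)


def metropolis_rate_matrix(
    states: list[LocalMinimum],
    adjacency: list[tuple[int, int]],
    p: EnergyParams,
) -> RateModel:
    """Metropolis generator: rate x->y = r0 min{1, exp(-(f(y)-f(x))/RT)}."""
    n = len(states)
    R = np.zeros((n, n))
    f = np.array([s.energy for s in states])
    for x, y in adjacency:
        R[x, y] = p.r0 * min(1.0, math.exp(-(f[y] - f[x]) / p.RT))
        R[y, x] = p.r0 * min(1.0, math.exp(-(f[x] - f[y]) / p.RT))
    np.fill_diagonal(R, -R.sum(axis=1))
    return RateModel(list(states), R, p)


def microscopic_model(
    seq: Sequence,
    p: EnergyParams,
    ceiling: float | None = None,
    allow_pk: bool = True,
    max_n: int = 30,
    ensemble: EnsembleIndex | None = None,
) -> tuple[RateModel, EnsembleIndex]:
    """Metropolis CTMC over every enumerated structure (validation oracle)."""
    ens = ensemble or enumerate_ensemble(
        seq, p, ceiling=ceiling, allow_pk=allow_pk, max_n=max_n
    )
    idx = {s.pairs: k for k, s in enumerate(ens.structures)}
    adjacency = []
    for k, s in enumerate(ens.structures):
        for q in s.pairs:
            t = idx.get(s.remove(*q).pairs)
            if t is not None:
                adjacency.append((k, t))
    states = [
        LocalMinimum(s, float(e), classify_pk(s))
        for s, e in zip(ens.structures, ens.energies)
    ]
    return metropolis_rate_matrix(states, adjacency, p), ens


def default_time_grid(
    t_min: float = 1e-2, t_max: float = 1e18, per_decade: int = 60, cap: int = 600
) -> np.ndarray:
    """Log-spaced time grid in r0^-1 units (mirrors typical kinetics plots)."""
    decades = math.log10(t_max) - math.log10(t_min)
    npts = min(cap, max(2, int(decades * per_decade)))
    return np.logspace(math.log10(t_min), math.log10(t_max), npts)


def propagate(
    model: RateModel, p0: np.ndarray, times: np.ndarray
) -> PopulationSeries:
    """Populations p(t) = p0 exp(tR) on the given time grid.

    The generator is reversible w.r.t. the Boltzmann distribution, so it is
    symmetrized as M = D^{1/2} R D^{-1/2} (D = diag(pi)) and propagated by a
    single symmetric eigendecomposition; probability is conserved to machine
    precision at every time.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (len(model.states),) or abs(p0.sum() - 1.0) > 1e-9 or (
        p0 < -EPS
    ).any():
        raise ValueError("p0 must be a probability vector over the states")
    pi = model.equilibrium()
    d = np.sqrt(pi)
    M = (model.R * d[:, None] / d[None, :])
    M = 0.5 * (M + M.T)  # exact for reversible generators; guards rounding
    lam, U = scipy.linalg.eigh(M)
    lam = np.minimum(lam, 0.0)  # generator spectrum is non-positive
    # The stationary modes (one per connected component) must have eigenvalue
    # exactly 0; rounding noise of order 1e-16 would otherwise decay the
    # equilibrium visibly at times beyond ~1e12.
    off = model.R - np.diag(np.diag(model.R))
    n_comp, _ = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(off > 0), directed=False
    )
    lam[-n_comp:] = 0.0
    left = (p0 / d) @ U
    out = np.empty((len(times), len(p0)))
    for k, t in enumerate(times):
        out[k] = (left * np.exp(lam * t)) @ U.T * d
    return PopulationSeries(np.asarray(times, dtype=float), out, model.states)


def equilibrium_time(
    series: PopulationSeries, pi: np.ndarray, tol: float = 0.01
) -> float:
    """First grid time at which the L1 distance to equilibrium drops below
    ``tol``; +inf if it never does within the grid."""
    dist = np.abs(series.populations - pi[None, :]).sum(axis=1)
    hit = np.nonzero(dist < tol)[0]
    return float(series.times[hit[0]]) if hit.size else math.inf


def qss_reduce(
    model: RateModel,
    max_states: int,
    protected: set[int] | None = None,
) -> tuple[RateModel, list[int]]:
    """Quasi-steady-state elimination down to at most ``max_states`` states.

    Repeatedly removes the non-protected state with the lowest degree
    (highest energy on ties) — low-degree minima are short-lived pathway
    intermediates — redistributing its flux by the Schur complement.
    Returns the reduced model and the retained original indices.
    """
    protected = set(protected or ())
    if max_states < len(protected):
        raise ValueError("max_states smaller than the protected set")
    keep = list(range(len(model.states)))
    R = model.R.copy()
    while len(keep) > max_states:
        off = R - np.diag(np.diag(R))
        deg = ((off > 0) | (off.T > 0)).sum(axis=1)
        candidates = [
            (deg[k], -model.states[orig].energy, k)
            for k, orig in enumerate(keep)
            if orig not in protected
        ]
        if not candidates:
            break
        _, _, q = min(candidates)
        lam_q = -R[q, q]
        if lam_q > 0:
            out_rates = R[q, :].copy()
            out_rates[q] = 0.0
            in_rates = R[:, q].copy()
            in_rates[q] = 0.0
            R += np.outer(in_rates, out_rates) / lam_q
        R = np.delete(np.delete(R, q, axis=0), q, axis=1)
        np.fill_diagonal(R, 0.0)
        np.fill_diagonal(R, -R.sum(axis=1))
        keep.pop(q)
    states = [model.states[k] for k in keep]
    return RateModel(states, R, model.params), keep


def aggregate_to_basins(
    series: PopulationSeries,
    basin_of: list[int],
    n_basins: int,
) -> np.ndarray:
    """Sum microscopic state populations into their gradient-walk basins."""
    out = np.zeros((series.populations.shape[0], n_basins))
    for k, b in enumerate(basin_of):
        out[:, b] += series.populations[:, k]
    return out
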