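"""Optimal refolding paths in a basin hopping graph.

Two optimality criteria are provided:

* **Criterion A** — minimize the peak energy along the path (evaluated on
  edge saddles, where BHG paths attain their maxima) and, among equally good
  solutions, the accumulated activation energy
  ``sum_s (S(x_s, x_{s+1}) - f(x_s))``.
* **Criterion B** — maximum-likelihood timed trajectories
  ``U = (x0, t0, x1, t1, ..., xk)`` under an upper time bound ``T_m``, with

      L(U) = prod_i r(x_i -> x_{i+1})
             * exp(-(sum_i lambda_{x_i} t_i + lambda_{x_k} (T_m - sum t_i)))

  For ``T_m = 0`` every waiting time vanishes and maximizing L is equivalent
  to minimizing the accumulated activation energy.  For ``T_m > 0`` the time
  allocation is linear in the waiting times over a simplex, so the optimum
  puts the whole slack on the visited state with the smallest total exit
  rate (the earliest such state on ties).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .bhg import BasinHoppingGraph
from .kinetics import RateModel

__all__ = [
    "PathScore",
    "Trajectory",
    "optimal_path_A",
    "optimal_path_B",
    "trajectory_loglik",
    "accumulated_activation",
]

EPS = 1e-9


@dataclass(frozen=True)
class PathScore:
    peak: float  # kcal/mol, over edge saddles
    activation: float  # accumulated activation energy, kcal/mol
    loglik: float | None = None


@dataclass(frozen=True)
class Trajectory:
    """Timed state sequence (x0, t0, x1, t1, ..., xk) with horizon T_m."""

    states: tuple[int, ...]
    times: tuple[float, ...]  # waiting time in every state but the last
    horizon: float

    def __post_init__(self) -> None:
        if len(self.times) != max(len(self.states) - 1, 0):
            raise ValueError("need one waiting time per non-final state")
        if any(t < 0 for t in self.times):
            raise ValueError("waiting times must be non-negative")


def _edge_saddle(bhg: BasinHoppingGraph, a: int, b: int) -> float:
    return bhg.graph.edges[a, b]["saddle"]


def accumulated_activation(bhg: BasinHoppingGraph, nodes: list[int]) -> float:
    """sum_s (S(x_s, x_{s+1}) - f(x_s)) along consecutive BHG edges."""
    total = 0.0
    for a, b in zip(nodes, nodes[1:]):
        total += _edge_saddle(bhg, a, b) - bhg.lms[a].energy
    return total


def _dijkstra_activation(
    bhg: BasinHoppingGraph,
    x: int,
    y: int,
    saddle_cap: float = math.inf,
) -> list[int]:
    """Least accumulated-activation-energy path, edges above the cap
    excluded; deterministic tie-break by fewer edges, then node-id sequence."""
    # priority: (cost, hops, path); activation weights are non-negative
    heap = [(0.0, 0, (x,))]
    best: dict[int, tuple[float, int, tuple[int, ...]]] = {}
    while heap:
        cost, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in best and (cost, hops, path) > best[node]:
            continue
        if node == y:
            return list(path)
        for nb in sorted(bhg.graph.neighbors(node)):
            s = _edge_saddle(bhg, node, nb)
            if s > saddle_cap + EPS:
                continue
            w = s - bhg.lms[node].energy
            if w < -EPS:
                raise ValueError("edge saddle below source energy")
            cand = (cost + max(w, 0.0), hops + 1, path + (nb,))
            if nb not in best or (cand[0], cand[1], cand[2]) < best[nb]:
                best[nb] = (cand[0], cand[1], cand[2])
                heapq.heappush(heap, cand)
    raise ValueError(f"nodes {x} and {y} are not connected")


def optimal_path_A(
    bhg: BasinHoppingGraph, x: int, y: int
) -> tuple[list[int], PathScore]:
    """Criterion-A optimal refolding path between two BHG nodes.

    First the minimax saddle value is computed (bottleneck shortest path);
    the search is then restricted to edges at or below that value and the
    least accumulated-activation-energy path is taken, with deterministic
    tie-breaks (fewer edges, then lexicographic node ids).
    """
    if x == y:
        return [x], PathScore(bhg.lms[x].energy, 0.0)
    bottleneck = bhg.saddle(x, y)
    if not math.isfinite(bottleneck):
        raise ValueError(f"nodes {x} and {y} are not connected")
    nodes = _dijkstra_activation(bhg, x, y, saddle_cap=bottleneck)
    peak = max(_edge_saddle(bhg, a, b) for a, b in zip(nodes, nodes[1:]))
    return nodes, PathScore(peak, accumulated_activation(bhg, nodes))


def trajectory_loglik(u: Trajectory, model: RateModel) -> float:
    """Log-likelihood of a timed trajectory under the CTMC.

    Returns -inf when the waiting times exceed the horizon.  Consecutive
    states must be adjacent (nonzero rate), otherwise a ValueError is
    raised.
    """
    if sum(u.times) > u.horizon + EPS:
        return -math.inf
    lam = model.outflow()
    ll = 0.0
    for a, b in zip(u.states, u.states[1:]):
        r = model.R[a, b]
        if r <= 0:
            raise ValueError(f"states {a} and {b} are not adjacent")
        ll += math.log(r)
    ll -= sum(lam[a] * t for a, t in zip(u.states, u.times))
    ll -= lam[u.states[-1]] * (u.horizon - sum(u.times))
    return ll


def optimal_path_B(
    bhg: BasinHoppingGraph,
    model: RateModel,
    x: int,
    y: int,
    T_m: float = 0.0,
) -> tuple[Trajectory, PathScore]:
    """Maximum-likelihood refolding trajectory with time bound ``T_m``.

    The state sequence is the minimum accumulated-activation-energy path
    (for T_m = 0 this *is* the exact maximum-likelihood trajectory); for
    T_m > 0 the whole slack is assigned to the visited state with minimal
    total exit rate, the earliest on ties, which is optimal for the given
    sequence because the exponent is linear in the waiting times.
    """
    if T_m < 0:
        raise ValueError("T_m must be non-negative")
    nodes = _dijkstra_activation(bhg, x, y)
    lam = model.outflow()
    times = [0.0] * (len(nodes) - 1)
    if T_m > 0 and len(nodes) > 0:
        lam_path = [lam[n] for n in nodes]
        k_min = int(np.argmin(lam_path))
        if k_min < len(times):
            times[k_min] = T_m
        # slack in the final state is implicit in the horizon term
    u = Trajectory(tuple(nodes), tuple(times), T_m)
    ll = trajectory_loglik(u, model)
    peak = (
        max(_edge_saddle(bhg, a, b) for a, b in zip(nodes, nodes[1:]))
        if len(nodes) > 1
        else bhg.lms[x].energy
    )
    return u, PathScore(peak, accumulated_activation(bhg, nodes), ll)
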