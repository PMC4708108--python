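"""Free energies of 1-structures under a pluggable stacking model.

The evaluator is deliberately simple and fully documented: the free energy of
a structure is the sum of

* stacking terms over consecutive pairs inside each helix (negative for
  stabilizing stacks),
* a positive helix-end penalty per helix (a crude stand-in for loop
  initiation costs), and
* a pseudoknot penalty per crossing component, depending on its type
  (``beta_H <= beta_K <= min(beta_L, beta_M)``).

The open chain has energy 0 by construction.  The default penalties make the
*first* crossing pair of any structure strictly uphill (the penalty exceeds
the largest possible single-move stacking gain), so gradient walks started
from crossing-free structures never end in pseudoknotted local minima.

A custom nested-structure evaluator can be plugged in via
``EnergyParams.nested_hook`` to replace the stacking+end-penalty part while
keeping the pseudoknot penalties and every landscape algorithm unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import yaml

from .structures import (
    Helix,
    Sequence,
    Structure,
    classify_components,
    decompose_helices,
)

__all__ = [
    "EnergyParams",
    "DEFAULT_PAIR_STRENGTH",
    "energy",
    "boltzmann_weight",
    "load_params",
    "save_params",
    "default_stacking_table",
]

#: per-pair-type stabilities (kcal/mol) used to generate the default
#: stacking table: stack(p, q) = -(strength(p) + strength(q)) / 2
DEFAULT_PAIR_STRENGTH = {
    "GC": 3.3,
    "CG": 3.3,
    "AU": 1.1,
    "UA": 1.1,
    "GU": 0.7,
    "UG": 0.7,
}

GAS_CONSTANT = 0.00198717  # kcal/(mol*K)


def default_stacking_table() -> dict[tuple[str, str], float]:
    """Stacking energies for all 36 ordered pairs of canonical pair types."""
    table = {}
    for p, sp in DEFAULT_PAIR_STRENGTH.items():
        for q, sq in DEFAULT_PAIR_STRENGTH.items():
            table[(p, q)] = round(-(sp + sq) / 2, 2)
    return table


@dataclass(frozen=True)
class EnergyParams:
    """Parameters of the energy model.

    Units: kcal/mol for energies, Kelvin for the temperature.  ``r0`` is the
    dimensionless rate gauge that defines the time unit of the kinetics.
    """

    stacking: dict = field(default_factory=default_stacking_table)
    helix_end_penalty: float = 2.0
    beta_H: float = 9.6
    beta_K: float = 12.6
    beta_L: float = 14.6
    beta_M: float = 14.6
    temperature: float = 310.15
    gas_constant: float = GAS_CONSTANT
    r0: float = 1.0
    nested_hook: Callable | None = None
    #: per-instance memo of evaluated structures, keyed (residues, pairs)
    cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.beta_H <= self.beta_K <= min(self.beta_L, self.beta_M):
            raise ValueError(
                "pseudoknot penalties must satisfy "
                "beta_H <= beta_K <= min(beta_L, beta_M)"
            )
        if self.RT <= 0:
            raise ValueError("RT must be positive")
        for (p, q), e in self.stacking.items():
            if p in ("GC", "CG") and q in ("GC", "CG") and e > 0:
                raise ValueError("Watson-Crick stacks must be stabilizing")

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature

    def beta(self, pk_type: str) -> float:
        return {
            "H": self.beta_H,
            "K": self.beta_K,
            "L": self.beta_L,
            "M": self.beta_M,
        }[pk_type]

    def max_single_move_gain(self) -> float:
        """Largest energy gain a single pair addition can achieve: closing a
        gap between two stacks gains two stacking terms and removes one
        helix-end penalty."""
        best_stack = min(self.stacking.values())
        return -2 * best_stack + self.helix_end_penalty


def _helix_energy(seq: Sequence, helix: Helix, p: EnergyParams) -> float:
    e = p.helix_end_penalty
    pairs = helix.pairs
    for k in range(len(pairs) - 1):
        (i, j), (i2, j2) = pairs[k], pairs[k + 1]
        key = (seq[i] + seq[j], seq[i2] + seq[j2])
        if key not in p.stacking:
            raise ValueError(f"no stacking entry for {key}")
        e += p.stacking[key]
    return e


def energy(seq: Sequence, s: Structure, p: EnergyParams) -> float:
    """Free energy f(x) of a 1-structure x, in kcal/mol (open chain = 0)."""
    key = (seq.residues, s.pairs)
    hit = p.cache.get(key)
    if hit is not None:
        return hit
    s.check_canonical(seq)
    if p.nested_hook is not None:
        e = p.nested_hook(seq, s)
    else:
        e = 0.0
        for helix in decompose_helices(s):
            e += _helix_energy(seq, helix, p)
    for pk_type in classify_components(s):  # raises on non-1-structures
        e += p.beta(pk_type)
    e = round(e, 10)
    p.cache[key] = e
    return e


def boltzmann_weight(e: float, p: EnergyParams) -> float:
    """exp(-e / RT)."""
    if not math.isfinite(e):
        raise ValueError("energy must be finite")
    return math.exp(-e / p.RT)


_SCALAR_KEYS = (
    "helix_end_penalty",
    "beta_H",
    "beta_K",
    "beta_L",
    "beta_M",
    "temperature",
    "gas_constant",
    "r0",
)


def load_params(path) -> EnergyParams:
    """Load parameters from a YAML key-value file; missing keys take the
    documented defaults, and the beta ordering invariant is enforced."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("parameter file must be a mapping")
    kwargs = {}
    for key in _SCALAR_KEYS:
        if key in raw:
            kwargs[key] = float(raw.pop(key))
    if "pair_strengths" in raw:
        strengths = {str(k): float(v) for k, v in raw.pop("pair_strengths").items()}
        table = {
            (p, q): round(-(sp + sq) / 2, 2)
            for p, sp in strengths.items()
            for q, sq in strengths.items()
        }
        kwargs["stacking"] = table
    if "stacking" in raw:
        table = kwargs.get("stacking", default_stacking_table()).copy()
        for key, val in raw.pop("stacking").items():
            a, b = str(key).split("/")
            table[(a, b)] = float(val)
        kwargs["stacking"] = table
    if raw:
        raise ValueError(f"unknown parameter keys: {sorted(raw)}")
    return EnergyParams(**kwargs)


def save_params(p: EnergyParams, path) -> None:
    data = {key: getattr(p, key) for key in _SCALAR_KEYS}
    data["stacking"] = {f"{a}/{b}": e for (a, b), e in sorted(p.stacking.items())}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
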