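"""Reduced nearest-neighbor energy model used by the built-in reference folder.

The model keeps the load-bearing features of full nearest-neighbor
thermodynamics — sequence-dependent helix stacking over all six canonical
pairs, plus destabilizing loop penalties — while replacing the long tail of
tabulated special cases (terminal mismatches, tetraloop bonuses, asymmetry
terms, coaxial stacking) with affine penalties.  It exists so that folding
can be verified exactly against brute-force enumeration; quantitative
kcal/mol agreement with a full Turner-2004 engine is explicitly not a goal.

Energy of a structure = sum over loops:

* stack (i,j) on (i+1,j-1): tabulated 6x6 stacking term;
* hairpin of u unpaired nt (u >= 3): ``hairpin_a + hairpin_b*(u-3)``;
* bulge of u unpaired nt: ``bulge_a + bulge_b*(u-1)``;
* internal loop of u total unpaired nt: ``internal_a + internal_b*(u-2)``;
* multibranch loop: ``ml_a + ml_b*(branches+1) + ml_c*unpaired``
  (the ``+1`` counts the closing pair);
* exterior loop: 0, so the open chain has exactly 0.0 kcal/mol.

Bulge/internal loops with more than ``max_interior`` unpaired nucleotides
are outside the model (infinite energy), as are hairpins under
``min_hairpin`` unpaired, non-canonical pairs and — unless
``allow_lone_pairs`` — helices of a single pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import BASE_INDEX, PAIR_REVERSE, pair_type
from .structure import SecondaryStructure, loop_decomposition

#: kcal/(mol*K) times 310.15 K
RT_37 = 0.0019872 * 310.15

# Stacking free energies, kcal/mol, for the pair (i,j) stacked on (i+1,j-1).
# Specified on a generating half-set; the rest follows from the symmetry
# E[outer][inner] = E[rev(inner)][rev(outer)] (reading the duplex from the
# other strand).  Watson-Crick values follow the published nearest-neighbor
# scale; wobble-containing stacks use rounded representative values.
_STACK_SPEC = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("AU", "GC"): -2.08, ("AU", "CG"): -2.24,
    ("UA", "AU"): -1.33, ("UA", "GC"): -2.11, ("UA", "CG"): -2.35,
    ("GC", "GC"): -3.26, ("GC", "CG"): -3.42,
    ("CG", "GC"): -2.36,
    ("AU", "GU"): -0.60, ("AU", "UG"): -1.40,
    ("UA", "GU"): -1.00, ("UA", "UG"): -1.30,
    ("GC", "GU"): -1.50, ("GC", "UG"): -2.50,
    ("CG", "GU"): -1.40, ("CG", "UG"): -2.10,
    ("GU", "GU"): 0.50, ("GU", "UG"): -0.50, ("UG", "GU"): -0.60,
}

_PAIR_ORDER = ["AU", "UA", "GC", "CG", "GU", "UG"]


def _build_stack_table() -> np.ndarray:
    idx = {p: k for k, p in enumerate(_PAIR_ORDER)}
    table = np.full((6, 6), np.nan)
    for (o, i), e in _STACK_SPEC.items():
        table[idx[o], idx[i]] = e
    # complete by symmetry
    for o in range(6):
        for i in range(6):
            mirror = table[PAIR_REVERSE[i], PAIR_REVERSE[o]]
            if np.isnan(table[o, i]):
                table[o, i] = mirror
            elif not np.isnan(mirror) and abs(table[o, i] - mirror) > 1e-9:
                raise AssertionError("stack table breaks duplex symmetry")
    assert not np.isnan(table).any()
    return table


@dataclass(frozen=True)
class ReducedParams:
    """Parameter set of the reduced nearest-neighbor model (kcal/mol)."""

    stack: np.ndarray = field(default_factory=_build_stack_table)
    hairpin_a: float = 5.4
    hairpin_b: float = 0.25
    bulge_a: float = 3.8
    bulge_b: float = 0.3
    internal_a: float = 4.0
    internal_b: float = 0.3
    ml_a: float = 3.4
    ml_b: float = 0.4
    ml_c: float = 0.4
    min_hairpin: int = 3
    max_interior: int = 30
    allow_lone_pairs: bool = False
    rt: float = RT_37

    def hairpin(self, u: int) -> float:
        if u < self.min_hairpin:
            return math.inf
        return self.hairpin_a + self.hairpin_b * (u - 3)

    def interior(self, left: int, right: int) -> float:
        """Bulge/internal penalty for left/right unpaired counts (not a stack)."""
        u = left + right
        if u == 0:
            raise ValueError("a 0x0 interior loop is a stack")
        if u > self.max_interior:
            return math.inf
        if left == 0 or right == 0:
            return self.bulge_a + self.bulge_b * (u - 1)
        return self.internal_a + self.internal_b * (u - 2)

    def multiloop(self, n_branches: int, n_unpaired: int) -> float:
        return self.ml_a + self.ml_b * (n_branches + 1) + self.ml_c * n_unpaired


DEFAULT_PARAMS = ReducedParams()


def structure_energy(
    seq: str, structure: SecondaryStructure, params: ReducedParams = DEFAULT_PARAMS
) -> float:
    """Free energy of an explicit structure under the reduced model.

    Scores by loop decomposition, independently of any folding recursion;
    returns ``inf`` for structures outside the model (non-canonical pairs,
    short hairpins, oversized interior loops, lone pairs when disallowed).
    """
    enc = [BASE_INDEX[c] for c in seq]
    if len(enc) != structure.length:
        raise ValueError("sequence/structure length mismatch")
    ptypes = {}
    for i, j in structure.pairs:
        t = pair_type(enc[i - 1], enc[j - 1])
        if t < 0:
            return math.inf
        ptypes[(i, j)] = t
    if not params.allow_lone_pairs and structure.has_lone_pairs():
        return math.inf

    energy = 0.0
    for loop in loop_decomposition(structure):
        kind = loop["kind"]
        if kind == "exterior":
            continue
        i, j = loop["closing"]
        if kind == "hairpin":
            energy += params.hairpin(j - i - 1)
        elif kind == "stack":
            (p, q) = loop["branches"][0]
            energy += params.stack[ptypes[(i, j)], ptypes[(p, q)]]
        elif kind in ("bulge", "internal"):
            (p, q) = loop["branches"][0]
            energy += params.interior(p - i - 1, j - q - 1)
        else:  # multibranch
            energy += params.multiloop(len(loop["branches"]), len(loop["unpaired"]))
        if not math.isfinite(energy):
            return math.inf
    return energy
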