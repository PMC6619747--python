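"""Thermodynamic folding contract: MFE, ensemble quantities, Boltzmann
sampling and loop probabilities, over pluggable backends.

Two engines satisfy the contract:

``vienna``
    ViennaRNA with full Turner-2004 parameters (quantitative kcal/mol).
``reference``
    Built-in reduced-parameter folder (dependency-free, verified exactly
    against brute-force enumeration on short sequences).

All quantities are at 37 degC.  Ensemble diversity (ED) is the expected
base-pair distance between two ensemble draws,
``ED = sum_{i<j} 2 p_ij (1 - p_ij)``; the centroid is the set of pairs with
``p_ij > 0.5`` (both conventions match the Vienna definitions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .alphabet import normalize_rna
from .fold_reference import FoldLengthError, ReferenceFold
from .fold_vienna import ViennaFold
from .structure import SecondaryStructure, loop_decomposition

__all__ = [
    "BACKENDS",
    "EnsembleSummary",
    "LoopSpec",
    "ensemble",
    "fold_mfe",
    "get_folder",
    "loop_probability",
    "sample_structures",
]

BACKENDS = ("vienna", "reference")


class UnknownBackend(ValueError):
    pass


def get_folder(seq: str, engine: str = "vienna"):
    """Instantiate the folding engine *engine* for *seq*."""
    if engine == "vienna":
        return ViennaFold(seq)
    if engine == "reference":
        return ReferenceFold(seq)
    raise UnknownBackend(f"unknown folding backend {engine!r}; choose from {BACKENDS}")


@dataclass(frozen=True)
class EnsembleSummary:
    """Partition-function summary of one sequence's Boltzmann ensemble."""

    dg_mfe: float
    ensemble_free_energy: float
    ed: float
    centroid: SecondaryStructure
    mfe_structure: SecondaryStructure
    bpp: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.ensemble_free_energy > self.dg_mfe + 1e-6:
            raise ValueError("ensemble free energy cannot exceed the MFE")


def fold_mfe(seq: str, engine: str = "vienna") -> tuple[SecondaryStructure, float]:
    """MFE structure and folding free energy (kcal/mol, 37 degC).

    Sequences that cannot form any canonical pair return the open chain
    with exactly 0.0.
    """
    folder = get_folder(seq, engine)
    structure, dg = folder.mfe()
    if not structure.pairs:
        dg = 0.0
    return structure, dg


def ensemble(seq: str, engine: str = "vienna", max_len: int | None = None) -> EnsembleSummary:
    """Ensemble summary: MFE, ensemble free energy, bpp matrix, ED, centroid."""
    seq = normalize_rna(seq)
    if max_len is not None and len(seq) > max_len:
        raise FoldLengthError(f"sequence of {len(seq)} nt exceeds the configured cap {max_len}")
    folder = get_folder(seq, engine)
    mfe_structure, dg = folder.mfe()
    if not mfe_structure.pairs:
        dg = 0.0
    bpp = folder.base_pair_probabilities()
    n = len(seq)
    iu, ju = np.triu_indices(n + 1, k=1)
    p = bpp[iu, ju]
    if hasattr(folder, "ensemble_diversity"):
        ed = folder.ensemble_diversity()
    else:
        ed = float(np.sum(2.0 * p * (1.0 - p)))
    centroid_pairs = frozenset(
        (int(i), int(j)) for i, j in zip(iu[p > 0.5], ju[p > 0.5]) if i >= 1
    )
    return EnsembleSummary(
        dg_mfe=dg,
        ensemble_free_energy=folder.ensemble_free_energy(),
        ed=float(ed),
        centroid=SecondaryStructure(length=n, pairs=centroid_pairs),
        mfe_structure=mfe_structure,
        bpp=bpp,
    )


def sample_structures(
    seq: str, n: int, seed: int, engine: str = "vienna"
) -> list[SecondaryStructure]:
    """Draw *n* structures from the Boltzmann ensemble (seeded, deterministic)."""
    if n < 1:
        raise ValueError("need at least one sample")
    folder = get_folder(seq, engine)
    rng = np.random.default_rng(seed)
    return folder.sample(n, rng)


@dataclass(frozen=True)
class LoopSpec:
    """A loop inside a secondary structure.

    ``closing_pairs`` lists the closing pair first, then any branch pairs
    (for multibranch/internal loops); ``unpaired`` lists the loop's unpaired
    positions.  A structure *contains* the loop when every closing pair is
    present and every listed position is unpaired.
    """

    loop_kind: str
    closing_pairs: tuple
    unpaired: tuple

    _KINDS = ("hairpin", "internal", "bulge", "multibranch")

    def __post_init__(self):
        if self.loop_kind not in self._KINDS:
            raise ValueError(f"loop_kind must be one of {self._KINDS}")
        if not self.closing_pairs:
            raise ValueError("a loop needs at least one closing pair")
        if self.loop_kind == "hairpin":
            if len(self.closing_pairs) != 1:
                raise ValueError("a hairpin loop has exactly one closing pair")
            (i, j) = self.closing_pairs[0]
            if set(self.unpaired) - set(range(i + 1, j)):
                raise ValueError("hairpin unpaired positions must lie inside the closing pair")
        if self.loop_kind in ("internal", "bulge") and len(self.closing_pairs) != 2:
            raise ValueError(f"an {self.loop_kind} loop has a closing and an interior pair")

    @classmethod
    def from_structure(cls, structure: SecondaryStructure, closing: tuple) -> "LoopSpec":
        """The loop of *structure* closed by pair *closing*."""
        for loop in loop_decomposition(structure):
            if loop["closing"] == tuple(closing):
                kind = loop["kind"]
                if kind == "stack":
                    kind = "internal"  # zero-unpaired limit; still checkable
                return cls(
                    loop_kind=kind,
                    closing_pairs=tuple([loop["closing"], *loop["branches"]]),
                    unpaired=tuple(loop["unpaired"]),
                )
        raise ValueError(f"no loop closed by {closing} in structure")

    def contained_in(self, structure: SecondaryStructure) -> bool:
        pairs = structure.pairs
        partner = structure.partner()
        return all(tuple(p) in pairs for p in self.closing_pairs) and not any(
            u in partner for u in self.unpaired
        )


def loop_probability(
    seq: str, loop: LoopSpec, n: int = 1000, seed: int = 0, engine: str = "vienna"
) -> tuple[float, float]:
    """Probability that *loop* forms, estimated by Boltzmann sampling.

    Returns ``(frequency, binomial standard error)``.  This is the
    sampling-based loop-probability estimator: the frequency with which the
    loop appears in an ensemble of sampled structures approximates its
    ensemble probability.
    """
    seq = normalize_rna(seq)
    nseq = len(seq)
    for i, j in loop.closing_pairs:
        if not (1 <= i < j <= nseq):
            raise ValueError(f"loop pair ({i},{j}) outside sequence of length {nseq}")
    samples = sample_structures(seq, n, seed, engine)
    k = sum(loop.contained_in(s) for s in samples)
    p = k / n
    se = math.sqrt(p * (1.0 - p) / n)
    return p, se
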