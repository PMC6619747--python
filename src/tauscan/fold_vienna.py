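"""Adapter to the ViennaRNA (Turner-2004) folding engine.

This is the full-parameter backend used for quantitative kcal/mol work; the
built-in reduced-parameter engine (:mod:`tauscan.fold_reference`) is the
oracle-verified fallback.  Imported lazily so the rest of the package works
without the bindings.
"""

from __future__ import annotations

import numpy as np

from .alphabet import normalize_rna
from .structure import SecondaryStructure


class ViennaNotAvailable(ImportError):
    pass


def _rna():
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ViennaNotAvailable(
            "the 'vienna' backend needs the ViennaRNA Python bindings (import RNA)"
        ) from exc
    return RNA


class ViennaFold:
    """Folding engine for one sequence via ViennaRNA at 37 degC, default
    model details (lonely pairs permitted, dangles as shipped)."""

    def __init__(self, seq: str):
        self.seq = normalize_rna(seq)
        self.n = len(self.seq)
        RNA = _rna()
        md = RNA.md()
        md.uniq_ML = 1  # needed for stochastic backtracking
        self._RNA = RNA
        self._fc = RNA.fold_compound(self.seq, md)
        self._mfe = None
        self._pf_done = False

    def mfe(self) -> tuple[SecondaryStructure, float]:
        if self._mfe is None:
            db, dg = self._fc.mfe()
            self._mfe = (SecondaryStructure.from_dot_bracket(db), float(dg))
        return self._mfe

    def _ensure_pf(self):
        if not self._pf_done:
            _, dg = self.mfe()
            self._fc.exp_params_rescale(dg)
            _, self._pf_energy = self._fc.pf()
            self._pf_done = True

    def ensemble_free_energy(self) -> float:
        self._ensure_pf()
        return float(self._pf_energy)

    def base_pair_probabilities(self) -> np.ndarray:
        self._ensure_pf()
        return np.array(self._fc.bpp())

    def ensemble_diversity(self) -> float:
        self._ensure_pf()
        return float(self._fc.mean_bp_distance())

    def sample(self, n_samples: int, rng: np.random.Generator) -> list[SecondaryStructure]:
        """Boltzmann sample; the Vienna RNG is seeded from *rng* so results
        are reproducible for a fixed seed."""
        self._ensure_pf()
        self._RNA.init_rand(int(rng.integers(0, 2**31 - 1)))
        return [
            SecondaryStructure.from_dot_bracket(db)
            for db in self._fc.pbacktrack(int(n_samples))
        ]
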