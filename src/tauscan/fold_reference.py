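"""Built-in reference folding engine over the reduced nearest-neighbor model.

Implements minimum-free-energy folding (Zuker-style dynamic programming with
deterministic traceback), the partition function with inside-outside
base-pair probabilities (McCaskill-style), and stochastic backtracking, all
over one shared grammar:

* ``H(i,j)`` — (i,j) paired and stacked on (i+1,j-1): helix continuation;
* ``C(i,j)`` — (i,j) paired and closing a hairpin, interior or multibranch
  loop (the innermost pair of its helix);
* ``M``/``M1`` — multibranch-loop regions (one-or-more components / exactly
  the last component plus trailing unpaired nucleotides).

Helix components entered from the exterior, an interior loop or a
multibranch loop are ``H`` when lone pairs are disallowed (the default:
every helix then has at least two stacked pairs) and ``H + C`` when they are
allowed.  The decomposition is unambiguous, so the same recursions serve
minimization, Boltzmann summation and sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import encode, normalize_rna, pair_type
from .energy_params import DEFAULT_PARAMS, ReducedParams
from .structure import SecondaryStructure

__all__ = ["ReferenceFold", "FoldLengthError"]

NEG_INF = -math.inf
INF = math.inf


class FoldLengthError(ValueError):
    """Sequence too long for the requested partition-function computation."""


@dataclass
class _Tables:
    """Inside DP tables (energies for MFE, Boltzmann weights for pf)."""

    H: np.ndarray
    C: np.ndarray
    M: np.ndarray
    M1: np.ndarray
    ext: np.ndarray  # exterior prefix


class ReferenceFold:
    """Folding engine for one sequence under :class:`ReducedParams`.

    Builds the MFE tables lazily on first use and the partition-function
    tables on first ensemble query.  Lengths beyond ``max_pf_len`` raise
    :class:`FoldLengthError` for partition-function work (unscaled Boltzmann
    weights overflow float64 well before memory becomes a concern).
    """

    def __init__(self, seq: str, params: ReducedParams = DEFAULT_PARAMS, max_pf_len: int = 300):
        self.seq = normalize_rna(seq)
        self.params = params
        self.max_pf_len = max_pf_len
        self.n = len(self.seq)
        enc = encode(self.seq)
        n = self.n
        self._pt = np.full((n + 2, n + 2), -1, dtype=int)
        for i in range(1, n + 1):
            for j in range(i + params.min_hairpin + 1, n + 1):
                self._pt[i, j] = pair_type(enc[i - 1], enc[j - 1])
        self._mfe_tables: _Tables | None = None
        self._pf_tables: _Tables | None = None
        self._bpp: np.ndarray | None = None

    # ------------------------------------------------------------------
    # MFE
    # ------------------------------------------------------------------
    def mfe(self) -> tuple[SecondaryStructure, float]:
        """Minimum free energy structure and its energy (kcal/mol)."""
        t = self._fill_mfe()
        energy = t.ext[self.n]
        pairs = self._traceback(t)
        dg = 0.0 if not pairs else float(energy)
        return SecondaryStructure(length=self.n, pairs=frozenset(pairs)), round(dg, 10)

    def _component(self, t: _Tables, i: int, j: int) -> float:
        """Energy/weight of a helix component starting with pair (i,j)."""
        if self.params.allow_lone_pairs:
            return min(t.H[i, j], t.C[i, j])
        return t.H[i, j]

    def _fill_mfe(self) -> _Tables:
        if self._mfe_tables is not None:
            return self._mfe_tables
        n, p = self.n, self.params
        H = np.full((n + 2, n + 2), INF)
        C = np.full((n + 2, n + 2), INF)
        M = np.full((n + 2, n + 2), INF)
        M1 = np.full((n + 2, n + 2), INF)
        t = _Tables(H, C, M, M1, np.zeros(n + 1))
        comp = (lambda i, j: min(H[i, j], C[i, j])) if p.allow_lone_pairs else (
            lambda i, j: H[i, j]
        )

        for d in range(p.min_hairpin + 1, n):
            for i in range(1, n - d + 1):
                j = i + d
                if self._pt[i, j] >= 0:
                    # C: closing a loop
                    best = p.hairpin(j - i - 1)
                    for pp in range(i + 1, j - 1):
                        left = pp - i - 1
                        if left > p.max_interior:
                            break
                        for q in range(j - 1, pp + p.min_hairpin, -1):
                            right = j - q - 1
                            if left + right > p.max_interior:
                                break
                            if left == 0 and right == 0:
                                continue  # stack: handled by H
                            if self._pt[pp, q] >= 0:
                                cand = p.interior(left, right) + comp(pp, q)
                                if cand < best:
                                    best = cand
                    # multibranch closing
                    base = p.ml_a + p.ml_b
                    for k in range(i + 2, j - 1):
                        cand = base + M[i + 1, k - 1] + M1[k, j - 1]
                        if cand < best:
                            best = cand
                    C[i, j] = best
                    # H: helix continuation
                    if self._pt[i + 1, j - 1] >= 0:
                        inner = min(H[i + 1, j - 1], C[i + 1, j - 1])
                        if inner < INF:
                            H[i, j] = p.stack[self._pt[i, j], self._pt[i + 1, j - 1]] + inner
                # M1: last multiloop component starting at i, ending <= j
                cb = comp(i, j) + p.ml_b if self._pt[i, j] >= 0 else INF
                M1[i, j] = min(cb, M1[i, j - 1] + p.ml_c)
                # M: >= 1 component in [i, j]
                best_m = M[i, j - 1] + p.ml_c
                for k in range(i, j):
                    cbk = comp(k, j)
                    if cbk < INF:
                        cbk += p.ml_b
                        lead = p.ml_c * (k - i)
                        if lead + cbk < best_m:
                            best_m = lead + cbk
                        if M[i, k - 1] + cbk < best_m:
                            best_m = M[i, k - 1] + cbk
                M[i, j] = best_m

        ext = t.ext
        for j in range(1, n + 1):
            best = ext[j - 1]
            for i in range(1, j):
                cand = ext[i - 1] + comp(i, j)
                if cand < best:
                    best = cand
            ext[j] = best
        self._mfe_tables = t
        return t

    def _traceback(self, t: _Tables) -> set[tuple[int, int]]:
        """Deterministic traceback: candidates are examined in a fixed order
        (unpaired first, then 5'-most alternatives) and the first optimum is
        taken, so ties always resolve the same way."""
        p = self.params
        pairs: set[tuple[int, int]] = set()
        eps = 1e-9
        comp = self._component
        stack: list[tuple[str, int, int]] = []

        j = self.n
        while j > 0:
            if t.ext[j] >= t.ext[j - 1] - eps and abs(t.ext[j] - t.ext[j - 1]) <= eps:
                j -= 1
                continue
            hit = None
            for i in range(1, j):
                if abs(t.ext[i - 1] + comp(t, i, j) - t.ext[j]) <= eps:
                    hit = i
                    break
            assert hit is not None, "exterior traceback failed"
            stack.append(("CP", hit, j))
            j = hit - 1

        while stack:
            state, i, j = stack.pop()
            if state == "CP":
                if not p.allow_lone_pairs or t.H[i, j] <= t.C[i, j]:
                    stack.append(("H", i, j))
                else:
                    stack.append(("C", i, j))
            elif state == "H":
                pairs.add((i, j))
                inner_h, inner_c = t.H[i + 1, j - 1], t.C[i + 1, j - 1]
                s = p.stack[self._pt[i, j], self._pt[i + 1, j - 1]]
                if abs(s + inner_h - t.H[i, j]) <= eps:
                    stack.append(("H", i + 1, j - 1))
                else:
                    assert abs(s + inner_c - t.H[i, j]) <= eps
                    stack.append(("C", i + 1, j - 1))
            elif state == "C":
                pairs.add((i, j))
                e = t.C[i, j]
                if abs(p.hairpin(j - i - 1) - e) <= eps:
                    continue
                found = False
                for pp in range(i + 1, j - 1):
                    left = pp - i - 1
                    if left > p.max_interior or found:
                        break
                    for q in range(j - 1, pp + p.min_hairpin, -1):
                        right = j - q - 1
                        if left + right > p.max_interior:
                            break
                        if (left or right) and self._pt[pp, q] >= 0:
                            if abs(p.interior(left, right) + comp(t, pp, q) - e) <= eps:
                                stack.append(("CP", pp, q))
                                found = True
                                break
                if found:
                    continue
                base = p.ml_a + p.ml_b
                for k in range(i + 2, j - 1):
                    if abs(base + t.M[i + 1, k - 1] + t.M1[k, j - 1] - e) <= eps:
                        stack.append(("M", i + 1, k - 1))
                        stack.append(("M1", k, j - 1))
                        found = True
                        break
                assert found, "C traceback failed"
            elif state == "M1":
                e = t.M1[i, j]
                cb = comp(t, i, j) + p.ml_b if self._pt[i, j] >= 0 else INF
                if abs(cb - e) <= eps:
                    stack.append(("CP", i, j))
                else:
                    stack.append(("M1", i, j - 1))
            else:  # M
                e = t.M[i, j]
                if abs(t.M[i, j - 1] + p.ml_c - e) <= eps:
                    stack.append(("M", i, j - 1))
                    continue
                found = False
                for k in range(i, j):
                    cbk = comp(t, k, j)
                    if cbk >= INF:
                        continue
                    cbk += p.ml_b
                    if abs(p.ml_c * (k - i) + cbk - e) <= eps:
                        stack.append(("CP", k, j))
                        found = True
                        break
                    if abs(t.M[i, k - 1] + cbk - e) <= eps:
                        stack.append(("M", i, k - 1))
                        stack.append(("CP", k, j))
                        found = True
                        break
                assert found, "M traceback failed"
        return pairs

    # ------------------------------------------------------------------
    # Partition function
    # ------------------------------------------------------------------
    def _w(self, e: float) -> float:
        return math.exp(-e / self.params.rt) if math.isfinite(e) else 0.0

    def _fill_pf(self) -> _Tables:
        if self._pf_tables is not None:
            return self._pf_tables
        if self.n > self.max_pf_len:
            raise FoldLengthError(
                f"partition function limited to {self.max_pf_len} nt "
                f"(got {self.n}); use the full-parameter backend for long sequences"
            )
        n, p = self.n, self.params
        rt = p.rt
        wb = math.exp(-p.ml_b / rt)
        wc = math.exp(-p.ml_c / rt)
        wcl = math.exp(-(p.ml_a + p.ml_b) / rt)
        H = np.zeros((n + 2, n + 2))
        C = np.zeros((n + 2, n + 2))
        M = np.zeros((n + 2, n + 2))
        M1 = np.zeros((n + 2, n + 2))
        comp = (lambda i, j: H[i, j] + C[i, j]) if p.allow_lone_pairs else (
            lambda i, j: H[i, j]
        )

        for d in range(p.min_hairpin + 1, n):
            for i in range(1, n - d + 1):
                j = i + d
                if self._pt[i, j] >= 0:
                    z = self._w(p.hairpin(j - i - 1))
                    for pp in range(i + 1, j - 1):
                        left = pp - i - 1
                        if left > p.max_interior:
                            break
                        for q in range(j - 1, pp + p.min_hairpin, -1):
                            right = j - q - 1
                            if left + right > p.max_interior:
                                break
                            if (left or right) and self._pt[pp, q] >= 0:
                                z += self._w(p.interior(left, right)) * comp(pp, q)
                    for k in range(i + 2, j - 1):
                        z += wcl * M[i + 1, k - 1] * M1[k, j - 1]
                    C[i, j] = z
                    if self._pt[i + 1, j - 1] >= 0:
                        s = p.stack[self._pt[i, j], self._pt[i + 1, j - 1]]
                        H[i, j] = self._w(s) * (H[i + 1, j - 1] + C[i + 1, j - 1])
                M1[i, j] = comp(i, j) * wb + M1[i, j - 1] * wc
                zm = M[i, j - 1] * wc
                for k in range(i, j):
                    cbk = comp(k, j) * wb
                    if cbk:
                        zm += (wc ** (k - i)) * cbk + M[i, k - 1] * cbk
                M[i, j] = zm

        ext = np.zeros(n + 2)
        ext[0] = 1.0
        for j in range(1, n + 1):
            z = ext[j - 1]
            for i in range(1, j):
                z += ext[i - 1] * comp(i, j)
            ext[j] = z
        t = _Tables(H, C, M, M1, ext)
        self._pf_tables = t
        return t

    @property
    def partition(self) -> float:
        return float(self._fill_pf().ext[self.n])

    def ensemble_free_energy(self) -> float:
        return -self.params.rt * math.log(self.partition)

    def base_pair_probabilities(self) -> np.ndarray:
        """(n+1)x(n+1) array of pair probabilities (1-based, upper triangle)."""
        if self._bpp is not None:
            return self._bpp
        t = self._fill_pf()
        n, p = self.n, self.params
        rt = p.rt
        wb = math.exp(-p.ml_b / rt)
        wc = math.exp(-p.ml_c / rt)
        wcl = math.exp(-(p.ml_a + p.ml_b) / rt)
        Z = t.ext[n]

        # exterior suffix partition
        suf = np.zeros(n + 3)
        suf[n + 1] = 1.0
        suf[n + 2] = 1.0

        def comp(i, j):
            if p.allow_lone_pairs:
                return t.H[i, j] + t.C[i, j]
            return t.H[i, j]

        for i in range(n, 0, -1):
            z = suf[i + 1]
            for j in range(i + 1, n + 1):
                z += comp(i, j) * suf[j + 1]
            suf[i] = z

        Oh = np.zeros((n + 2, n + 2))
        Oc = np.zeros((n + 2, n + 2))
        Om = np.zeros((n + 2, n + 2))
        Om1 = np.zeros((n + 2, n + 2))

        def add_comp_outer(i, j, w):
            """Credit outer weight w to the component nonterminals at (i,j)."""
            Oh[i, j] += w
            if p.allow_lone_pairs:
                Oc[i, j] += w

        # exterior occurrences
        for i in range(1, n + 1):
            for j in range(i + p.min_hairpin + 1, n + 1):
                if self._pt[i, j] >= 0:
                    add_comp_outer(i, j, t.ext[i - 1] * suf[j + 1])

        for d in range(n - 1, p.min_hairpin, -1):
            # pass A: emit from M and M1 at this span (targets include
            # same-span component nonterminals)
            for i in range(1, n - d + 1):
                j = i + d
                if Om1[i, j]:
                    if self._pt[i, j] >= 0:
                        add_comp_outer(i, j, Om1[i, j] * wb)
                    Om1[i, j - 1] += Om1[i, j] * wc
                if Om[i, j]:
                    Om[i, j - 1] += Om[i, j] * wc
                    for k in range(i, j):
                        cb = comp(k, j)
                        if self._pt[k, j] >= 0:
                            w1 = Om[i, j] * (wc ** (k - i)) * wb
                            w2 = Om[i, j] * t.M[i, k - 1] * wb
                            add_comp_outer(k, j, w1 + w2)
                        if cb:
                            Om[i, k - 1] += Om[i, j] * cb * wb
            # pass B: emit from H and C at this span (targets strictly smaller)
            for i in range(1, n - d + 1):
                j = i + d
                if self._pt[i, j] < 0:
                    continue
                if Oh[i, j] and self._pt[i + 1, j - 1] >= 0:
                    s = self._w(p.stack[self._pt[i, j], self._pt[i + 1, j - 1]])
                    Oh[i + 1, j - 1] += Oh[i, j] * s
                    Oc[i + 1, j - 1] += Oh[i, j] * s
                if Oc[i, j]:
                    for pp in range(i + 1, j - 1):
                        left = pp - i - 1
                        if left > p.max_interior:
                            break
                        for q in range(j - 1, pp + p.min_hairpin, -1):
                            right = j - q - 1
                            if left + right > p.max_interior:
                                break
                            if (left or right) and self._pt[pp, q] >= 0:
                                add_comp_outer(pp, q, Oc[i, j] * self._w(p.interior(left, right)))
                    for k in range(i + 2, j - 1):
                        w = Oc[i, j] * wcl
                        if t.M1[k, j - 1]:
                            Om[i + 1, k - 1] += w * t.M1[k, j - 1]
                        if t.M[i + 1, k - 1]:
                            Om1[k, j - 1] += w * t.M[i + 1, k - 1]

        bpp = np.zeros((n + 1, n + 1))
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if self._pt[i, j] >= 0:
                    bpp[i, j] = (Oh[i, j] * t.H[i, j] + Oc[i, j] * t.C[i, j]) / Z
        self._bpp = bpp
        return bpp

    # ------------------------------------------------------------------
    # Stochastic backtracking
    # ------------------------------------------------------------------
    def sample(self, n_samples: int, rng: np.random.Generator) -> list[SecondaryStructure]:
        """Draw structures from the Boltzmann distribution."""
        t = self._fill_pf()
        return [self._sample_one(t, rng) for _ in range(n_samples)]

    def _sample_one(self, t: _Tables, rng: np.random.Generator) -> SecondaryStructure:
        p = self.params
        rt = p.rt
        wb = math.exp(-p.ml_b / rt)
        wc = math.exp(-p.ml_c / rt)
        wcl = math.exp(-(p.ml_a + p.ml_b) / rt)
        pairs: set[tuple[int, int]] = set()

        def comp(i, j):
            if p.allow_lone_pairs:
                return t.H[i, j] + t.C[i, j]
            return t.H[i, j]

        def pick(weights):
            total = sum(w for _, w in weights)
            x = rng.random() * total
            acc = 0.0
            for item, w in weights:
                acc += w
                if x <= acc:
                    return item
            return weights[-1][0]

        stack: list[tuple[str, int, int]] = []
        j = self.n
        while j > 0:
            opts = [(0, t.ext[j - 1])]
            opts += [(i, t.ext[i - 1] * comp(i, j)) for i in range(1, j) if comp(i, j)]
            i = pick(opts)
            if i == 0:
                j -= 1
            else:
                stack.append(("CP", i, j))
                j = i - 1

        while stack:
            state, i, j = stack.pop()
            if state == "CP":
                if p.allow_lone_pairs:
                    state = pick([("H", t.H[i, j]), ("C", t.C[i, j])])
                else:
                    state = "H"
            if state == "H":
                pairs.add((i, j))
                stack.append((pick([("H", t.H[i + 1, j - 1]), ("C", t.C[i + 1, j - 1])]),
                              i + 1, j - 1))
            elif state == "C":
                pairs.add((i, j))
                opts = [(("hp", 0, 0), self._w(p.hairpin(j - i - 1)))]
                for pp in range(i + 1, j - 1):
                    left = pp - i - 1
                    if left > p.max_interior:
                        break
                    for q in range(j - 1, pp + p.min_hairpin, -1):
                        right = j - q - 1
                        if left + right > p.max_interior:
                            break
                        if (left or right) and self._pt[pp, q] >= 0 and comp(pp, q):
                            opts.append((("il", pp, q),
                                         self._w(p.interior(left, right)) * comp(pp, q)))
                for k in range(i + 2, j - 1):
                    w = wcl * t.M[i + 1, k - 1] * t.M1[k, j - 1]
                    if w:
                        opts.append((("ml", k, 0), w))
                kind, a, b = pick(opts)
                if kind == "il":
                    stack.append(("CP", a, b))
                elif kind == "ml":
                    stack.append(("M", i + 1, a - 1))
                    stack.append(("M1", a, j - 1))
            elif state == "M1":
                cb = comp(i, j) * wb
                tail = t.M1[i, j - 1] * wc
                if pick([("comp", cb), ("tail", tail)]) == "comp":
                    stack.append(("CP", i, j))
                else:
                    stack.append(("M1", i, j - 1))
            else:  # M
                opts = [(("un", 0), t.M[i, j - 1] * wc)]
                for k in range(i, j):
                    cb = comp(k, j) * wb
                    if cb:
                        opts.append((("one", k), (wc ** (k - i)) * cb))
                        if t.M[i, k - 1]:
                            opts.append((("more", k), t.M[i, k - 1] * cb))
                kind, k = pick(opts)
                if kind == "un":
                    stack.append(("M", i, j - 1))
                elif kind == "one":
                    stack.append(("CP", k, j))
                else:
                    stack.append(("M", i, k - 1))
                    stack.append(("CP", k, j))
        return SecondaryStructure(length=self.n, pairs=frozenset(pairs))
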