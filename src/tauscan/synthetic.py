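"""Synthetic input generator with ground truth.

Emulates the study's input classes so every pipeline stage can be tested
without downloads: multi-exon genes with introns, thermodynamically stable
hairpins embedded at splice junctions in compositionally matched random
background, and homolog families derived from a reference sequence by
compensatory (pair-preserving) and neutral substitutions at stated rates.
All generators are deterministic under their seed, and each emits a
:class:`SyntheticTruth` that fully determines the expected test outcome.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .alphabet import PAIR_TYPES, normalize_rna
from .conservation import AlignedFamily
from .seq_model import Exon, GeneModel
from .structure import SecondaryStructure

__all__ = [
    "SyntheticTruth",
    "embed_hairpin",
    "make_background",
    "make_family",
    "make_gene",
    "mapt_like_composition",
]

BASES = np.array(list("ACGU"))

#: uniform background
UNIFORM = (0.25, 0.25, 0.25, 0.25)


def mapt_like_composition(gc: float = 0.55) -> tuple:
    """GC-rich background preset (junction hairpins in tau are GC-rich)."""
    at = (1.0 - gc) / 2.0
    return (at, gc / 2.0, gc / 2.0, at)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside generated data.

    ``motifs``: list of dicts with keys ``start``, ``end`` (absolute,
    1-based) and ``pairs`` (designed base pairs, absolute coordinates).
    ``family``: per-row dicts of compensatory/neutral substitution positions.
    ``params``: the generation parameters, seed included.
    """

    params: dict = field(default_factory=dict)
    motifs: list = field(default_factory=list)
    family: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def make_background(length: int, composition=UNIFORM, seed: int = 0) -> str:
    """I.i.d. random RNA of the given base composition (A, C, G, U order)."""
    comp = np.asarray(composition, dtype=float)
    if abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(BASES, size=length, p=comp))


def _design_hairpin(stem_len: int, loop_len: int, gc_fraction: float, rng) -> tuple[str, list]:
    """A stem-loop sequence and its intended pairs (local coordinates)."""
    left, right = [], []
    for _ in range(stem_len):
        if rng.random() < gc_fraction:
            a, b = ("G", "C") if rng.random() < 0.5 else ("C", "G")
        else:
            a, b = ("A", "U") if rng.random() < 0.5 else ("U", "A")
        left.append(a)
        right.append(b)
    loop = "".join(rng.choice(["A", "A", "C"]) for _ in range(loop_len))
    seq = "".join(left) + loop + "".join(reversed(right))
    total = 2 * stem_len + loop_len
    pairs = [(k + 1, total - k) for k in range(stem_len)]
    return seq, pairs


def embed_hairpin(
    background: str,
    stem_len: int,
    loop_len: int = 4,
    gc_fraction: float = 0.8,
    position: int = 1,
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Overwrite part of *background* with a designed stem-loop.

    The insert replaces ``2*stem_len + loop_len`` nucleotides starting at
    1-based *position* (in place, so coordinates elsewhere are unchanged).
    ``stem_len = 0`` leaves the sequence untouched.
    """
    background = normalize_rna(background)
    truth = SyntheticTruth(
        params={
            "stem_len": stem_len, "loop_len": loop_len,
            "gc_fraction": gc_fraction, "position": position, "seed": seed,
        }
    )
    if stem_len == 0:
        return background, truth
    rng = np.random.default_rng(seed)
    seq, local_pairs = _design_hairpin(stem_len, loop_len, gc_fraction, rng)
    end = position + len(seq) - 1
    if position < 1 or end > len(background):
        raise ValueError(f"insert {position}..{end} does not fit in background")
    mutated = background[: position - 1] + seq + background[end:]
    truth.motifs.append(
        {
            "start": position,
            "end": end,
            "pairs": [(position + i - 1, position + j - 1) for i, j in local_pairs],
        }
    )
    return mutated, truth


def make_gene(
    n_exons: int,
    exon_len: tuple[int, int] = (80, 150),
    intron_len: tuple[int, int] = (150, 400),
    junction_motifs: dict | None = None,
    composition=UNIFORM,
    seed: int = 0,
    gene_id: str = "synthetic",
) -> tuple[GeneModel, SyntheticTruth]:
    """Random multi-exon gene, optionally with hairpins straddling chosen
    5' splice sites.

    *junction_motifs* maps exon index (1-based; the motif straddles that
    exon's downstream junction) to hairpin parameters
    ``{"stem_len": ..., "loop_len": ..., "gc_fraction": ...}``.
    """
    rng = np.random.default_rng(seed)
    junction_motifs = junction_motifs or {}
    exons, pieces = [], []
    pos = 0
    boundaries = {}
    for k in range(n_exons):
        elen = int(rng.integers(exon_len[0], exon_len[1] + 1))
        exons.append(Exon(f"E{k + 1}", pos + 1, pos + elen))
        pieces.append(make_background(elen, composition, seed=int(rng.integers(2**31))))
        pos += elen
        if k + 1 < n_exons:
            boundaries[k + 1] = pos  # 5' splice site after exon k+1
            ilen = int(rng.integers(intron_len[0], intron_len[1] + 1))
            pieces.append(make_background(ilen, composition, seed=int(rng.integers(2**31))))
            pos += ilen
    sequence = "".join(pieces)
    truth = SyntheticTruth(
        params={
            "n_exons": n_exons, "exon_len": exon_len, "intron_len": intron_len,
            "composition": tuple(composition), "seed": seed,
        }
    )
    for exon_index, spec in sorted(junction_motifs.items()):
        b = boundaries[exon_index]
        stem = spec.get("stem_len", 12)
        loop = spec.get("loop_len", 4)
        total = 2 * stem + loop
        start = b - total // 2 + 1  # straddles the splice site
        sequence, t = embed_hairpin(
            sequence, stem, loop, spec.get("gc_fraction", 0.8),
            position=start, seed=int(rng.integers(2**31)),
        )
        truth.motifs.extend(t.motifs)
    gene = GeneModel(gene_id=gene_id, sequence=sequence, exons=tuple(exons))
    return gene, truth


def make_family(
    seq: str,
    structure: SecondaryStructure,
    n_species: int,
    compensatory_rate: float = 0.2,
    neutral_rate: float = 0.1,
    seed: int = 0,
) -> tuple[AlignedFamily, SyntheticTruth]:
    """Gapless homolog family evolved from *seq* under *structure*.

    Per species: each consensus pair is replaced (with probability
    ``compensatory_rate``) by one of the 5 alternative canonical pairs,
    keeping it paired; each unpaired position mutates to a random different
    base with probability ``neutral_rate``.  The query is row 0.
    """
    seq = normalize_rna(seq)
    if structure.length != len(seq):
        raise ValueError("structure length does not match sequence")
    rng = np.random.default_rng(seed)
    all_pairs = sorted(structure.pairs)
    paired_positions = {p for ij in all_pairs for p in ij}
    unpaired = [k for k in range(1, len(seq) + 1) if k not in paired_positions]
    pair_alphabet = list(PAIR_TYPES)  # the 6 canonical pairs

    truth = SyntheticTruth(
        params={
            "n_species": n_species, "compensatory_rate": compensatory_rate,
            "neutral_rate": neutral_rate, "seed": seed, "n_pairs": len(all_pairs),
        }
    )
    rows = [("query", seq)]
    for s in range(n_species):
        chars = list(seq)
        comp_hits, neutral_hits = [], []
        for i, j in all_pairs:
            if rng.random() < compensatory_rate:
                current = (chars[i - 1], chars[j - 1])
                options = [p for p in pair_alphabet if p != current]
                a, b = options[int(rng.integers(len(options)))]
                chars[i - 1], chars[j - 1] = a, b
                comp_hits.append((i, j))
        for k in unpaired:
            if rng.random() < neutral_rate:
                alt = [c for c in "ACGU" if c != chars[k - 1]]
                chars[k - 1] = alt[int(rng.integers(3))]
                neutral_hits.append(k)
        rid = f"sp{s + 1}"
        rows.append((rid, "".join(chars)))
        truth.family.append(
            {"id": rid, "compensatory": comp_hits, "neutral": neutral_hits}
        )
    return AlignedFamily(rows=tuple(rows), query_index=0), truth
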