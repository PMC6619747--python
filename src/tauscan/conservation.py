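"""Homolog filtering, alignment handling and base-pair conservation scoring.

The consensus structure is the query's predicted structure mapped onto
alignment columns (no consensus refolding); conservation of each mapped
pair is the percentage of alignment rows whose two column characters still
form a canonical pair.  A simplified covariation counter reports pairs at
which two or more non-query species carry substitutions while retaining
canonical pairing.  Alignments are ingested as aligned FASTA or Stockholm;
a small built-in pairwise aligner (match +1 / mismatch -1 / gap -2, stacked
onto query coordinates) exists so tests need no external alignment tool.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

from Bio import Align, SeqIO

from .alphabet import can_pair, normalize_rna
from .structure import SecondaryStructure

__all__ = [
    "AlignedFamily",
    "ConservationReport",
    "HomologSet",
    "align_family",
    "apsi",
    "bp_conservation",
    "covariation_count",
    "filter_homologs",
    "map_structure",
    "read_alignment",
    "write_stockholm",
]

GAP = "-"


@dataclass(frozen=True)
class HomologSet:
    """A query sequence plus homologous hits (e.g. exported BLAST matches)."""

    query: str
    hits: tuple  # of (id, sequence, note)

    def __post_init__(self):
        object.__setattr__(self, "query", normalize_rna(self.query))
        norm = tuple((hid, normalize_rna(s), note) for hid, s, note in self.hits)
        object.__setattr__(self, "hits", norm)
        if not self.query:
            raise ValueError("query sequence is empty")


@dataclass(frozen=True)
class AlignedFamily:
    """A multiple alignment with a designated query row (row 0 by default)."""

    rows: tuple  # of (id, gapped sequence over {A,C,G,U,-})
    query_index: int = 0

    def __post_init__(self):
        rows = tuple((rid, s.upper().replace("T", "U")) for rid, s in self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise ValueError("alignment has no rows")
        width = len(rows[0][1])
        for rid, s in rows:
            if len(s) != width:
                raise ValueError(f"row {rid!r} has length {len(s)} != {width}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index][1]

    def degapped_query(self) -> str:
        return self.query_row.replace(GAP, "")


@dataclass(frozen=True)
class ConservationReport:
    """Canonical-pair conservation of a consensus structure over a family."""

    pairs: tuple  # of (col_i, col_j)
    per_pair_pct: tuple  # same order as pairs, percent of rows canonical
    average_pct: float | None  # mean over pairs (None when no pairs)
    average_pct_cells: float | None  # mean over row x pair cells
    n_species: int  # rows excluding the query
    apsi: float | None

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"col_i": [p[0] for p in self.pairs],
             "col_j": [p[1] for p in self.pairs],
             "pct_canonical": self.per_pair_pct}
        )


# ----------------------------------------------------------------------
def filter_homologs(hs: HomologSet, min_length_fraction: float = 0.8) -> HomologSet:
    """Drop exact duplicate hit sequences and hits shorter than
    ``min_length_fraction`` of the query (a hit of exactly that length is
    kept: only strictly shorter fragments are excluded)."""
    cutoff = min_length_fraction * len(hs.query)
    seen: set[str] = set()
    kept = []
    for hid, seq, note in hs.hits:
        if len(seq) < cutoff or seq in seen:
            continue
        seen.add(seq)
        kept.append((hid, seq, note))
    return HomologSet(query=hs.query, hits=tuple(kept))


def map_structure(alignment: AlignedFamily, query_structure: SecondaryStructure) -> tuple:
    """Map query-sequence pair indices to alignment-column pairs."""
    q = alignment.query_row
    degapped = q.replace(GAP, "")
    if query_structure.length != len(degapped):
        raise ValueError(
            f"structure length {query_structure.length} != degapped query {len(degapped)}"
        )
    col_of = {}
    k = 0
    for col, c in enumerate(q, start=1):
        if c != GAP:
            k += 1
            col_of[k] = col
    return tuple(sorted((col_of[i], col_of[j]) for i, j in query_structure.pairs))


def bp_conservation(alignment: AlignedFamily, pairs) -> ConservationReport:
    """Percent of rows forming a canonical pair at each consensus pair.

    A gap in either column counts as non-canonical.  ``average_pct`` is the
    mean of the per-pair percentages; ``average_pct_cells`` averages over
    all row x pair cells instead (both conventions are reported).
    """
    pairs = tuple(tuple(p) for p in pairs)
    ncol = alignment.n_columns
    for i, j in pairs:
        if not (1 <= i < j <= ncol):
            raise ValueError(f"pair columns ({i},{j}) outside alignment width {ncol}")
    per_pair = []
    total_canonical = 0
    for i, j in pairs:
        ok = sum(
            1 for _, row in alignment.rows if can_pair_or_gap(row[i - 1], row[j - 1])
        )
        per_pair.append(100.0 * ok / alignment.n_rows)
        total_canonical += ok
    n_cells = len(pairs) * alignment.n_rows
    return ConservationReport(
        pairs=pairs,
        per_pair_pct=tuple(per_pair),
        average_pct=(sum(per_pair) / len(per_pair)) if per_pair else None,
        average_pct_cells=(100.0 * total_canonical / n_cells) if n_cells else None,
        n_species=alignment.n_rows - 1,
        apsi=apsi(alignment) if alignment.n_rows >= 2 else None,
    )


def can_pair_or_gap(a: str, b: str) -> bool:
    if a == GAP or b == GAP:
        return False
    return can_pair(a, b)


def apsi(alignment: AlignedFamily) -> float:
    """Average pairwise sequence identity, percent.

    For each row pair: identical residue columns divided by columns where
    at least one of the two rows has a residue (double-gap columns are
    excluded from the denominator).
    """
    if alignment.n_rows < 2:
        raise ValueError("APSI needs at least 2 rows")
    idents = []
    for (_, a), (_, b) in itertools.combinations(alignment.rows, 2):
        num = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
        den = sum(1 for x, y in zip(a, b) if x != GAP or y != GAP)
        idents.append(100.0 * num / den if den else 100.0)
    return sum(idents) / len(idents)


def covariation_count(alignment: AlignedFamily, pairs) -> tuple[int, dict]:
    """Simplified covariation counter.

    A consensus pair covaries when two or more non-query rows differ from
    the query at one or both paired columns while still forming a canonical
    pair.  Returns the total count and, per pair, the ids of supporting
    rows.  (No covariation statistic or E-value is computed here.)
    """
    q = alignment.query_row
    support: dict[tuple, list] = {}
    count = 0
    for i, j in (tuple(p) for p in pairs):
        rows = []
        for k, (rid, row) in enumerate(alignment.rows):
            if k == alignment.query_index:
                continue
            a, b = row[i - 1], row[j - 1]
            if (a, b) != (q[i - 1], q[j - 1]) and can_pair_or_gap(a, b):
                rows.append(rid)
        support[(i, j)] = rows
        if len(rows) >= 2:
            count += 1
    return count, support


# ----------------------------------------------------------------------
# Alignment construction / IO
# ----------------------------------------------------------------------
def align_family(
    hs: HomologSet, query_id: str = "query", match: float = 1.0,
    mismatch: float = -1.0, gap: float = -2.0,
) -> AlignedFamily:
    """Built-in test-mode aligner: globally align each hit to the query and
    stack the pairwise alignments onto query coordinates.

    Insertions relative to the query open shared gap columns sized by the
    longest insertion at that query position.  Supply a pre-computed
    alignment (MAFFT etc.) via :func:`read_alignment` for real analyses.
    """
    if not hs.hits:
        raise ValueError("need at least one hit to build a family")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap

    q = hs.query
    pairwise = []
    for hid, seq, _ in hs.hits:
        aln = aligner.align(q, seq)[0]
        gq, gh = str(aln[0]), str(aln[1])
        pairwise.append((hid, gq, gh))

    # maximum insertion length after each query position (0 = before start)
    ins = [0] * (len(q) + 1)
    for _, gq, _ in pairwise:
        k = 0
        run = 0
        for c in gq:
            if c == GAP:
                run += 1
            else:
                ins[k] = max(ins[k], run)
                run = 0
                k += 1
        ins[len(q)] = max(ins[len(q)], run)

    def expand(gq: str, gh: str) -> str:
        out = []
        k = 0
        run_chars: list[str] = []
        for cq, ch in zip(gq, gh):
            if cq == GAP:
                run_chars.append(ch)
            else:
                out.append(run_chars + [GAP] * (ins[k] - len(run_chars)))
                run_chars = []
                out.append([ch])
                k += 1
        out.append(run_chars + [GAP] * (ins[len(q)] - len(run_chars)))
        return "".join(itertools.chain.from_iterable(out))

    rows = [(query_id, expand(q, q))]
    for hid, gq, gh in pairwise:
        # re-expand this hit against the merged gap pattern
        out = []
        k = 0
        run: list[str] = []
        for cq, ch in zip(gq, gh):
            if cq == GAP:
                run.append(ch)
            else:
                out.append("".join(run) + GAP * (ins[k] - len(run)))
                run = []
                out.append(ch)
                k += 1
        out.append("".join(run) + GAP * (ins[len(q)] - len(run)))
        rows.append((hid, "".join(out)))
    return AlignedFamily(rows=tuple(rows), query_index=0)


def read_alignment(path, query_id: str | None = None) -> AlignedFamily:
    """Read an aligned FASTA or Stockholm file into an AlignedFamily."""
    path = Path(path)
    fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") else "fasta"
    rows = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), fmt)]
    qi = 0
    if query_id is not None:
        qi = [rid for rid, _ in rows].index(query_id)
    return AlignedFamily(rows=tuple(rows), query_index=qi)


def write_alignment(family: AlignedFamily, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in family.rows:
            fh.write(f">{rid}\n{seq}\n")


def write_stockholm(family: AlignedFamily, pairs, path) -> None:
    """Write Stockholm with the consensus pairs as an SS_cons line."""
    ss = ["."] * family.n_columns
    for i, j in pairs:
        ss[i - 1], ss[j - 1] = "(", ")"
    width = max(len(rid) for rid, _ in family.rows) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for rid, seq in family.rows:
            fh.write(f"{rid:<{width}}{seq}\n")
        fh.write(f"{'#=GC SS_cons':<{width}}{''.join(ss)}\n//\n")
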