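"""Gene sequence + exon annotation model and junction-relative coordinates.

A :class:`GeneModel` stores one sense-strand pre-mRNA sequence (RNA; DNA
input is transcribed on load) together with ordered, non-overlapping exon
intervals.  Splice junctions take their names from the flanking exon/intron
("E10-I10" for a 5' splice site, "I9-E10" for a 3' splice site) and
positions near them are expressed in the field's junction-relative
notation: exonic positions count from the first nucleotide of the exon;
intronic positions are +n downstream of a 5' splice site and -n upstream of
a 3' splice site.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .alphabet import normalize_rna

__all__ = [
    "AnnotationError",
    "CoordinateError",
    "Exon",
    "GeneModel",
    "Junction",
    "JunctionCoordinate",
    "RegionSpec",
    "extract_centered",
    "junction_region",
    "load_gene",
    "resolve_junction",
    "write_bed",
]


class AnnotationError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class Exon:
    exon_id: str
    start: int  # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Junction:
    """One splice site: the boundary between an exon and its flanking intron."""

    junction_id: str
    kind: str  # "5ss" (exon -> intron) or "3ss" (intron -> exon)
    exon_id: str
    #: last position of the 5' (upstream) side; the splice site lies
    #: between ``boundary`` and ``boundary + 1``
    boundary: int


@dataclass(frozen=True)
class JunctionCoordinate:
    """A position in junction-relative notation.

    ``side='exonic'``: offset counts from the first nucleotide of the exon
    (positive).  ``side='intronic'``: +n is the n-th intronic nucleotide
    downstream of a 5' splice site; -n the n-th upstream of a 3' splice
    site.  Offset 0 does not exist in this notation.
    """

    junction_id: str
    side: str  # "exonic" | "intronic"
    offset: int

    def __post_init__(self):
        if self.side not in ("exonic", "intronic"):
            raise ValueError("side must be 'exonic' or 'intronic'")
        if self.offset == 0:
            raise ValueError("offset 0 does not exist in junction-relative notation")


def _intron_name(exon_id: str) -> str:
    return "I" + exon_id[1:] if exon_id.startswith("E") else f"{exon_id}.i"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    sequence: str
    exons: tuple

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(self.exons))
        n = len(self.sequence)
        ids = [e.exon_id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise AnnotationError("exon ids are not unique")
        prev_end = 0
        for e in self.exons:
            if e.start > e.end:
                raise AnnotationError(f"exon {e.exon_id}: start {e.start} > end {e.end}")
            if e.start < 1 or e.end > n:
                raise AnnotationError(f"exon {e.exon_id} outside sequence bounds 1..{n}")
            if e.start <= prev_end:
                raise AnnotationError(f"exon {e.exon_id} overlaps or is out of order")
            prev_end = e.end

    @property
    def length(self) -> int:
        return len(self.sequence)

    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise KeyError(f"no exon {exon_id!r} in gene {self.gene_id}")

    def junctions(self) -> list[Junction]:
        """All splice sites with a flanking intron, in gene order."""
        out = []
        for k, e in enumerate(self.exons):
            intron = _intron_name(e.exon_id)
            if k + 1 < len(self.exons):
                out.append(Junction(f"{e.exon_id}-{intron}", "5ss", e.exon_id, e.end))
            if k > 0:
                prev_intron = _intron_name(self.exons[k - 1].exon_id)
                out.append(
                    Junction(f"{prev_intron}-{e.exon_id}", "3ss", e.exon_id, e.start - 1)
                )
        return sorted(out, key=lambda j: j.boundary)

    def junction(self, junction_id: str) -> Junction:
        for j in self.junctions():
            if j.junction_id == junction_id:
                return j
        raise KeyError(f"no junction {junction_id!r} in gene {self.gene_id}")

    def subsequence(self, start: int, end: int) -> str:
        if not (1 <= start <= end <= self.length):
            raise CoordinateError(f"interval {start}..{end} outside gene bounds")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class RegionSpec:
    """A labelled region of a gene: one or more intervals, 5'->3'."""

    label: str
    gene_id: str
    intervals: tuple  # ((start, end), ...) 1-based inclusive
    sequence: str
    truncated: bool = False
    #: offset of the splice site inside the extracted sequence, if any
    site_offset: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "intervals", tuple(tuple(iv) for iv in self.intervals))
        total = sum(e - s + 1 for s, e in self.intervals)
        if total != len(self.sequence):
            raise ValueError("interval lengths do not sum to sequence length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]


# ----------------------------------------------------------------------
# Loading
# ----------------------------------------------------------------------
def _read_exon_table(path) -> dict[str, list[Exon]]:
    table: dict[str, list[Exon]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            gene_id, exon_id, start, end = row[:4]
            table.setdefault(gene_id, []).append(Exon(exon_id, int(start), int(end)))
    return table


def load_gene(path, exon_table=None, gene_id: str | None = None) -> GeneModel:
    """Load a GeneModel from a FASTA or GenBank-style record.

    Exons come from GenBank ``exon`` features when present, else from
    *exon_table* (a TSV of ``gene_id  exon_id  start  end`` or a sequence of
    ``(exon_id, start, end)`` tuples).  DNA is transcribed to RNA and case
    is normalized.
    """
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    record = next(SeqIO.parse(str(path), fmt))
    seq = normalize_rna(str(record.seq))
    gid = gene_id or record.id

    exons: list[Exon] = []
    if fmt == "genbank":
        k = 0
        for feat in record.features:
            if feat.type != "exon":
                continue
            k += 1
            label = feat.qualifiers.get("number", feat.qualifiers.get("label", [str(k)]))[0]
            exon_id = label if str(label).startswith("E") else f"E{label}"
            exons.append(
                Exon(exon_id, int(feat.location.start) + 1, int(feat.location.end))
            )
    if not exons and exon_table is not None:
        if isinstance(exon_table, (str, Path)):
            table = _read_exon_table(exon_table)
            rows = table.get(gid) or next(iter(table.values()))
            exons = rows
        else:
            exons = [Exon(str(e), int(s), int(t)) for e, s, t in exon_table]
    if not exons:
        raise AnnotationError("no exon annotation: supply GenBank features or an exon table")
    exons.sort(key=lambda e: e.start)
    return GeneModel(gene_id=gid, sequence=seq, exons=tuple(exons))


# ----------------------------------------------------------------------
# Coordinates
# ----------------------------------------------------------------------
def resolve_junction(gene: GeneModel, jc: JunctionCoordinate) -> int:
    """Absolute 1-based position of a junction-relative coordinate."""
    junction = gene.junction(jc.junction_id)
    exon = gene.exon(junction.exon_id)
    exon_index = [e.exon_id for e in gene.exons].index(exon.exon_id)

    if jc.side == "exonic":
        if jc.offset < 0:
            raise CoordinateError("exonic positions count from the exon's first nt (>= 1)")
        if jc.offset > exon.length:
            raise CoordinateError(
                f"exonic offset {jc.offset} exceeds exon {exon.exon_id} length {exon.length}"
            )
        return exon.start + jc.offset - 1

    if junction.kind == "5ss":
        if jc.offset < 0:
            raise CoordinateError("intronic offsets at a 5' splice site are positive (+n)")
        pos = exon.end + jc.offset
        nxt = gene.exons[exon_index + 1]
        if pos >= nxt.start:
            raise CoordinateError(f"intronic offset +{jc.offset} runs into exon {nxt.exon_id}")
        return pos
    # 3' splice site: -n upstream of the exon
    if jc.offset > 0:
        raise CoordinateError("intronic offsets at a 3' splice site are negative (-n)")
    pos = exon.start + jc.offset  # offset is negative
    prev = gene.exons[exon_index - 1]
    if pos <= prev.end:
        raise CoordinateError(f"intronic offset {jc.offset} runs into exon {prev.exon_id}")
    return pos


def extract_centered(gene: GeneModel, junction_id: str, total_len: int) -> RegionSpec:
    """Window of *total_len* nt centered on a splice site.

    Half the window lies on each side of the site; if the gene end truncates
    one side the region is shortened and flagged rather than dropped, so
    near-terminal junctions remain scannable.
    """
    if total_len % 2:
        raise ValueError("total_len must be even")
    junction = gene.junction(junction_id)
    b = junction.boundary
    half = total_len // 2
    start = max(1, b - half + 1)
    end = min(gene.length, b + half)
    truncated = (start != b - half + 1) or (end != b + half)
    return RegionSpec(
        label=junction_id,
        gene_id=gene.gene_id,
        intervals=((start, end),),
        sequence=gene.subsequence(start, end),
        truncated=truncated,
        site_offset=b - start + 1,
    )


def junction_region(
    gene: GeneModel,
    junction_id: str,
    exonic: tuple[int, int] | None = None,
    intronic: tuple[int, int] | None = None,
    label: str | None = None,
) -> RegionSpec:
    """Region described the way junction tables do, e.g. exonic 73-93 plus
    intronic +1..+31 of a 5' splice site (or intronic -n..-1 plus exonic
    1..m at a 3' splice site)."""
    junction = gene.junction(junction_id)
    spans = []
    for side, rng in (("exonic", exonic), ("intronic", intronic)):
        if rng is None:
            continue
        a, b = rng
        pa = resolve_junction(gene, JunctionCoordinate(junction_id, side, a))
        pb = resolve_junction(gene, JunctionCoordinate(junction_id, side, b))
        spans.append((min(pa, pb), max(pa, pb)))
    if not spans:
        raise ValueError("specify at least one of exonic/intronic ranges")
    spans.sort()
    # merge contiguous spans
    merged = [spans[0]]
    for s, e in spans[1:]:
        if s == merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    seq = "".join(gene.subsequence(s, e) for s, e in merged)
    offset = junction.boundary - merged[0][0] + 1
    return RegionSpec(
        label=label or junction_id,
        gene_id=gene.gene_id,
        intervals=tuple(merged),
        sequence=seq,
        site_offset=offset if 1 <= offset <= len(seq) else None,
    )


def write_bed(regions: Iterable[RegionSpec], path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            for s, e in r.intervals:
                fh.write(f"{r.gene_id}\t{s - 1}\t{e}\t{r.label}\n")
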