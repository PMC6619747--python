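"""Report-table helpers: junction-relative interval notation and sidecars.

Junction tables describe intervals the way the splicing literature does,
e.g. ``73-93 of E10 and E10+1 to E10+31 of I10`` — exonic positions counted
from the exon's first nucleotide, intronic positions +n downstream of a 5'
splice site or -n upstream of a 3' splice site.  ASCII hyphens/minuses are
used so the TSVs stay grep-safe; pass ``typographic=True`` for en-dashes.
"""

from __future__ import annotations

from .seq_model import GeneModel, Junction

__all__ = ["junction_notation", "write_dotbracket"]


def junction_notation(
    gene: GeneModel, junction: Junction, start: int, end: int, typographic: bool = False
) -> str:
    """Describe absolute interval [start, end] relative to a splice site."""
    dash = "–" if typographic else "-"
    minus = "−" if typographic else "-"
    exon = gene.exon(junction.exon_id)
    exon_name, intron_name = (
        junction.junction_id.split("-")
        if junction.kind == "5ss"
        else junction.junction_id.split("-")[::-1]
    )
    b = junction.boundary
    parts = []
    if junction.kind == "5ss":
        if start <= b:
            a, z = start - exon.start + 1, min(end, b) - exon.start + 1
            parts.append(f"{a}{dash}{z} of {exon_name}")
        if end > b:
            a, z = max(start, b + 1) - b, end - b
            parts.append(f"{exon_name}+{a} to {exon_name}+{z} of {intron_name}")
    else:
        if start <= b:
            a, z = start - exon.start, min(end, b) - exon.start  # negative offsets
            parts.append(
                f"{exon_name}{minus}{-a} to {exon_name}{minus}{-z} of {intron_name}"
            )
        if end > b:
            a, z = max(start, b + 1) - exon.start + 1, end - exon.start + 1
            parts.append(f"{a}{dash}{z} of {exon_name}")
    return " and ".join(parts)


def write_dotbracket(records, path) -> None:
    """Write (name, sequence, structure) records as a dot-bracket file."""
    with open(path, "w") as fh:
        for name, seq, structure in records:
            db = structure if isinstance(structure, str) else structure.dot_bracket()
            fh.write(f">{name}\n{seq}\n{db}\n")
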