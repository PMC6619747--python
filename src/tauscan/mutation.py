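"""Point-mutation structure reports for junction windows.

Given a region (typically the wild-type window a junction table reports)
and a single-nucleotide substitution in splice-site notation — ``C(+14)T``
for the 14th intronic nucleotide downstream of a 5' splice site, ``G(-10)T``
for the 10th intronic nucleotide upstream of a 3' splice site — the report
folds wild type and mutant and tabulates dG, ddG (positive = destabilizing),
ensemble diversity and its change, MFE and centroid structures, and the
base-pair distance between the two MFE structures.

Protein-style labels (e.g. S305N) carry no nucleotide position by
themselves; they are accepted only together with an explicit nucleotide
definition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .alphabet import normalize_rna
from .seq_model import GeneModel, JunctionCoordinate, RegionSpec, resolve_junction
from .thermo import EnsembleSummary, ensemble, fold_mfe

__all__ = [
    "MutationModel",
    "MutationResult",
    "PointMutation",
    "ReferenceMismatch",
    "apply_mutation",
    "mutation_report",
    "parse_mutation_label",
]

_SPLICE_LABEL = re.compile(r"^([ACGTU])\(([+-]\d+)\)([ACGTU])$")


class ReferenceMismatch(ValueError):
    pass


@dataclass(frozen=True)
class PointMutation:
    """A single-base substitution located absolutely or junction-relative."""

    label: str
    position: int | JunctionCoordinate
    ref_base: str
    alt_base: str

    def __post_init__(self):
        object.__setattr__(self, "ref_base", normalize_rna(self.ref_base))
        object.__setattr__(self, "alt_base", normalize_rna(self.alt_base))

    @property
    def is_identity(self) -> bool:
        return self.ref_base == self.alt_base


def parse_mutation_label(
    label: str,
    junction_id: str | None = None,
    definitions: dict | None = None,
) -> PointMutation:
    """Parse splice-site notation like ``C(+14)T`` / ``G(-10)T``.

    Other labels (protein-style names) must appear in *definitions*, a
    mapping ``label -> (position, ref, alt)`` where position is absolute or
    a :class:`JunctionCoordinate`; otherwise a clear error is raised rather
    than guessing codon positions.
    """
    m = _SPLICE_LABEL.match(label)
    if m:
        if junction_id is None:
            raise ValueError(f"label {label!r} is junction-relative; supply junction_id")
        ref, offset, alt = m.group(1), int(m.group(2)), m.group(3)
        return PointMutation(
            label=label,
            position=JunctionCoordinate(junction_id, "intronic", offset),
            ref_base=ref,
            alt_base=alt,
        )
    if definitions and label in definitions:
        pos, ref, alt = definitions[label]
        return PointMutation(label=label, position=pos, ref_base=ref, alt_base=alt)
    raise ValueError(
        f"mutation label {label!r} carries no nucleotide position; provide an explicit "
        "definition (position, ref, alt), e.g. from the cDNA change it corresponds to"
    )


def _absolute_position(m: PointMutation, gene: GeneModel | None) -> int:
    if isinstance(m.position, JunctionCoordinate):
        if gene is None:
            raise ValueError("junction-relative mutation needs the GeneModel to resolve")
        return resolve_junction(gene, m.position)
    return int(m.position)


def _region_offset(region: RegionSpec, abs_pos: int) -> int:
    """1-based offset of an absolute gene position inside a region."""
    off = 0
    for s, e in region.intervals:
        if s <= abs_pos <= e:
            return off + (abs_pos - s + 1)
        off += e - s + 1
    raise ValueError(f"position {abs_pos} outside region {region.label}")


def apply_mutation(
    region: RegionSpec, m: PointMutation, gene: GeneModel | None = None
) -> str:
    """Mutated region sequence; the declared reference base is checked."""
    pos = _region_offset(region, _absolute_position(m, gene))
    seq = region.sequence
    found = seq[pos - 1]
    if found != m.ref_base:
        raise ReferenceMismatch(
            f"{m.label}: region has {found} at position {pos}, expected {m.ref_base}"
        )
    return seq[: pos - 1] + m.alt_base + seq[pos:]


@dataclass(frozen=True)
class MutationResult:
    """WT-vs-mutant thermodynamic comparison (no splicing-outcome claims)."""

    mutation: PointMutation
    wt: EnsembleSummary
    mut: EnsembleSummary
    ddg: float  # dG_mut - dG_wt; positive = destabilizing
    ded: float  # ED_mut - ED_wt
    mfe_bp_distance: int

    def summary(self) -> str:
        w, u = self.wt, self.mut
        return "\n".join(
            [
                f"Point mutation report: {self.mutation.label}",
                "=" * 48,
                f"             {'WT':>10} {'mutant':>10}",
                f"dG (kcal/mol){w.dg_mfe:10.2f} {u.dg_mfe:10.2f}   ddG = {self.ddg:+.2f}",
                f"ED (bp)      {w.ed:10.2f} {u.ed:10.2f}   dED = {self.ded:+.2f}",
                f"MFE bp distance: {self.mfe_bp_distance}",
                f"WT  MFE:      {w.mfe_structure.dot_bracket()}",
                f"mut MFE:      {u.mfe_structure.dot_bracket()}",
                f"WT  centroid: {w.centroid.dot_bracket()}",
                f"mut centroid: {u.centroid.dot_bracket()}",
            ]
        )


def mutation_report(
    region: RegionSpec,
    m: PointMutation,
    backend: str = "vienna",
    gene: GeneModel | None = None,
) -> MutationResult:
    """Fold WT and mutant region and compare."""
    mut_seq = apply_mutation(region, m, gene)
    wt = ensemble(region.sequence, backend)
    mut = ensemble(mut_seq, backend)
    return MutationResult(
        mutation=m,
        wt=wt,
        mut=mut,
        ddg=round(mut.dg_mfe - wt.dg_mfe, 10),
        ded=round(mut.ed - wt.ed, 10),
        mfe_bp_distance=wt.mfe_structure.bp_distance(mut.mfe_structure),
    )


class MutationModel:
    """Model object: a region plus one point mutation; ``fit()`` folds both
    alleles and returns a :class:`MutationResult`."""

    def __init__(
        self,
        region: RegionSpec,
        mutation: PointMutation,
        backend: str = "vienna",
        gene: GeneModel | None = None,
    ):
        self.region = region
        self.mutation = mutation
        self.backend = backend
        self.gene = gene

    def fit(self) -> MutationResult:
        return mutation_report(self.region, self.mutation, self.backend, self.gene)
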