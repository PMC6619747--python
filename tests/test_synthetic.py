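"""Synthetic-data generators and their ground truth."""

import math

import numpy as np
import pytest

from tauscan.scan import ScanConfig, StructureScan
from tauscan.seq_model import GeneModel
from tauscan.structure import SecondaryStructure
from tauscan.synthetic import (
    SyntheticTruth,
    embed_hairpin,
    make_background,
    make_family,
    make_gene,
    mapt_like_composition,
)
from tauscan.thermo import fold_mfe


class TestBackground:
    def test_degenerate_composition_gives_homopolymer(self):
        assert make_background(30, (1, 0, 0, 0), seed=0) == "A" * 30

    def test_frequencies_within_binomial_bound(self):
        n = 10_000
        seq = make_background(n, seed=5)
        bound = 3 * math.sqrt(0.25 * 0.75 / n)
        for base in "ACGU":
            assert abs(seq.count(base) / n - 0.25) <= bound

    def test_seeded_determinism(self):
        assert make_background(200, seed=9) == make_background(200, seed=9)

    def test_gc_rich_preset(self):
        comp = mapt_like_composition(0.55)
        seq = make_background(20_000, comp, seed=2)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.55) < 0.02

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError):
            make_background(10, (0.5, 0.5, 0.5, 0.5))


class TestEmbedHairpin:
    def test_designed_stem_is_the_mfe_fold(self):
        """The inserted segment refolds (reference engine) to exactly the
        designed pairs."""
        background = make_background(120, seed=3)
        seq, truth = embed_hairpin(background, stem_len=15, loop_len=4,
                                   gc_fraction=1.0, position=40, seed=8)
        t = truth.motifs[0]
        segment = seq[t["start"] - 1 : t["end"]]
        structure, dg = fold_mfe(segment, "reference")
        designed = {(i - t["start"] + 1, j - t["start"] + 1) for i, j in t["pairs"]}
        assert structure.pairs == frozenset(designed)
        assert dg < -20

    def test_zero_stem_is_identity(self):
        background = make_background(50, seed=0)
        seq, truth = embed_hairpin(background, stem_len=0, position=10)
        assert seq == background and truth.motifs == []

    def test_two_insertions_both_recorded(self):
        background = make_background(200, seed=1)
        seq, t1 = embed_hairpin(background, 10, position=20, seed=2)
        seq, t2 = embed_hairpin(seq, 10, position=120, seed=3)
        intervals = [(m["start"], m["end"]) for m in t1.motifs + t2.motifs]
        assert intervals == [(20, 43), (120, 143)]

    def test_insert_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            embed_hairpin("ACGU" * 5, stem_len=10, position=15)


class TestMakeGene:
    def test_valid_gene_without_motifs(self):
        gene, truth = make_gene(3, seed=11)
        assert isinstance(gene, GeneModel) and len(gene.exons) == 3
        assert truth.motifs == []

    def test_motif_straddles_junction(self):
        gene, truth = make_gene(4, junction_motifs={2: {"stem_len": 12}}, seed=7)
        (motif,) = truth.motifs
        boundary = gene.exons[1].end  # junction downstream of exon 2
        assert motif["start"] <= boundary < motif["end"]

    def test_deterministic_under_seed(self):
        g1, _ = make_gene(3, junction_motifs={1: {"stem_len": 10}}, seed=5)
        g2, _ = make_gene(3, junction_motifs={1: {"stem_len": 10}}, seed=5)
        assert g1 == g2

    def test_truth_serialization_round_trip(self, tmp_path):
        _, truth = make_gene(3, junction_motifs={1: {"stem_len": 10}}, seed=5)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = SyntheticTruth.from_json(p)
        assert back.params["n_exons"] == 3
        assert [tuple(map(tuple, m["pairs"])) for m in back.motifs] == [
            tuple(map(tuple, m["pairs"])) for m in truth.motifs
        ]


class TestMakeFamily:
    STRUCT = SecondaryStructure(
        length=24, pairs={(i, 25 - i) for i in range(1, 9)}
    )
    SEQ = "GGCGCGCG" + "AAAAAAAA" + "CGCGCGCC"

    def test_zero_rates_give_identical_rows(self):
        from tauscan.conservation import bp_conservation

        family, truth = make_family(self.SEQ, self.STRUCT, n_species=5,
                                    compensatory_rate=0, neutral_rate=0, seed=1)
        assert len({s for _, s in family.rows}) == 1
        rep = bp_conservation(family, sorted(self.STRUCT.pairs))
        assert rep.average_pct == 100.0

    def test_forced_compensation_covaries_everywhere(self):
        from tauscan.conservation import covariation_count

        family, _ = make_family(self.SEQ, self.STRUCT, n_species=3,
                                compensatory_rate=1.0, neutral_rate=0, seed=2)
        count, _ = covariation_count(family, sorted(self.STRUCT.pairs))
        assert count == len(self.STRUCT.pairs)

    def test_compensatory_changes_stay_canonical(self):
        from tauscan.alphabet import can_pair

        family, _ = make_family(self.SEQ, self.STRUCT, n_species=8,
                                compensatory_rate=0.5, neutral_rate=0.2, seed=3)
        for _, row in family.rows:
            for i, j in self.STRUCT.pairs:
                assert can_pair(row[i - 1], row[j - 1])

    def test_truth_records_match_rows(self):
        family, truth = make_family(self.SEQ, self.STRUCT, n_species=4,
                                    compensatory_rate=0.4, neutral_rate=0.3, seed=9)
        q = family.rows[0][1]
        for entry, (_, row) in zip(truth.family, family.rows[1:]):
            changed = {k + 1 for k in range(len(q)) if row[k] != q[k]}
            recorded = {p for ij in entry["compensatory"] for p in ij}
            recorded |= set(entry["neutral"])
            assert changed <= recorded  # a swap may keep one base identical


def test_junction_scan_recovers_planted_motifs():
    """End-to-end on a multi-exon gene: hairpins planted at 5' splice sites
    are flagged by the junction scan (z-outliers) at most junctions."""
    recovered = total = 0
    for seed in range(6):
        gene, truth = make_gene(
            5, junction_motifs={1: {"stem_len": 13}, 3: {"stem_len": 13}},
            composition=mapt_like_composition(), seed=100 + seed,
        )
        for motif in truth.motifs:
            total += 1
            # scan the junction the motif straddles
            junction = next(
                j for j in gene.junctions()
                if motif["start"] <= j.boundary <= motif["end"]
            )
            result = StructureScan.from_gene(
                gene, junction.junction_id, preset="junction-stage1",
                n_shuffles=30, seed=seed, backend="vienna",
            ).fit()
            region_start = result.model.region.start
            for m in result.selected("z"):
                if (region_start + m.start - 1 <= motif["end"]
                        and region_start + m.end - 1 >= motif["start"]):
                    recovered += 1
                    break
    assert total == 12
    assert recovered >= 10
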