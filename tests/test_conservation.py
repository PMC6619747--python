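"""Homolog filtering, structure mapping, conservation, APSI, covariation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauscan.conservation import (
    AlignedFamily,
    HomologSet,
    align_family,
    apsi,
    bp_conservation,
    covariation_count,
    filter_homologs,
    map_structure,
    read_alignment,
    write_alignment,
    write_stockholm,
)
from tauscan.structure import SecondaryStructure
from tauscan.synthetic import make_family


def fam(*rows):
    return AlignedFamily(rows=tuple((f"r{i}", s) for i, s in enumerate(rows)))


class TestFilterHomologs:
    def test_exact_duplicates_collapse(self):
        hs = HomologSet("ACGUACGUAC", (("h1", "ACGUACGUAC", ""),
                                       ("h2", "ACGUACGUAC", ""),
                                       ("h3", "ACGUACGUAG", "")))
        kept = filter_homologs(hs)
        assert [h[0] for h in kept.hits] == ["h1", "h3"]

    def test_length_boundary_at_80_percent(self):
        query = "A" * 100
        hs = HomologSet(query, (("short", "ACGU" * 19 + "ACG", ""),   # 79 nt
                                ("exact", "ACGU" * 20, "")))          # 80 nt
        kept = filter_homologs(hs)
        assert [h[0] for h in kept.hits] == ["exact"]

    def test_empty_hits_allowed(self):
        assert filter_homologs(HomologSet("ACGU", ())).hits == ()


class TestMapStructure:
    def test_gapless_alignment_is_identity(self):
        family = fam("ACGGAAACCGU", "ACGGAAACCGU")
        s = SecondaryStructure.from_dot_bracket("((....))...")
        assert map_structure(family, s) == ((1, 8), (2, 7))

    def test_query_gap_shifts_columns(self):
        family = fam("AC-GU", "ACAGU")
        s = SecondaryStructure(length=4, pairs={(1, 4)})
        assert map_structure(family, s) == ((1, 5),)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10**6))
    def test_mapping_matches_gap_count_oracle(self, seed):
        """Column index = sequence index + number of query gaps before it."""
        import numpy as np

        rng = np.random.default_rng(seed)
        n = 12
        seq = "".join(rng.choice(list("ACGU"), n))
        gapped = []
        for c in seq:
            while rng.random() < 0.2:
                gapped.append("-")
            gapped.append(c)
        gq = "".join(gapped)
        family = AlignedFamily(rows=(("q", gq), ("h", "A" * len(gq))))
        s = SecondaryStructure(length=n, pairs={(2, 9)})
        ((ci, cj),) = map_structure(family, s)
        gaps_before = lambda k: sum(
            1 for col, ch in enumerate(gq) if ch == "-" and col < k
        )
        # the k-th residue sits at column k + (gaps before it)
        residues = [c for c in range(len(gq)) if gq[c] != "-"]
        assert ci == residues[1] + 1 and cj == residues[8] + 1

    def test_length_mismatch_rejected(self):
        family = fam("ACGU", "ACGU")
        with pytest.raises(ValueError, match="length"):
            map_structure(family, SecondaryStructure(length=6, pairs=frozenset()))


class TestConservation:
    def test_identical_rows_are_fully_conserved(self):
        q = "GGGGAAAACCCC"
        family = fam(q, q, q)
        pairs = [(i, 13 - i) for i in range(1, 5)]
        rep = bp_conservation(family, pairs)
        assert all(p == 100.0 for p in rep.per_pair_pct)
        assert rep.average_pct == 100.0
        assert rep.n_species == 2

    def test_two_row_arithmetic(self):
        # 10 pairs; second row breaks exactly one (G->A opposite C)
        q = "G" * 10 + "AAAA" + "C" * 10
        h = "A" + "G" * 9 + "AAAA" + "C" * 10
        pairs = [(i, 25 - i) for i in range(1, 11)]
        rep = bp_conservation(fam(q, h), pairs)
        assert rep.per_pair_pct.count(50.0) == 1
        assert rep.average_pct == pytest.approx(95.0)
        assert rep.average_pct_cells == pytest.approx(95.0)

    def test_gap_counts_as_non_canonical(self):
        rep = bp_conservation(fam("GAAAC", "-AAAC"), [(1, 5)])
        assert rep.per_pair_pct == (50.0,)

    def test_row_and_pair_permutation_invariance(self):
        q = "GGCGAAAACGCC"
        rows = [q, "GGUGAAAACACC", "AGCGAAAACGCU"]
        pairs = [(1, 12), (2, 11), (3, 10), (4, 9)]
        base = bp_conservation(fam(*rows), pairs)
        for perm in itertools.permutations(rows):
            rep = bp_conservation(fam(*perm), pairs)
            assert sorted(rep.per_pair_pct) == sorted(base.per_pair_pct)
            assert rep.average_pct == pytest.approx(base.average_pct)
        rep = bp_conservation(fam(*rows), list(reversed(pairs)))
        assert rep.average_pct == pytest.approx(base.average_pct)

    def test_adding_query_identical_row_never_lowers_percentages(self):
        q = "GGCGAAAACGCC"
        rows = [q, "GAUGAAAACAUC", "AGCGAAAACGCU"]
        pairs = [(1, 12), (2, 11), (3, 10)]
        before = bp_conservation(fam(*rows), pairs)
        after = bp_conservation(fam(*(rows + [q])), pairs)
        for b, a in zip(before.per_pair_pct, after.per_pair_pct):
            assert a >= b

    def test_no_pairs_flagged_undefined(self):
        rep = bp_conservation(fam("ACGU", "ACGU"), [])
        assert rep.average_pct is None


class TestApsi:
    def test_identical_rows(self):
        assert apsi(fam("ACGUACGUAC", "ACGUACGUAC")) == 100.0

    def test_one_mismatch_in_ten(self):
        assert apsi(fam("ACGUACGUAC", "ACGUACGUAG")) == pytest.approx(90.0)

    def test_three_rows_equal_brute_force(self):
        rows = ["ACGU-CGUAC", "ACGUACGUAC", "AC-UACGAAC"]
        family = fam(*rows)
        pair_ids = []
        for a, b in itertools.combinations(rows, 2):
            num = sum(1 for x, y in zip(a, b) if x == y and x != "-")
            den = sum(1 for x, y in zip(a, b) if x != "-" or y != "-")
            pair_ids.append(100 * num / den)
        assert apsi(family) == pytest.approx(sum(pair_ids) / 3)

    def test_single_row_undefined(self):
        with pytest.raises(ValueError):
            apsi(AlignedFamily(rows=(("q", "ACGU"),)))


class TestCovariation:
    def test_no_substitutions_no_covariation(self):
        q = "GGGGAAAACCCC"
        count, _ = covariation_count(fam(q, q, q), [(i, 13 - i) for i in range(1, 5)])
        assert count == 0

    def test_single_species_insufficient(self):
        q = "GAAAC"
        count, support = covariation_count(fam(q, "CAAAG", q), [(1, 5)])
        assert count == 0 and support[(1, 5)] == ["r1"]

    def test_designed_compensatory_family(self):
        # 3 species carry GC->AU swaps at all 5 stem pairs
        q = "GGGGG" + "AAAA" + "CCCCC"
        swapped = "AAAAA" + "AAAA" + "UUUUU"
        pairs = [(i, 15 - i) for i in range(1, 6)]
        count, support = covariation_count(fam(q, swapped, swapped, swapped), pairs)
        assert count == 5
        assert all(len(support[p]) == 3 for p in support)

    def test_count_bounded_by_pairs(self):
        family, _ = make_family(
            "GGCGCAAAAGCGCC",
            SecondaryStructure(length=14, pairs={(1, 14), (2, 13), (3, 12), (4, 11), (5, 10)}),
            n_species=6, compensatory_rate=1.0, neutral_rate=0.0, seed=4,
        )
        pairs = [(1, 14), (2, 13), (3, 12), (4, 11), (5, 10)]
        count, _ = covariation_count(family, pairs)
        assert count == 5  # forced: every pair mutated in every species


class TestAligner:
    def test_identical_sequences_align_gapless(self):
        hs = HomologSet("ACGUACGUAC", (("h", "ACGUACGUAC", ""),))
        family = align_family(hs)
        assert family.rows[0][1] == "ACGUACGUAC"
        assert family.rows[1][1] == "ACGUACGUAC"

    def test_single_deletion_opens_one_gap(self):
        q = "ACGUACGUAC"
        hs = HomologSet(q, (("h", "ACGUCGUAC", ""),))  # A at position 5 deleted
        family = align_family(hs)
        assert family.rows[0][1] == q
        assert family.rows[1][1].count("-") == 1
        assert family.rows[1][1].replace("-", "") == "ACGUCGUAC"

    def test_ingested_alignment_round_trips(self, tmp_path):
        family = fam("AC-GUA", "ACAGUA")
        p = tmp_path / "aln.fasta"
        write_alignment(family, p)
        back = read_alignment(p)
        assert back.rows == family.rows

    def test_stockholm_ss_cons_line(self, tmp_path):
        family = fam("GGAAACC", "GGAAACC")
        p = tmp_path / "fam.sto"
        write_stockholm(family, [(1, 7), (2, 6)], p)
        text = p.read_text()
        assert "#=GC SS_cons" in text and "((...))" in text

    def test_inconsistent_row_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            AlignedFamily(rows=(("a", "ACGU"), ("b", "ACG")))
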