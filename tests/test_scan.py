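"""Sliding-window scan: windows, shuffles, null statistics, selection,
merging, determinism, calibration and detection power."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauscan.scan import (
    MotifRegion,
    ScanConfig,
    StructureScan,
    WindowMetrics,
    merge_and_refold,
    null_stats,
    scan,
    select_windows,
    shuffle_seq,
    window_metrics,
    windowize,
)
from tauscan.synthetic import embed_hairpin, make_background

rna = st.text(alphabet="ACGU", min_size=2, max_size=60)


class TestWindowize:
    @pytest.mark.parametrize(
        "region_len,window,step,n_windows,last_start",
        [
            (100, 30, 10, 8, 71),
            (30, 30, 10, 1, 1),
            (250, 70, 1, 181, 181),
            (4163, 150, 10, 402, 4011),
        ],
    )
    def test_window_counts(self, region_len, window, step, n_windows, last_start):
        w = windowize(region_len, window, step)
        assert len(w) == n_windows
        assert w[0] == (1, window)
        assert w[-1][0] == last_start
        assert all(e - s + 1 == window for s, e in w)

    def test_window_longer_than_region(self):
        with pytest.raises(ValueError, match="empty scan"):
            windowize(20, 30, 10)


class TestShuffle:
    @settings(max_examples=80, deadline=None)
    @given(rna, st.integers(0, 2**31 - 1))
    def test_mononucleotide_preserves_composition(self, seq, seed):
        rng = np.random.default_rng(seed)
        out = shuffle_seq(seq, "mononucleotide", rng)
        assert sorted(out) == sorted(seq)

    @settings(max_examples=80, deadline=None)
    @given(rna, st.integers(0, 2**31 - 1))
    def test_dinucleotide_preserves_dinucleotide_counts(self, seq, seed):
        from collections import Counter

        rng = np.random.default_rng(seed)
        out = shuffle_seq(seq, "dinucleotide", rng)
        assert Counter(zip(out, out[1:])) == Counter(zip(seq, seq[1:]))

    def test_homopolymer_fixed_point(self):
        rng = np.random.default_rng(0)
        for mode in ("mononucleotide", "dinucleotide"):
            assert shuffle_seq("AAAA", mode, rng) == "AAAA"

    def test_dinucleotide_shuffle_actually_permutes(self):
        seq = make_background(60, seed=9)
        rng = np.random.default_rng(1)
        outs = {shuffle_seq(seq, "dinucleotide", rng) for _ in range(20)}
        assert len(outs) > 1


class TestNullStats:
    def test_direct_arithmetic(self):
        mean, sd, z, p, degen = null_stats(-10.0, [-5.0, -6.0, -7.0])
        assert (mean, sd) == (-6.0, 1.0)
        assert z == pytest.approx(-4.0)
        assert p == 0.0 and not degen

    def test_p_counts_strictly_lower(self):
        *_, p, _ = null_stats(-6.0, [-5.0, -6.0, -7.0])
        assert p == pytest.approx(1 / 3)

    def test_degenerate_null_flags_not_nan(self):
        mean, sd, z, p, degen = null_stats(0.0, [0.0, 0.0, 0.0])
        assert degen and z == 0.0 and p == 0.0

    def test_homopolymer_window_degenerate(self):
        cfg = ScanConfig(window_len=20, step=20, n_shuffles=5, backend="reference")
        m = window_metrics("A" * 20, cfg)
        assert m.degenerate_null and m.z == 0.0 and m.p == 0.0


class TestSelection:
    def _metrics(self, zs, eds=None):
        eds = eds or [1.0] * len(zs)
        return [
            WindowMetrics(start=10 * k + 1, end=10 * k + 30, dg_native=0, dg_random_mean=0,
                          dg_random_sd=1, z=z, p=0, ed=e)
            for k, (z, e) in enumerate(zip(zs, eds))
        ]

    def test_one_sd_rule(self):
        flagged = select_windows(self._metrics([-2.0, -1.0, 0.0, 1.0]))
        assert [m.z_outlier for m in flagged] == [True, False, False, False]

    def test_identical_z_selects_nothing(self):
        flagged = select_windows(self._metrics([1.0, 1.0, 1.0]))
        assert not any(m.z_outlier for m in flagged)

    def test_ed_outliers_reported_separately(self):
        flagged = select_windows(self._metrics([0.0, 0.0, 0.0, 0.0],
                                               eds=[5.0, 5.0, 5.0, 0.5]))
        assert not any(m.z_outlier for m in flagged)
        assert [m.ed_outlier for m in flagged] == [False, False, False, True]


class TestMerge:
    def _mk(self, s, e):
        return WindowMetrics(start=s, end=e, dg_native=0, dg_random_mean=0,
                             dg_random_sd=1, z=-2, p=0, ed=1, z_outlier=True)

    def test_overlapping_windows_merge(self):
        seq = make_background(60, seed=0)
        regions = merge_and_refold([self._mk(1, 30), self._mk(11, 40)], seq, "reference")
        assert len(regions) == 1 and (regions[0].start, regions[0].end) == (1, 40)

    def test_disjoint_windows_stay_separate(self):
        seq = make_background(80, seed=0)
        regions = merge_and_refold([self._mk(1, 30), self._mk(45, 74)], seq, "reference")
        assert [(r.start, r.end) for r in regions] == [(1, 30), (45, 74)]

    def test_merged_region_recovers_embedded_hairpin(self):
        """The merged z-outlier region covers >= 90% of a planted hairpin."""
        background = make_background(240, seed=21)
        seq, truth = embed_hairpin(background, stem_len=14, loop_len=4,
                                   gc_fraction=0.9, position=100, seed=3)
        cfg = ScanConfig(window_len=30, step=10, n_shuffles=30, seed=5, backend="vienna")
        result = StructureScan(seq, cfg).fit()
        motifs = result.motifs("z")
        assert motifs, "no z-outlier region found over the planted hairpin"
        t = truth.motifs[0]
        covered = max(
            max(0, min(m.end, t["end"]) - max(m.start, t["start"]) + 1) for m in motifs
        )
        assert covered >= 0.9 * (t["end"] - t["start"] + 1)


class TestScan:
    def test_determinism_bit_identical(self):
        seq = make_background(150, seed=3)
        cfg = ScanConfig(window_len=30, step=15, n_shuffles=10, seed=42, backend="vienna")
        a = scan(seq, cfg)
        b = scan(seq, cfg)
        assert a == b

    def test_p_and_z_concordant(self):
        """Within one scan, p and z rank windows the same way."""
        from scipy.stats import spearmanr

        seq = make_background(400, seed=8)
        cfg = ScanConfig(window_len=40, step=10, n_shuffles=30, seed=2, backend="vienna")
        ms = [m for m in scan(seq, cfg) if not m.degenerate_null]
        rho, _ = spearmanr([m.p for m in ms], [m.z for m in ms])
        assert rho > 0

    def test_covering_windows_have_minimum_z(self):
        """Windows over a planted GC-clamped hairpin carry the scan minimum."""
        background = make_background(300, seed=13)
        seq, truth = embed_hairpin(background, stem_len=15, loop_len=4,
                                   gc_fraction=1.0, position=140, seed=1)
        cfg = ScanConfig(window_len=30, step=10, n_shuffles=20, seed=7, backend="vienna")
        ms = scan(seq, cfg)
        t = truth.motifs[0]
        zmin_window = min(ms, key=lambda m: m.z)
        assert zmin_window.start <= t["end"] and zmin_window.end >= t["start"]

    def test_detection_power_over_replicates(self):
        """A hairpin far below the background energy scale is flagged in
        >= 95% of seeded replicates."""
        hits = 0
        reps = 100
        for seed in range(reps):
            background = make_background(150, seed=1000 + seed)
            seq, truth = embed_hairpin(background, stem_len=12, loop_len=4,
                                       gc_fraction=0.9, position=60, seed=seed)
            cfg = ScanConfig(window_len=30, step=10, n_shuffles=20,
                             seed=seed, backend="vienna")
            result = StructureScan(seq, cfg).fit()
            t = truth.motifs[0]
            if any(m.start <= t["end"] and m.end >= t["start"]
                   for m in result.selected("z")):
                hits += 1
        assert hits >= 0.95 * reps
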