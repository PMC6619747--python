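"""Sliding-window thermodynamic scan with a shuffle-based null model.

For each window the scan computes the native folding free energy, the mean
and SD of the MFE over ``n_shuffles`` randomized versions of the window,
the resulting z-score ``z = (dG_native - mean(dG_random)) / sd(dG_random)``,
the empirical p-value (fraction of randomized windows folding *more* stably
than the native one) and the ensemble diversity of the native window.
Windows whose z (or ED) falls more than ``selection_sd`` sample SDs below
the scan average are flagged as outliers; overlapping flagged windows are
merged and refolded into candidate structured regions.

The scan is exposed statsmodels-style: :class:`StructureScan` holds the
region and configuration, ``.fit()`` runs the scan and returns a
:class:`ScanResult` with the per-window table, selection, merging and a
``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import normalize_rna
from .seq_model import GeneModel, RegionSpec, extract_centered
from .structure import SecondaryStructure
from .thermo import ensemble, fold_mfe

__all__ = [
    "PRESETS",
    "MotifRegion",
    "ScanConfig",
    "ScanResult",
    "StructureScan",
    "WindowMetrics",
    "merge_and_refold",
    "null_stats",
    "scan",
    "select_windows",
    "shuffle_seq",
    "window_metrics",
    "windowize",
]

log = logging.getLogger(__name__)

#: scan presets: (centered length or None, window length, step)
PRESETS = {
    "junction-stage1": (500, 30, 10),
    "junction-stage2": (250, 70, 1),
    "utr": (None, 150, 10),
}


@dataclass(frozen=True)
class ScanConfig:
    window_len: int
    step: int
    n_shuffles: int = 50
    shuffle_mode: str = "mononucleotide"
    seed: int = 0
    backend: str = "vienna"
    selection_sd: float = 1.0

    def __post_init__(self):
        if self.window_len < 10:
            raise ValueError("window_len must be >= 10")
        if not (1 <= self.step <= self.window_len):
            raise ValueError("step must satisfy 1 <= step <= window_len")
        if self.n_shuffles < 2:
            raise ValueError("need at least 2 shuffles for a null SD")
        if self.shuffle_mode not in ("mononucleotide", "dinucleotide"):
            raise ValueError("shuffle_mode must be 'mononucleotide' or 'dinucleotide'")


@dataclass(frozen=True)
class WindowMetrics:
    """Per-window scan statistics (coordinates are region-relative, 1-based)."""

    start: int
    end: int
    dg_native: float
    dg_random_mean: float
    dg_random_sd: float
    z: float
    p: float
    ed: float
    degenerate_null: bool = False
    z_outlier: bool = False
    ed_outlier: bool = False


@dataclass(frozen=True)
class MotifRegion:
    """A merged, refolded run of outlier windows."""

    start: int
    end: int
    structure: SecondaryStructure
    dg: float
    min_z: float
    min_ed: float
    n_windows: int
    z_outlier: bool
    ed_outlier: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ----------------------------------------------------------------------
# Windows and shuffles
# ----------------------------------------------------------------------
def windowize(region_len: int, window_len: int, step: int) -> list[tuple[int, int]]:
    """Window intervals starting at 1, 1+step, ...; trailing fragments
    shorter than *window_len* are dropped."""
    if window_len > region_len:
        raise ValueError(
            f"window ({window_len} nt) longer than region ({region_len} nt): empty scan"
        )
    return [
        (s, s + window_len - 1) for s in range(1, region_len - window_len + 2, step)
    ]


def shuffle_seq(seq: str, mode: str, rng: np.random.Generator) -> str:
    """Randomize a sequence preserving mononucleotide or dinucleotide counts.

    Dinucleotide mode is the Euler-path (Altschul-Erickson) shuffle: the
    output is a uniform-ish random sequence with exactly the same 16-entry
    dinucleotide count vector (and hence composition and end bases).
    """
    if len(seq) < 2:
        return seq
    if mode == "mononucleotide":
        chars = np.array(list(seq))
        rng.shuffle(chars)
        return "".join(chars)
    if mode != "dinucleotide":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return _euler_shuffle(seq, rng)


def _euler_shuffle(seq: str, rng: np.random.Generator) -> str:
    first, last = seq[0], seq[-1]
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, [])
    vertices = [v for v in adj if adj[v]]

    # pick a random "last edge" per vertex (except the terminal one) such
    # that following last edges always reaches the terminal vertex
    for _ in range(1000):
        last_edge = {
            v: adj[v][int(rng.integers(len(adj[v])))] for v in vertices if v != last
        }
        ok = True
        for v in vertices:
            if v == last:
                continue
            w, hops = v, 0
            while w != last and hops <= len(vertices):
                w = last_edge.get(w, last)
                hops += 1
            if w != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not construct an Eulerian last-edge tree")

    walk_lists: dict[str, list[str]] = {}
    for v in adj:
        edges = list(adj[v])
        if v != last and v in last_edge:
            edges.remove(last_edge[v])
            rng.shuffle(edges)
            edges.append(last_edge[v])
        else:
            rng.shuffle(edges)
        walk_lists[v] = edges

    out = [first]
    pos = {v: 0 for v in adj}
    v = first
    for _ in range(len(seq) - 1):
        nxt = walk_lists[v][pos[v]]
        pos[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


# ----------------------------------------------------------------------
# Metrics
# ----------------------------------------------------------------------
def null_stats(dg_native: float, randoms) -> tuple[float, float, float, float, bool]:
    """Shuffle-null summary: (mean, sample SD, z, p, degenerate flag).

    ``z = (dG_native - mean)/SD``; ``p`` counts randomized sequences folding
    strictly more stably than the native one.  An all-identical null (e.g. a
    homopolymer window) is flagged degenerate and reports z = 0, not NaN.
    """
    randoms = np.asarray(randoms, dtype=float)
    mean = float(randoms.mean())
    sd = float(randoms.std(ddof=1))
    p = float(np.sum(randoms < dg_native)) / len(randoms)
    if sd == 0.0:
        return mean, sd, 0.0, p, True
    return mean, sd, float((dg_native - mean) / sd), p, False


def window_metrics(
    seq: str,
    cfg: ScanConfig,
    rng: np.random.Generator | None = None,
    start: int = 1,
) -> WindowMetrics:
    """Scan statistics for one window sequence."""
    seq = normalize_rna(seq)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    _, dg_native = fold_mfe(seq, cfg.backend)
    summary = ensemble(seq, cfg.backend)
    randoms = [
        fold_mfe(shuffle_seq(seq, cfg.shuffle_mode, rng), cfg.backend)[1]
        for _ in range(cfg.n_shuffles)
    ]
    mean, sd, z, p, degenerate = null_stats(dg_native, randoms)
    return WindowMetrics(
        start=start,
        end=start + len(seq) - 1,
        dg_native=dg_native,
        dg_random_mean=mean,
        dg_random_sd=sd,
        z=z,
        p=p,
        ed=summary.ed,
        degenerate_null=degenerate,
    )


def scan(region, cfg: ScanConfig) -> list[WindowMetrics]:
    """Scan a region (RegionSpec or plain sequence) window by window.

    Each window's shuffle RNG stream is derived from ``(cfg.seed, window
    start)``, so results are independent of evaluation order and bit-
    reproducible for a fixed seed.
    """
    seq = region.sequence if isinstance(region, RegionSpec) else normalize_rna(region)
    out = []
    for s, e in windowize(len(seq), cfg.window_len, cfg.step):
        rng = np.random.default_rng([cfg.seed, s])
        out.append(window_metrics(seq[s - 1 : e], cfg, rng, start=s))
    log.info("scanned %d windows of %d nt (step %d)", len(out), cfg.window_len, cfg.step)
    return out


def select_windows(
    metrics: Sequence[WindowMetrics], selection_sd: float = 1.0
) -> list[WindowMetrics]:
    """Flag z- and ED-outlier windows relative to this scan's own averages.

    A window is a z-outlier iff ``z < mean_z - selection_sd * sd_z`` (sample
    SD over all windows of the scan); ED-outliers analogously.  The two
    flags are independent.  A zero SD selects nothing.
    """
    if len(metrics) < 2:
        raise ValueError("selection needs at least 2 windows")
    z = np.array([m.z for m in metrics])
    ed = np.array([m.ed for m in metrics])
    out = []
    thr_z = z.mean() - selection_sd * z.std(ddof=1)
    thr_ed = ed.mean() - selection_sd * ed.std(ddof=1)
    if z.std(ddof=1) == 0.0:
        log.warning("all window z-scores identical; no z-outliers selectable")
    for m in metrics:
        out.append(
            replace(
                m,
                z_outlier=bool(z.std(ddof=1) > 0 and m.z < thr_z),
                ed_outlier=bool(ed.std(ddof=1) > 0 and m.ed < thr_ed),
            )
        )
    return out


def merge_and_refold(
    selected: Sequence[WindowMetrics], region, backend: str = "vienna"
) -> list[MotifRegion]:
    """Merge overlapping/adjacent selected windows and refold each merged
    interval as one sequence."""
    seq = region.sequence if isinstance(region, RegionSpec) else normalize_rna(region)
    chosen = sorted((m for m in selected), key=lambda m: m.start)
    if not chosen:
        return []
    groups: list[list[WindowMetrics]] = [[chosen[0]]]
    for m in chosen[1:]:
        if m.start <= groups[-1][-1].end + 1:
            groups[-1].append(m)
        else:
            groups.append([m])
    regions = []
    for grp in groups:
        s = min(m.start for m in grp)
        e = max(m.end for m in grp)
        structure, dg = fold_mfe(seq[s - 1 : e], backend)
        regions.append(
            MotifRegion(
                start=s,
                end=e,
                structure=structure,
                dg=dg,
                min_z=min(m.z for m in grp),
                min_ed=min(m.ed for m in grp),
                n_windows=len(grp),
                z_outlier=any(m.z_outlier for m in grp),
                ed_outlier=any(m.ed_outlier for m in grp),
            )
        )
    log.info("merged %d selected windows into %d regions", len(chosen), len(regions))
    return regions


# ----------------------------------------------------------------------
# Model / Results objects
# ----------------------------------------------------------------------
SCAN_COLUMNS = [
    "start", "end", "dg_native", "dg_random_mean", "dg_random_sd",
    "z", "p", "ed", "degenerate_null", "z_outlier", "ed_outlier",
]


class StructureScan:
    """Sliding-window scan model for one region.

    Parameters
    ----------
    region : RegionSpec or str
        The sequence to scan (a RegionSpec keeps gene coordinates attached).
    config : ScanConfig
        Window geometry, null model and backend.
    """

    def __init__(self, region, config: ScanConfig):
        self.region = region
        self.config = config
        self.sequence = (
            region.sequence if isinstance(region, RegionSpec) else normalize_rna(region)
        )

    @classmethod
    def from_gene(
        cls, gene: GeneModel, junction_id: str, preset: str = "junction-stage2", **overrides
    ) -> "StructureScan":
        """Scan centered on a splice junction using a named preset."""
        total_len, window_len, step = PRESETS[preset]
        region = extract_centered(gene, junction_id, total_len or 250)
        cfg = ScanConfig(window_len=window_len, step=step, **overrides)
        return cls(region, cfg)

    def fit(self, seed: int | None = None) -> "ScanResult":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        metrics = select_windows(scan(self.region, cfg), cfg.selection_sd)
        return ScanResult(self, cfg, metrics)


class ScanResult:
    """Fitted scan: per-window table, outlier selection and merged motifs."""

    def __init__(self, model: StructureScan, config: ScanConfig, windows: list[WindowMetrics]):
        self.model = model
        self.config = config
        self.windows = windows

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {c: getattr(m, c) for c in SCAN_COLUMNS} for m in self.windows
        ])

    @property
    def mean_z(self) -> float:
        return float(np.mean([m.z for m in self.windows]))

    def selected(self, criterion: str = "z") -> list[WindowMetrics]:
        """Outlier windows by criterion: 'z', 'ed' or 'both'."""
        if criterion == "z":
            return [m for m in self.windows if m.z_outlier]
        if criterion == "ed":
            return [m for m in self.windows if m.ed_outlier]
        if criterion == "both":
            return [m for m in self.windows if m.z_outlier and m.ed_outlier]
        raise ValueError("criterion must be 'z', 'ed' or 'both'")

    def motifs(self, criterion: str = "z") -> list[MotifRegion]:
        return merge_and_refold(self.selected(criterion), self.model.region, self.config.backend)

    def to_tsv(self, path) -> None:
        """Write the window table (columns as in SCAN_COLUMNS, one row per
        window, region-relative 1-based coordinates)."""
        self.frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        df = self.frame()
        cfg = self.config
        lines = [
            "Sliding-window thermodynamic scan",
            "=" * 48,
            f"region length: {len(self.model.sequence)} nt   windows: {len(df)}",
            f"window/step:   {cfg.window_len}/{cfg.step} nt   backend: {cfg.backend}",
            f"null model:    {cfg.n_shuffles} x {cfg.shuffle_mode} shuffle (seed {cfg.seed})",
            f"mean z: {df.z.mean():7.3f}   sd z: {df.z.std(ddof=1):.3f}",
            f"mean ED: {df.ed.mean():6.2f}   sd ED: {df.ed.std(ddof=1):.2f}",
            f"z-outliers: {int(df.z_outlier.sum())}   ED-outliers: {int(df.ed_outlier.sum())}"
            f"   (threshold: mean - {cfg.selection_sd} SD)",
        ]
        sel = df[df.z_outlier]
        if len(sel):
            lines.append("z-outlier windows (start-end, z, ED):")
            for _, r in sel.iterrows():
                lines.append(f"  {int(r.start):5d}-{int(r.end):<5d}  z={r.z:6.2f}  ED={r.ed:5.2f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """z-score track with the selection threshold; needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        df = self.frame()
        mid = (df.start + df.end) / 2
        ax.plot(mid, df.z, lw=1, label="z-score")
        thr = df.z.mean() - self.config.selection_sd * df.z.std(ddof=1)
        ax.axhline(thr, color="crimson", ls="--", lw=1, label="selection threshold")
        ax.set_xlabel("position (nt)")
        ax.set_ylabel("thermodynamic z-score")
        ax.legend(frameon=False)
        return ax
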