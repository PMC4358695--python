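"""Topology classification and introgression-tract calling.

Rooted four-taxon ingroup trees (outgroup removed) are mapped to canonical
classes: T1 groups the two cultivated lines with S. galapagense as the
closest wild sister, T2 puts the two wild species together, T3 pulls
S. pimpinellifolium toward the cultivated pair. Shapes that break the
cultivated (YP, H1706) cherry by pairing S. pimpinellifolium with exactly
one cultivated line are the introgression signatures: next to H1706 they
indicate wild material in the reference line, next to YP in the heirloom.
Because the heirloom predates modern breeding, an excess of INTROG_H1706
over INTROG_YP windows (equal under pure lineage sorting) is the
introgression signal; runs of such windows are merged into tracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trees import Clade, DEFAULT_TAXA

LABELS = ("T1", "T2", "T3", "INTROG_H1706", "INTROG_YP", "OTHER", "UNRESOLVED")


@dataclass(frozen=True)
class TopologyClass:
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown topology class {self.label!r}")


def classify_topology(rooted_ingroup_tree: Clade,
                      taxa: Sequence[str] = DEFAULT_TAXA) -> TopologyClass:
    """Classify a rooted ingroup tree on the four non-outgroup taxa.

    Invariant to branch lengths and tip order; total over all 15 rooted
    four-taxon shapes.
    """
    yp, h17, gal, pim = taxa[:4]
    tips = rooted_ingroup_tree.leaf_names()
    if tips != frozenset((yp, h17, gal, pim)):
        raise ValueError(f"expected tips {{{yp},{h17},{gal},{pim}}}, got {set(tips)}")
    clades = set(rooted_ingroup_tree.clades())
    lyc = frozenset((yp, h17))
    if lyc in clades:
        if frozenset((yp, h17, gal)) in clades:
            return TopologyClass("T1")
        if frozenset((yp, h17, pim)) in clades:
            return TopologyClass("T3")
        return TopologyClass("T2")
    if frozenset((h17, pim)) in clades:
        return TopologyClass("INTROG_H1706")
    if frozenset((yp, pim)) in clades:
        return TopologyClass("INTROG_YP")
    return TopologyClass("OTHER")


# ---------------------------------------------------------------------------
# Genome-scale summaries


@dataclass
class ScanWindow:
    chrom: str
    start: int
    end: int
    label: str
    support: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeScanResult:
    windows: list  # of ScanWindow, coordinate-sorted per chromosome

    def __post_init__(self):
        self.windows = sorted(self.windows, key=lambda w: (w.chrom, w.start))
        for a, b in zip(self.windows, self.windows[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError("overlapping windows in scan result")

    @property
    def total_bp(self) -> int:
        return sum(w.length for w in self.windows)


def classify_scan(results, outgroup: str = "TUB") -> GenomeScanResult:
    """Label every fitted window of a genome scan.

    Unresolved fits map to UNRESOLVED; resolved fits are rooted with the
    outgroup and classified.
    """
    wins = []
    for r in results:
        if r.status != "resolved" or r.best_topology is None:
            label, support = "UNRESOLVED", float("nan")
        else:
            label = classify_topology(r.rooted_ingroup(outgroup), r.taxa).label
            support = float(r.support[r.best_topology - 1])
        wins.append(ScanWindow(r.chrom, r.start, r.end, label, support))
    return GenomeScanResult(wins)


def summarize_fractions(scan: GenomeScanResult,
                        support_threshold: float = 0.9) -> pd.DataFrame:
    """Two genome tabulations per topology class.

    ``frac_passing``: fraction of the genome in windows of the class whose
    best-topology support passes the threshold (UNRESOLVED excluded from
    passing). ``frac_best``: fraction by best-supported class regardless of
    support — these sum to exactly 1 over all classes including
    OTHER/UNRESOLVED. Locus counts accompany both.
    """
    if not scan.windows:
        raise ValueError("empty genome scan")
    total = scan.total_bp
    rows = []
    for label in LABELS:
        wins = [w for w in scan.windows if w.label == label]
        bp_best = sum(w.length for w in wins)
        passing = [w for w in wins
                   if label != "UNRESOLVED" and w.support >= support_threshold]
        rows.append({
            "class": label,
            "n_loci_best": len(wins),
            "frac_best": bp_best / total,
            "n_loci_passing": len(passing),
            "frac_passing": sum(w.length for w in passing) / total,
        })
    return pd.DataFrame(rows).set_index("class")


# ---------------------------------------------------------------------------
# Tract calling


@dataclass
class IntrogressionTract:
    chrom: str
    start: int
    end: int
    n_windows: int
    mean_support: float
    label: str

    @property
    def length(self) -> int:
        return self.end - self.start


def call_tracts(scan: GenomeScanResult, target_class: str = "INTROG_H1706",
                support_threshold: float = 0.9, min_windows: int = 1,
                merge_gap: int = 1) -> list[IntrogressionTract]:
    """Merge runs of target-class windows into tracts.

    Consecutive target windows separated by at most ``merge_gap``
    non-target windows join one tract; tracts with fewer than
    ``min_windows`` target windows are dropped. Tract support is the
    length-weighted mean over its target windows.
    """
    tracts: list[IntrogressionTract] = []
    by_chrom: dict[str, list[ScanWindow]] = {}
    for w in scan.windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        run: list[ScanWindow] = []
        gap = 0
        for w in by_chrom[chrom]:
            is_target = w.label == target_class and w.support >= support_threshold
            if is_target:
                run.append(w)
                gap = 0
            elif run:
                gap += 1
                if gap > merge_gap:
                    _flush(run, tracts, chrom, target_class, min_windows)
                    run, gap = [], 0
        _flush(run, tracts, chrom, target_class, min_windows)
    return tracts


def _flush(run, tracts, chrom, label, min_windows):
    if len(run) >= min_windows and run:
        lengths = np.array([w.length for w in run], float)
        supports = np.array([w.support for w in run], float)
        tracts.append(IntrogressionTract(
            chrom, run[0].start, run[-1].end, len(run),
            float((lengths * supports).sum() / lengths.sum()), label))
    run.clear()


def tracts_to_bed(tracts: Iterable[IntrogressionTract], path) -> None:
    from . import io as dio
    dio.write_bed([(t.chrom, t.start, t.end,
                    f"{t.label};n={t.n_windows};support={t.mean_support:.3f}")
                   for t in tracts], path)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|) for two half-open intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


# ---------------------------------------------------------------------------
# Feature densities


def feature_density(features, window_size: int = 1_000_000,
                    chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-window feature counts and densities.

    ``features`` is an iterable of (chrom, pos) points or
    (chrom, start, end) spans; a span counts in the window containing its
    start. Windows tile [0, L) per chromosome, L from ``chrom_lengths`` or
    the maximum feature coordinate. Features beyond a declared chromosome
    end are clipped into the last window with a warning.
    """
    import warnings

    pts: dict[str, list[int]] = {}
    for f in features:
        chrom, pos = f[0], int(f[1])
        pts.setdefault(chrom, []).append(pos)
    lengths = dict(chrom_lengths or {})
    for chrom, pp in pts.items():
        lengths.setdefault(chrom, max(pp) + 1)
    rows = []
    for chrom in sorted(lengths):
        L = lengths[chrom]
        n_win = max(1, -(-L // window_size))
        counts = np.zeros(n_win, int)
        for pos in pts.get(chrom, []):
            if pos >= L:
                warnings.warn(f"feature at {chrom}:{pos} beyond chromosome end; clipped")
                pos = L - 1
            counts[pos // window_size] += 1
        for i, c in enumerate(counts):
            s, e = i * window_size, min((i + 1) * window_size, L)
            rows.append({"chrom": chrom, "start": s, "end": e,
                         "count": int(c), "density": c / (e - s)})
    return pd.DataFrame(rows)


def density_to_bedgraph(df: pd.DataFrame, path, column: str = "count") -> None:
    from . import io as dio
    dio.write_bedgraph(df[["chrom", "start", "end", column]].itertuples(index=False),
                       path)
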