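"""Rule-based deletion calling from coverage tracks.

The rules: a deletion candidate is a maximal zero-coverage run longer
than 15 bp, not on chromosome 0; candidates overlapping assembly gaps in
the reference (or gaps recovered by self-mapping the reference line) are
removed outright; a candidate is *confirmed* only if no de novo contig
with acceptable identity (>= 90%) maps over it — otherwise the region is
divergent rather than deleted. A gene is called deleted when at least 90%
of its span lies inside confirmed deletions, every contig hit to it
covers less than 50% of the gene, and no reciprocal-best contig hit
exists.

Interval arithmetic is implemented here directly on sorted half-open
(start, end) pairs — the data volumes are tiny and the per-base oracle in
the test suite pins the semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MIN_GAP_LEN = 16          # "greater than 15 base pairs"
MIN_CONTIG_IDENTITY = 90.0
GENE_CONTAINMENT = 0.9
GENE_RESCUE_COVERAGE = 0.5


# ---------------------------------------------------------------------------
# Interval primitives (sorted half-open intervals on one chromosome)


def merge_intervals(ivs: Iterable[Sequence[int]]) -> list[tuple[int, int]]:
    """Union of intervals: sorted, non-overlapping, adjacent runs merged."""
    ivs = sorted((int(s), int(e)) for s, e in ivs if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(ivs: Iterable[Sequence[int]]) -> int:
    return sum(e - s for s, e in merge_intervals(ivs))


def overlap_length(a: Sequence[int], ivs: Iterable[Sequence[int]]) -> int:
    """Total overlap of interval ``a`` with a set of intervals."""
    s0, e0 = int(a[0]), int(a[1])
    return sum(max(0, min(e0, e) - max(s0, s)) for s, e in merge_intervals(ivs))


def overlaps_any(a: Sequence[int], ivs: Iterable[Sequence[int]]) -> bool:
    s0, e0 = int(a[0]), int(a[1])
    return any(min(e0, e) > max(s0, s) for s, e in ivs)


def subtract_intervals(a: Iterable[Sequence[int]],
                       b: Iterable[Sequence[int]]) -> list[tuple[int, int]]:
    """Set difference a \\ b as merged intervals."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# Coverage tracks


@dataclass
class CoverageTrack:
    chrom: str
    runs: list  # RLE (start, end, depth), sorted, covering [0, L)

    def __post_init__(self):
        self.runs = sorted((int(s), int(e), d) for s, e, d in self.runs)
        prev = None
        for s, e, _ in self.runs:
            if e <= s:
                raise ValueError("empty coverage run")
            if prev is not None and s != prev:
                raise ValueError("coverage runs must tile the chromosome")
            prev = e

    @property
    def length(self) -> int:
        return self.runs[-1][1] if self.runs else 0

    @classmethod
    def from_bedgraph(cls, df: pd.DataFrame) -> dict[str, "CoverageTrack"]:
        return {chrom: cls(chrom, list(g[["start", "end", "value"]].itertuples(index=False)))
                for chrom, g in df.groupby("chrom")}


def _is_chrom0(chrom: str) -> bool:
    digits = "".join(c for c in chrom if c.isdigit())
    return digits != "" and int(digits) == 0


def zero_coverage_intervals(track: CoverageTrack,
                            min_len: int = MIN_GAP_LEN) -> list[tuple[int, int]]:
    """Maximal zero-depth runs of length >= min_len (i.e. > 15 bp with the
    default); chromosome 0 yields no candidates."""
    if _is_chrom0(track.chrom):
        return []
    zero = merge_intervals((s, e) for s, e, d in track.runs if d == 0)
    return [(s, e) for s, e in zero if e - s >= min_len]


def subtract_reference_gaps(candidates: Iterable[Sequence[int]],
                            ref_gaps: Iterable[Sequence[int]],
                            self_gaps: Iterable[Sequence[int]] = (),
                            mode: str = "remove") -> list[tuple[int, int]]:
    """Drop candidates that touch reference-assembly gaps or gaps from the
    reference line's self-mapping. ``mode='remove'`` (default) removes a
    candidate on any overlap; ``mode='trim'`` subtracts the gap bases
    instead."""
    gaps = merge_intervals(list(ref_gaps) + list(self_gaps))
    cands = merge_intervals(candidates)
    if mode == "remove":
        return [c for c in cands if not overlaps_any(c, gaps)]
    if mode == "trim":
        return subtract_intervals(cands, gaps)
    raise ValueError("mode must be 'remove' or 'trim'")


# ---------------------------------------------------------------------------
# Deletion calls


@dataclass
class DeletionCall:
    chrom: str
    start: int
    end: int
    confirmed: bool            # False = divergent (contig maps over it)
    genotype: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def _accepted_hits(contig_hits: pd.DataFrame,
                   min_identity: float = MIN_CONTIG_IDENTITY) -> pd.DataFrame:
    if contig_hits is None or len(contig_hits) == 0:
        return pd.DataFrame(columns=["contig", "chrom", "start", "end",
                                     "identity", "gene_id", "gene_coverage",
                                     "best", "reciprocal_best"])
    return contig_hits[contig_hits["identity"] >= min_identity]


def confirm_deletions(candidates: Iterable[Sequence[int]],
                      contig_hits: pd.DataFrame, chrom: str,
                      genotype: str = "",
                      min_identity: float = MIN_CONTIG_IDENTITY) -> list[DeletionCall]:
    """Confirmed iff no accepted (identity >= 90%) contig hit overlaps the
    candidate; otherwise the candidate is kept but marked divergent."""
    hits = _accepted_hits(contig_hits, min_identity)
    hits = hits[hits["chrom"] == chrom]
    hit_ivs = [(int(s), int(e)) for s, e in hits[["start", "end"]].itertuples(index=False)]
    out = []
    for s, e in merge_intervals(candidates):
        covered = overlaps_any((s, e), hit_ivs)
        out.append(DeletionCall(chrom, s, e, confirmed=not covered,
                                genotype=genotype))
    return out


@dataclass
class GeneDeletionCall:
    gene_id: str
    chrom: str
    containment: float
    n_contig_hits: int
    max_gene_coverage: float
    has_reciprocal_best: bool
    deleted: bool


def call_deleted_genes(genes: pd.DataFrame, deletions: Sequence[DeletionCall],
                       contig_hits: pd.DataFrame,
                       containment: float = GENE_CONTAINMENT,
                       rescue_coverage: float = GENE_RESCUE_COVERAGE,
                       min_identity: float = MIN_CONTIG_IDENTITY) -> list[GeneDeletionCall]:
    """Gene-level deletion flags.

    ``genes`` has columns (gene_id, chrom, start, end), 0-based half-open.
    Deleted ⇔ >= 90% of the gene span lies in confirmed deletions AND every
    accepted contig hit to the gene covers < 50% of it AND none is a
    reciprocal best hit.
    """
    del_by_chrom: dict[str, list] = {}
    for d in deletions:
        if d.confirmed:
            del_by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    hits = _accepted_hits(contig_hits, min_identity)
    out = []
    for row in genes.itertuples(index=False):
        glen = int(row.end) - int(row.start)
        if glen <= 0:
            raise ValueError(f"zero-length gene {row.gene_id}")
        ov = overlap_length((row.start, row.end), del_by_chrom.get(row.chrom, []))
        frac = ov / glen
        ghits = hits[hits["gene_id"] == row.gene_id]
        max_cov = float(ghits["gene_coverage"].max()) if len(ghits) else 0.0
        has_rbh = bool(ghits["reciprocal_best"].any()) if len(ghits) else False
        deleted = (frac >= containment and max_cov < rescue_coverage
                   and not has_rbh)
        out.append(GeneDeletionCall(row.gene_id, row.chrom, frac, len(ghits),
                                    max_cov, has_rbh, deleted))
    return out


def gap_size_histogram(deletions: Sequence[DeletionCall],
                       bin_width: int = 10) -> tuple[pd.DataFrame, tuple | None]:
    """Deletion-length histogram in fixed-width bins plus the modal bin."""
    lengths = [d.length for d in deletions]
    if not lengths:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"]), None
    top = (max(lengths) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    df = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                       "count": counts})
    mode = df.loc[df["count"].idxmax()]
    return df, (int(mode["bin_start"]), int(mode["bin_end"]))


def deletions_to_bed(deletions: Sequence[DeletionCall], path) -> None:
    from . import io as dio
    dio.write_bed([(d.chrom, d.start, d.end,
                    "deletion" if d.confirmed else "divergent")
                   for d in deletions], path)
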