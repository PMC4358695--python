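"""Windowed maximum-likelihood genome phylogenies for five taxa.

A whole-genome multiple alignment is partitioned into fixed reference
windows (100 kb by default) and, for every window, all 15 unrooted
five-taxon topologies are fitted by bounded quasi-Newton optimization of
branch lengths under JC69 (or HKY85 with a per-window kappa). Per-topology
weights exp(ℓ_i − ℓ_max)/Σ exp(ℓ_j − ℓ_max) play the role of posterior
probabilities under equal topology priors; an optional nonparametric
bootstrap (site resampling) gives frequency-based support instead.

Windows where any taxon exceeds a missing-data threshold, with too few
informative sites, or where the two best topologies tie within tolerance
are reported as ``unresolved`` — the analogue of loci whose topology
cannot be deduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (MISSING, NucleotideModel, encode_sequences, get_model,
                     HKY85)
from .pruning import TopologyLikelihood, compress_patterns, tip_partials
from .trees import (DEFAULT_TAXA, OUTGROUP, Clade, enumerate_topologies,
                    root_with_outgroup, topology_tree)

DEFAULT_WINDOW_SIZE = 100_000
MISSING_THRESHOLD = 0.8
TIE_TOL = 1e-6
MIN_INFORMATIVE = 4


@dataclass
class Block:
    chrom: str
    start: int
    seqs: dict  # taxon -> gapped sequence (equal lengths)
    ref: str    # taxon providing the reference coordinates

    @property
    def ref_len(self) -> int:
        s = self.seqs[self.ref]
        return len(s) - s.count("-")

    @property
    def end(self) -> int:
        return self.start + self.ref_len


@dataclass
class GenomeAlignment:
    blocks: list
    taxa: tuple

    def chromosomes(self) -> dict[str, int]:
        ext: dict[str, int] = {}
        for b in self.blocks:
            ext[b.chrom] = max(ext.get(b.chrom, 0), b.end)
        return ext


@dataclass
class WindowAlignment:
    chrom: str
    start: int
    end: int
    taxa: tuple
    codes: np.ndarray            # (5, n_aligned_columns), MISSING-coded
    missing_fraction: dict       # taxon -> fraction of the window span missing

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]


@dataclass
class WindowTreeResult:
    chrom: str
    start: int
    end: int
    taxa: tuple
    topologies: list                     # 15 canonical cherry-pair topologies
    logliks: np.ndarray                  # (15,)
    branch_lengths: np.ndarray           # (15, n_params)
    support: np.ndarray                  # (15,), sums to 1
    best_topology: int | None            # 1-based index into `topologies`
    status: str                          # "resolved" | "unresolved"
    n_sites: int = 0
    informative_sites: int = 0
    bootstrap_counts: np.ndarray | None = None

    def best_tree(self) -> Clade:
        i = (self.best_topology or 1) - 1
        return topology_tree(self.topologies[i], self.taxa,
                             self.branch_lengths[i][:7])

    def rooted_ingroup(self, outgroup: str = OUTGROUP) -> Clade:
        return root_with_outgroup(self.best_tree(), outgroup)


# ---------------------------------------------------------------------------
# MAF input


def read_maf(path, taxa: Sequence[str] | None = None) -> GenomeAlignment:
    """Read a MAF file into per-block gapped sequences.

    Sequence names must look like ``taxon.chrom``; the first s-line of each
    block anchors the reference coordinates. Blocks with fewer than two
    taxa are rejected; unknown taxa (when ``taxa`` given) are skipped with
    a warning and treated as missing for their span.
    """
    from Bio import AlignIO

    blocks = []
    seen: list[str] = []
    for aln in AlignIO.parse(str(path), "maf"):
        if len(aln) < 2:
            raise ValueError("MAF block with fewer than two sequences")
        seqs, ref_taxon, chrom, start = {}, None, None, None
        for rec in aln:
            name = rec.id
            taxon, _, src_chrom = name.partition(".")
            if taxa is not None and taxon not in taxa:
                warnings.warn(f"unknown taxon {taxon!r} in MAF; skipped")
                continue
            if ref_taxon is None:
                ref_taxon, chrom = taxon, src_chrom or "chr"
                start = int(rec.annotations.get("start", 0))
            seqs[taxon] = str(rec.seq).upper()
            if taxon not in seen:
                seen.append(taxon)
        if ref_taxon is None:
            continue
        blocks.append(Block(chrom, start, seqs, ref_taxon))
    order = tuple(taxa) if taxa is not None else tuple(seen)
    return GenomeAlignment(blocks, order)


def partition_windows(aln: GenomeAlignment,
                      window_size: int = DEFAULT_WINDOW_SIZE) -> list[WindowAlignment]:
    """Tile each chromosome with half-open windows of ``window_size`` on the
    reference coordinate system; a shorter terminal window is kept.
    """
    if window_size < 1000:
        raise ValueError("window_size must be at least 1000 bp")
    if not aln.blocks:
        return []
    taxa = aln.taxa
    out = []
    for chrom, length in sorted(aln.chromosomes().items()):
        chrom_blocks = [b for b in aln.blocks if b.chrom == chrom]
        for wstart in range(0, length, window_size):
            wend = min(wstart + window_size, length)
            cols, covered = [], np.zeros((len(taxa),), float)
            for b in chrom_blocks:
                if b.end <= wstart or b.start >= wend:
                    continue
                codes = encode_sequences([b.seqs.get(t, "") or "-" * len(next(iter(b.seqs.values())))
                                          for t in taxa])
                ref_row = np.frombuffer(b.seqs[b.ref].encode(), np.uint8)
                ref_cols = np.flatnonzero(ref_row != ord("-"))
                ref_pos = b.start + np.arange(ref_cols.size)
                sel = (ref_pos >= wstart) & (ref_pos < wend)
                cols.append(codes[:, ref_cols[sel]])
            if cols:
                codes = np.concatenate(cols, axis=1)
            else:
                codes = np.empty((len(taxa), 0), np.int8)
            span = wend - wstart
            present = (codes != MISSING).sum(axis=1)
            missing = {t: 1.0 - present[i] / span for i, t in enumerate(taxa)}
            out.append(WindowAlignment(chrom, wstart, wend, taxa, codes, missing))
    return out


# ---------------------------------------------------------------------------
# Per-window fit


def _informative_sites(patterns: np.ndarray, counts: np.ndarray) -> int:
    n = 0
    for j in range(patterns.shape[1]):
        col = patterns[:, j]
        col = col[col != MISSING]
        if col.size < 4:
            continue
        _, c = np.unique(col, return_counts=True)
        if (c >= 2).sum() >= 2:
            n += int(counts[j])
    return n


def _unresolved(window: WindowAlignment, topologies, n_params: int,
                reason: str) -> WindowTreeResult:
    k = len(topologies)
    return WindowTreeResult(window.chrom, window.start, window.end, window.taxa,
                            topologies, np.full(k, np.nan), np.zeros((k, n_params)),
                            np.full(k, 1.0 / k), None, "unresolved",
                            window.n_sites, 0)


def _fit_all_topologies(tips, counts, topologies, taxa, model, estimate_kappa,
                        tol: float = TIE_TOL, x0s=None):
    k = len(topologies)
    n_params = 7 + (1 if estimate_kappa else 0)
    logliks = np.full(k, -np.inf)
    params = np.zeros((k, n_params))
    starts = ([0.05] * 7, [0.01] * 7, [0.3] * 7)
    bounds = [(0.0, 10.0)] * 7 + ([(np.log(0.2), np.log(50.0))] if estimate_kappa else [])
    for i, pairs in enumerate(topologies):
        if estimate_kappa:
            jac = False
            def nll(x, _pairs=pairs):
                try:
                    m = HKY85(float(np.exp(x[7])), model.pi)
                    return -TopologyLikelihood(_pairs, taxa, tips, counts,
                                               m).loglik(x[:7])
                except FloatingPointError:
                    return 1e12
        else:
            jac = True
            tl = TopologyLikelihood(pairs, taxa, tips, counts, model)
            def nll(x, _tl=tl):
                try:
                    f, g = _tl.loglik_and_grad(x)
                except FloatingPointError:
                    return 1e12, np.zeros_like(x)
                return -f, -g
        best = None
        cand = []
        if x0s is not None:
            warm = np.asarray(x0s[i], float).copy()
            warm[:7] = np.clip(warm[:7], 1e-4, 10.0)
            cand.append(warm)
        cand += [np.array(list(s) + ([np.log(2.0)] if estimate_kappa else []))
                 for s in starts]
        for x0 in cand:
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds, tol=tol,
                           jac=jac)
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
        logliks[i] = -best.fun
        params[i] = best.x
    return logliks, params


def fit_window_tree(window: WindowAlignment, subst_model="jc69",
                    missing_threshold: float = MISSING_THRESHOLD,
                    min_informative: int = MIN_INFORMATIVE,
                    tie_tol: float = TIE_TOL,
                    bootstrap: int = 0, rng=None) -> WindowTreeResult:
    """Exhaustive 15-topology ML fit for one window.

    ``subst_model`` is a model name ("jc69" | "hky85") or a prebuilt
    :class:`NucleotideModel`. With "hky85", base frequencies are empirical
    and kappa is estimated per window as an eighth free parameter.
    """
    taxa = window.taxa
    topologies = enumerate_topologies(taxa)
    estimate_kappa = isinstance(subst_model, str) and subst_model.lower() == "hky85"
    if isinstance(subst_model, NucleotideModel):
        model = subst_model
    elif estimate_kappa:
        freqs = np.bincount(window.codes[window.codes != MISSING].ravel(),
                            minlength=4)[:4] + 1.0
        model = HKY85(2.0, freqs / freqs.sum())
    else:
        model = get_model(subst_model)
    n_params = 7 + (1 if estimate_kappa else 0)

    if any(f > missing_threshold for f in window.missing_fraction.values()):
        return _unresolved(window, topologies, n_params, "missing")
    patterns, counts = compress_patterns(window.codes)
    n_inf = _informative_sites(patterns, counts)
    if n_inf < min_informative:
        r = _unresolved(window, topologies, n_params, "uninformative")
        r.n_sites = window.n_sites
        r.informative_sites = n_inf
        return r

    tips = tip_partials(patterns)
    logliks, params = _fit_all_topologies(tips, counts, topologies, taxa,
                                          model, estimate_kappa)
    support = np.exp(logliks - logliks.max())
    support /= support.sum()
    order = np.argsort(logliks)[::-1]
    best = int(order[0])
    status = "resolved"
    if logliks[order[0]] - logliks[order[1]] < tie_tol:
        status = "unresolved"

    boot_counts = None
    if bootstrap:
        rng = np.random.default_rng(rng)
        boot_counts = np.zeros(len(topologies), int)
        n_total = int(counts.sum())
        p = counts / counts.sum()
        for _ in range(bootstrap):
            bc = rng.multinomial(n_total, p).astype(float)
            keep = bc > 0
            ll, _ = _fit_all_topologies(tips[:, :, keep], bc[keep], topologies,
                                        taxa, model, estimate_kappa)
            boot_counts[int(np.argmax(ll))] += 1

    return WindowTreeResult(window.chrom, window.start, window.end, taxa,
                            topologies, logliks, params, support,
                            best + 1, status, window.n_sites, n_inf,
                            boot_counts)


def scan_genome(aln: GenomeAlignment, window_size: int = DEFAULT_WINDOW_SIZE,
                subst_model="jc69", **fit_kw) -> list[WindowTreeResult]:
    """Partition and fit every window (the whole-genome scan)."""
    return [fit_window_tree(w, subst_model, **fit_kw)
            for w in partition_windows(aln, window_size)]


def results_table(results: Sequence[WindowTreeResult]) -> pd.DataFrame:
    """Tab-friendly summary: one row per window with per-topology support."""
    rows = []
    for r in results:
        row = {"chrom": r.chrom, "start": r.start, "end": r.end,
               "best_topology": r.best_topology if r.best_topology else 0,
               "status": r.status, "n_sites": r.n_sites,
               "informative_sites": r.informative_sites}
        for i, s in enumerate(r.support, 1):
            row[f"support_{i}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
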