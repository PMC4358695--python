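"""Synthetic five-taxon genomes under the multispecies coalescent.

The generator emulates the statistical structure of a cultivated-tomato
resequencing panel: a ladder species tree (((((YP,H1706),GAL),PIM),TUB)
by default), incomplete lineage sorting controlled by branch lengths in
coalescent units, optional donor→recipient introgression tracts modelled
as lineage replacement, and neutral sequence evolution under JC69/HKY85.
Windows are recombination-free internally and independent of each other,
so each 100 kb window carries exactly one gene tree — the same unit the
genome scan analyses.

All coordinates are 0-based half-open; all randomness flows through one
`numpy` generator derived from an explicit integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import io as dio
from .models import BASES, NucleotideModel, JC69
from .trees import Clade, DEFAULT_TAXA, root_with_outgroup, tree_from_tuples

# Default calibration: clock rate 6.03e-9 substitutions/site/year, one
# generation per year, split times in generations chosen to match the
# global-clock divergence dates of the clade (GAL ~0.2 MYA, PIM ~0.45 MYA,
# TUB ~11 MYA; the two cultivated lines split on the domestication
# timescale). Ne = 125,000 puts the GAL–PIM internal branch at T = 1
# coalescent unit, a regime with appreciable lineage sorting.
DEFAULT_MU = 6.03e-9
DEFAULT_NODE_TIMES = (10_000.0, 200_000.0, 450_000.0, 11_070_000.0)
DEFAULT_POP_SIZE = 125_000.0
DEFAULT_WINDOW = 100_000


class SpeciesNetworkModel:
    """Ladder species tree with divergence times, population sizes and clock.

    Parameters
    ----------
    taxa:
        Five labels, tip order along the ladder; the last is the outgroup.
    node_times:
        Four divergence times in generations before present, strictly
        increasing: (taxa[0],taxa[1]) split, then successive joins of
        taxa[2], taxa[3], taxa[4].
    pop_sizes:
        Diploid effective size, either a scalar for every branch or a dict
        keyed by branch name (tip labels, or "anc1".."anc4" for the
        ancestral branches above 2, 3, 4 and all 5 taxa).
    mu:
        Substitution rate per site per generation.
    recomb_free_window:
        Window length in bp within which a single gene tree applies.
    """

    ANC_NAMES = ("anc1", "anc2", "anc3", "anc4")

    def __init__(self, taxa: Sequence[str] = DEFAULT_TAXA,
                 node_times: Sequence[float] = DEFAULT_NODE_TIMES,
                 pop_sizes=DEFAULT_POP_SIZE,
                 mu: float = DEFAULT_MU,
                 recomb_free_window: int = DEFAULT_WINDOW):
        self.taxa = tuple(taxa)
        self.node_times = tuple(float(t) for t in node_times)
        if len(self.taxa) != 5 or len(set(self.taxa)) != 5:
            raise ValueError("exactly five distinct taxa required")
        if len(self.node_times) != 4:
            raise ValueError("four divergence times required")
        if not all(a < b for a, b in zip(self.node_times, self.node_times[1:])):
            raise ValueError("node_times must strictly increase tipward→rootward")
        if any(t <= 0 for t in self.node_times):
            raise ValueError("node_times must be positive")
        branches = list(self.taxa) + list(self.ANC_NAMES)
        if np.isscalar(pop_sizes):
            self.pop_sizes = {b: float(pop_sizes) for b in branches}
        else:
            self.pop_sizes = {b: float(pop_sizes[b]) for b in branches}
        if any(n <= 0 for n in self.pop_sizes.values()):
            raise ValueError("population sizes must be positive")
        if mu <= 0:
            raise ValueError("mu must be positive")
        self.mu = float(mu)
        self.recomb_free_window = int(recomb_free_window)

    @property
    def outgroup(self) -> str:
        return self.taxa[-1]

    @property
    def internal_branch_T(self) -> float:
        """GAL–PIM internodal branch length in coalescent units (2N gen)."""
        return (self.node_times[2] - self.node_times[1]) / (2 * self.pop_sizes["anc2"])

    @classmethod
    def with_internal_branch(cls, T: float, mu: float = 1e-8,
                             taxa: Sequence[str] = DEFAULT_TAXA,
                             recomb_free_window: int = DEFAULT_WINDOW,
                             tight: float = 1e-3) -> "SpeciesNetworkModel":
        """A model whose only appreciable lineage sorting happens on the
        internal branch between the third and fourth splits, with length T
        coalescent units there.

        Every other ancestral branch gets a tiny population (``tight`` ×
        the nominal size), so sister lineages coalesce essentially
        immediately — the regime in which the rooted-triple discordance
        formula 1 − (2/3)e^(−T) applies exactly.
        """
        N = 125_000.0
        t1, t2 = 50_000.0, 300_000.0
        t3 = t2 + T * 2 * N
        t4 = t3 + 2_000_000.0
        pops = {b: N for b in list(taxa) + list(cls.ANC_NAMES)}
        pops["anc1"] = N * tight   # (YP,H1706) coalesce before the GAL split
        pops["anc2"] = N           # the ILS dial
        pops["anc3"] = N * tight   # full coalescence before the outgroup joins
        return cls(taxa, (t1, t2, t3, t4), pops, mu, recomb_free_window)


@dataclass(frozen=True)
class IntrogressionEvent:
    """Donor→recipient lineage replacement over a genomic interval.

    For any window inside ``[start, end)`` on ``chrom``, the recipient's
    sampled lineage is placed in the donor population from the present
    backward, so it coalesces inside the donor's branch — the simplest
    mechanism producing a contiguous tract of donor-like topologies.
    """

    donor: str
    recipient: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if self.end <= self.start:
            raise ValueError("empty introgression interval")


@dataclass
class SimulatedGenome:
    """One synthetic chromosome of window-aligned blocks with truth labels."""

    chrom: str
    window_len: int
    windows: list  # (start, end, {taxon: seq})
    truth_windows: list  # per-window topology class label (truth)
    truth_tracts: list  # (chrom, start, end, donor, recipient)
    taxa: tuple
    seed: int
    model: SpeciesNetworkModel | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def length(self) -> int:
        return self.windows[-1][1] if self.windows else 0

    def maf_blocks(self):
        for start, _end, seqs in self.windows:
            yield self.chrom, start, seqs

    def write_maf(self, path) -> None:
        dio.write_maf(self.maf_blocks(), path, {self.chrom: self.length})

    def write_truth_tracts(self, path) -> None:
        dio.write_bed([(c, s, e, f"{d}->{r}") for c, s, e, d, r in self.truth_tracts], path)


# ---------------------------------------------------------------------------
# Coalescent gene trees


def sample_gene_tree(model: SpeciesNetworkModel, window_index: int,
                     events: Sequence[IntrogressionEvent] = (),
                     rng=None, n_windows: int | None = None,
                     chrom: str = "chr1") -> Clade:
    """One gene tree for a window under the structured coalescent.

    Returns a rooted coalescent tree whose branch lengths are expected
    substitutions per site (coalescent times in generations × mu).
    """
    rng = np.random.default_rng(rng)
    if window_index < 0 or (n_windows is not None and window_index >= n_windows):
        raise ValueError(f"window index {window_index} outside the genome")

    w0 = window_index * model.recomb_free_window
    w1 = w0 + model.recomb_free_window
    # effective starting population per tip (lineage replacement)
    start_pop = {t: t for t in model.taxa}
    for ev in events:
        if ev.chrom == chrom and ev.start < w1 and w0 < ev.end:
            if ev.donor not in model.taxa or ev.recipient not in model.taxa:
                raise ValueError("event taxa must be in the model")
            start_pop[ev.recipient] = ev.donor

    # lineages: pop name -> list of (Clade, node_time)
    lineages: dict[str, list[tuple[Clade, float]]] = {t: [] for t in model.taxa}
    for t in model.taxa:
        lineages[start_pop[t]].append((Clade(t), 0.0))

    def coalesce_in(pop: str, t_start: float, t_end: float):
        """Random pairwise coalescence in `pop` during [t_start, t_end)."""
        group = lineages[pop]
        N = model.pop_sizes[pop]
        t = t_start
        while len(group) > 1:
            k = len(group)
            rate = k * (k - 1) / 2.0 / (2.0 * N)
            t = t + rng.exponential(1.0 / rate)
            if t >= t_end:
                return
            i, j = rng.choice(k, size=2, replace=False)
            (a, ta), (b, tb) = group[i], group[j]
            a.length, b.length = (t - ta) * model.mu, (t - tb) * model.mu
            parent = Clade(None, 0.0, [a, b])
            group[:] = [g for n, g in enumerate(group) if n not in (i, j)]
            group.append((parent, t))

    # epoch walk up the ladder; times = (0, t1, t2, t3, t4)
    times = (0.0,) + model.node_times
    # epoch 0: tip populations (a donor tip may hold two lineages after
    # lineage replacement)
    for pop in model.taxa:
        coalesce_in(pop, 0.0, times[1])
    for k in range(1, 5):
        anc = f"anc{k}"
        t_end = times[k + 1] if k < 4 else np.inf
        sources = [model.taxa[0], model.taxa[1]] if k == 1 else [f"anc{k - 1}", model.taxa[k]]
        pool = []
        for src in sources:
            pool.extend(lineages.pop(src, []))
        lineages[anc] = pool
        # tip populations that merge further up keep coalescing this epoch
        for pop in list(lineages):
            if pop != anc and lineages[pop]:
                coalesce_in(pop, times[k], t_end)
        coalesce_in(anc, times[k], t_end)

    (root, t_root), = lineages["anc4"]
    root.length = 0.0
    return root


def concordance_probability(T: float) -> float:
    """P(rooted triple matches the species tree) for an internal branch of
    T coalescent units: 1 − (2/3)e^(−T)."""
    return 1.0 - (2.0 / 3.0) * np.exp(-T)


# ---------------------------------------------------------------------------
# Sequence evolution


def simulate_alignment(gene_tree: Clade, length_bp: int,
                       subst_model: NucleotideModel | None = None,
                       rng=None) -> dict[str, str]:
    """Evolve a gapless alignment down a gene tree.

    Ancestral sites are drawn from the model's equilibrium frequencies and
    substitutions applied branch-by-branch under the continuous-time model.
    Deterministic for a fixed seed.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be at least 1")
    if len(gene_tree.leaves()) < 2:
        raise ValueError("gene tree needs at least two tips")
    model = subst_model or JC69()
    rng = np.random.default_rng(rng)
    base = np.frombuffer("ACGT".encode(), np.uint8)

    root_states = rng.choice(4, size=length_bp, p=model.pi)
    out: dict[str, str] = {}

    def evolve(node: Clade, states: np.ndarray):
        for child in node.children:
            P = model.pmat(child.length)
            cum = P.cumsum(axis=1)
            u = rng.random(length_bp)
            new = (u[:, None] > cum[states]).sum(axis=1)
            if child.is_leaf:
                out[child.label] = base[new].tobytes().decode()
            else:
                evolve(child, new)

    evolve(gene_tree, root_states)
    return out


# ---------------------------------------------------------------------------
# Whole-genome synthesis


def _snap(ev: IntrogressionEvent, window_len: int) -> IntrogressionEvent:
    s = (ev.start // window_len) * window_len
    e = -(-ev.end // window_len) * window_len
    if (s, e) != (ev.start, ev.end):
        warnings.warn(f"introgression interval [{ev.start},{ev.end}) snapped "
                      f"outward to window boundaries [{s},{e})")
        return IntrogressionEvent(ev.donor, ev.recipient, ev.chrom, s, e)
    return ev


def synthesize_genome(model: SpeciesNetworkModel, n_windows: int,
                      window_len: int | None = None,
                      events: Sequence[IntrogressionEvent] = (),
                      rng_seed: int = 0, chrom: str = "chr1",
                      subst_model: NucleotideModel | None = None) -> SimulatedGenome:
    """Simulate ``n_windows`` independent windows on one chromosome.

    Each window gets one coalescent gene tree (honouring any introgression
    events overlapping it) and a JC69/HKY85 alignment of ``window_len`` bp.
    The truth label of a window is the topology class of its *true* gene
    tree, rooted with the outgroup.
    """
    from .discordance import classify_topology  # local import: avoid cycle

    if n_windows < 1:
        raise ValueError("n_windows must be at least 1")
    window_len = window_len or model.recomb_free_window
    model = SpeciesNetworkModel(model.taxa, model.node_times, model.pop_sizes,
                                model.mu, window_len)
    events = [_snap(ev, window_len) for ev in events]
    rng = np.random.default_rng(rng_seed)
    windows, labels = [], []
    for w in range(n_windows):
        tree = sample_gene_tree(model, w, events, rng, n_windows, chrom)
        seqs = simulate_alignment(tree, window_len, subst_model, rng)
        seqs = {t: seqs[t] for t in model.taxa}
        windows.append((w * window_len, (w + 1) * window_len, seqs))
        ingroup = root_with_outgroup(tree, model.outgroup)
        labels.append(classify_topology(ingroup, model.taxa).label)
    tracts = [(ev.chrom, ev.start, min(ev.end, n_windows * window_len),
               ev.donor, ev.recipient)
              for ev in events if ev.chrom == chrom and ev.start < n_windows * window_len]
    return SimulatedGenome(chrom, window_len, windows, labels, tracts,
                           model.taxa, rng_seed, model)


# Representative rooted trees per topology class, used by the mixture
# generator to plant known class fractions with a tunable signal strength.
_CLASS_SHAPES = {
    "T1": (((("YP", "H1706"), "GAL"), "PIM"), "TUB"),
    "T2": ((("YP", "H1706"), ("GAL", "PIM")), "TUB"),
    "T3": (((("YP", "H1706"), "PIM"), "GAL"), "TUB"),
    "INTROG_H1706": (((("H1706", "PIM"), "YP"), "GAL"), "TUB"),
    "INTROG_YP": (((("YP", "PIM"), "H1706"), "GAL"), "TUB"),
}


def synthesize_topology_mixture(fractions: dict[str, float], n_windows: int,
                                window_len: int = 1000,
                                branch_length: float = 0.05,
                                rng_seed: int = 0, chrom: str = "chr1",
                                subst_model: NucleotideModel | None = None) -> SimulatedGenome:
    """Windows whose true topologies are drawn i.i.d. from given class
    fractions, each simulated with every branch at ``branch_length``
    substitutions/site (large values = strong per-window signal).

    This bypasses the coalescent: it is the controlled-composition fixture
    for testing fraction recovery by the genome scan.
    """
    labels_avail = list(fractions)
    bad = set(labels_avail) - set(_CLASS_SHAPES)
    if bad:
        raise ValueError(f"unknown topology classes: {sorted(bad)}")
    p = np.asarray([fractions[l] for l in labels_avail], float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(rng_seed)
    draws = rng.choice(len(labels_avail), size=n_windows, p=p)
    windows, labels = [], []
    for w, d in enumerate(draws):
        label = labels_avail[d]
        tree = tree_from_tuples(_CLASS_SHAPES[label], branch_length)
        seqs = simulate_alignment(tree, window_len, subst_model, rng)
        seqs = {t: seqs[t] for t in DEFAULT_TAXA}
        windows.append((w * window_len, (w + 1) * window_len, seqs))
        labels.append(label)
    return SimulatedGenome(chrom, window_len, windows, labels, [],
                           tuple(DEFAULT_TAXA), rng_seed)


# ---------------------------------------------------------------------------
# Coverage / annotation fixtures for the structural-variant rules


@dataclass
class CoverageFixture:
    """Deterministic toy inputs for deletion calling."""

    chrom: str
    genome_len: int
    coverage: list          # RLE (start, end, depth)
    ref_gaps: list          # (start, end)
    genes: list             # (gene_id, start, end)
    contig_hits: "object"   # pandas DataFrame in contig-hit table layout

    def write(self, outdir) -> dict:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "coverage": outdir / "coverage.bedgraph",
            "ref_gaps": outdir / "ref_gaps.bed",
            "genes": outdir / "genes.gff3",
            "contig_hits": outdir / "contig_hits.tsv",
        }
        dio.write_bedgraph([(self.chrom, s, e, d) for s, e, d in self.coverage],
                           paths["coverage"])
        dio.write_bed([(self.chrom, s, e) for s, e in self.ref_gaps], paths["ref_gaps"])
        dio.write_gff3_genes([(g, self.chrom, s, e) for g, s, e in self.genes],
                             paths["genes"])
        dio.write_contig_hits(self.contig_hits, paths["contig_hits"])
        return paths


def coverage_fixture(deletions: Sequence[tuple[int, int]],
                     ref_gaps: Sequence[tuple[int, int]],
                     genome_len: int, depth: int = 20,
                     genes: Sequence[tuple[str, int, int]] = (),
                     contig_hits=None, chrom: str = "chr1") -> CoverageFixture:
    """Coverage equal to ``depth`` everywhere except zero inside deletions,
    plus reference-gap BED, toy gene models and an (optionally empty)
    contig-hit table. Overlapping deletion/ref-gap specs are allowed —
    downstream filters are responsible for subtracting them.
    """
    import pandas as pd

    zero = np.zeros(genome_len, bool)
    for s, e in deletions:
        if not (0 <= s < e <= genome_len):
            raise ValueError(f"deletion [{s},{e}) outside the genome")
        zero[s:e] = True
    cov = []
    boundaries = np.flatnonzero(np.diff(zero.astype(np.int8)) != 0) + 1
    edges = [0, *boundaries.tolist(), genome_len]
    for s, e in zip(edges, edges[1:]):
        cov.append((s, e, 0 if zero[s] else depth))
    if contig_hits is None:
        contig_hits = pd.DataFrame(columns=dio.CONTIG_HIT_COLUMNS)
    return CoverageFixture(chrom, genome_len, cov, [tuple(g) for g in ref_gaps],
                           [tuple(g) for g in genes], contig_hits)
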