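"""MAF parsing, window partitioning and per-window topology fitting."""

import numpy as np
import pytest

from conftest import genome_to_alignment
from discordia.io import write_maf
from discordia.models import MISSING
from discordia.msc_synth import synthesize_topology_mixture, simulate_alignment
from discordia.trees import DEFAULT_TAXA, topology_of_tree, tree_from_tuples
from discordia.window_scan import (Block, GenomeAlignment, WindowAlignment,
                                   fit_window_tree, partition_windows,
                                   read_maf, results_table, scan_genome)

TAXA = DEFAULT_TAXA


def write_simple_maf(path, blocks):
    write_maf(blocks, path)


def test_read_maf_single_block(tmp_path):
    seqs = {t: "ACGT" * 25 for t in TAXA}
    p = tmp_path / "one.maf"
    write_simple_maf(p, [("chr1", 0, seqs)])
    aln = read_maf(p)
    assert len(aln.blocks) == 1
    assert aln.taxa == TAXA
    assert aln.blocks[0].seqs["GAL"] == seqs["GAL"]


def test_maf_write_read_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    base = np.array(list("ACGT"))
    blocks = [("chr1", i * 200, {t: "".join(rng.choice(base, 200)) for t in TAXA})
              for i in range(3)]
    p = tmp_path / "rt.maf"
    write_simple_maf(p, blocks)
    aln = read_maf(p)
    assert [(b.chrom, b.start) for b in aln.blocks] == [(c, s) for c, s, _ in blocks]
    assert all(aln.blocks[i].seqs == blocks[i][2] for i in range(3))


def test_block_missing_taxon_marked_missing(tmp_path):
    seqs = {t: "ACGT" * 300 for t in TAXA if t != "TUB"}
    p = tmp_path / "m.maf"
    write_simple_maf(p, [("chr1", 0, seqs)])
    aln = read_maf(p, taxa=TAXA)
    assert len(aln.blocks) == 1
    wins = partition_windows(aln, 1200)
    assert wins[0].missing_fraction["TUB"] == pytest.approx(1.0)
    assert wins[0].missing_fraction["YP"] == pytest.approx(0.0)


def test_partition_250kb_into_three_windows():
    rng = np.random.default_rng(1)
    base = np.array(list("ACGT"))
    seqs = {t: "".join(rng.choice(base, 250_000)) for t in TAXA}
    aln = GenomeAlignment([Block("chr1", 0, seqs, "YP")], TAXA)
    wins = partition_windows(aln, 100_000)
    assert [(w.start, w.end) for w in wins] == [
        (0, 100_000), (100_000, 200_000), (200_000, 250_000)]


def test_partition_window_count_matches_counting_oracle():
    """Window count over a multi-chromosome block layout equals the
    per-chromosome tiling count sum(ceil(L_c / ws))."""
    rng = np.random.default_rng(2)
    base = np.array(list("ACGT"))
    layout = {"chr1": 7815, "chr2": 4000, "chr3": 1999}
    blocks = []
    for chrom, L in layout.items():
        pos = 0
        while pos < L:
            size = min(int(rng.integers(500, 1500)), L - pos)
            blocks.append(Block(chrom, pos,
                                {t: "".join(rng.choice(base, size)) for t in TAXA},
                                "YP"))
            pos += size
    aln = GenomeAlignment(blocks, TAXA)
    ws = 1000
    wins = partition_windows(aln, ws)
    oracle = sum(-(-L // ws) for L in layout.values())
    assert len(wins) == oracle


def test_partition_errors():
    with pytest.raises(ValueError):
        partition_windows(GenomeAlignment([], TAXA), 10)
    assert partition_windows(GenomeAlignment([], TAXA), 1000) == []


def test_fit_recovers_strong_topology():
    g = synthesize_topology_mixture({"T3": 1.0}, 1, window_len=2000,
                                    branch_length=0.08, rng_seed=3)
    wins = partition_windows(genome_to_alignment(g), 2000)
    r = fit_window_tree(wins[0])
    assert r.status == "resolved"
    assert r.support[r.best_topology - 1] > 0.99
    best = r.topologies[r.best_topology - 1]
    truth = topology_of_tree(
        tree_from_tuples((((("YP", "H1706"), "PIM"), "GAL"), "TUB"), 0.1))
    assert best == truth


def test_support_sums_to_one_and_table():
    g = synthesize_topology_mixture({"T1": 1.0}, 2, window_len=600,
                                    branch_length=0.05, rng_seed=5)
    res = scan_genome(genome_to_alignment(g), 1000)
    for r in res:
        assert r.support.sum() == pytest.approx(1.0, abs=1e-9)
    df = results_table(res)
    assert list(df["start"]) == [0, 1000]
    assert {c for c in df.columns if c.startswith("support_")} == \
        {f"support_{i}" for i in range(1, 16)}


def test_identical_sequences_unresolved_tie():
    codes = {t: "ACGT" * 300 for t in TAXA}
    win = WindowAlignment("chr1", 0, 1200, TAXA,
                          np.tile(np.array([[0, 1, 2, 3]], np.int8), (5, 300)),
                          {t: 0.0 for t in TAXA})
    r = fit_window_tree(win)
    assert r.status == "unresolved"


def test_gapped_window_unresolved():
    """A taxon missing beyond the threshold pre-sets the window unresolved."""
    g = synthesize_topology_mixture({"T1": 1.0}, 1, window_len=1000,
                                    branch_length=0.05, rng_seed=6)
    start, end, seqs = g.windows[0]
    seqs = dict(seqs)
    seqs["PIM"] = "-" * 850 + seqs["PIM"][850:]
    aln = GenomeAlignment([Block("chr1", 0, seqs, "YP")], TAXA)
    win = partition_windows(aln, 1000)[0]
    assert win.missing_fraction["PIM"] > 0.8
    r = fit_window_tree(win)
    assert r.status == "unresolved"
    assert r.best_topology is None
    assert r.support.sum() == pytest.approx(1.0)


def test_too_few_informative_sites_unresolved():
    codes = np.zeros((5, 1000), np.int8)
    codes[0, 0] = 1  # a single singleton
    win = WindowAlignment("chr1", 0, 1000, TAXA, codes, {t: 0.0 for t in TAXA})
    assert fit_window_tree(win).status == "unresolved"


def test_support_monotone_in_signal():
    """Appending sites generated under the same topology does not decrease
    the support of that topology (paired simulation)."""
    gains = []
    for seed in range(6):
        g = synthesize_topology_mixture({"T3": 1.0}, 1, window_len=600,
                                        branch_length=0.02, rng_seed=seed)
        start, end, seqs = g.windows[0]
        short = {t: s[:200] for t, s in seqs.items()}
        aln_s = GenomeAlignment([Block("chr1", 0, short, "YP")], TAXA)
        aln_l = GenomeAlignment([Block("chr1", 0, dict(seqs), "YP")], TAXA)
        r_s = fit_window_tree(partition_windows(aln_s, 1000)[0])
        r_l = fit_window_tree(partition_windows(aln_l, 1000)[0])
        truth = topology_of_tree(
            tree_from_tuples((((("YP", "H1706"), "PIM"), "GAL"), "TUB"), 0.1))
        i = r_s.topologies.index(truth)
        gains.append(r_l.support[i] - r_s.support[i])
    assert np.mean(gains) > 0


def test_hky_model_window_fit():
    g = synthesize_topology_mixture({"T1": 1.0}, 1, window_len=1500,
                                    branch_length=0.06, rng_seed=9)
    win = partition_windows(genome_to_alignment(g), 1500)[0]
    r = fit_window_tree(win, subst_model="hky85")
    assert r.status == "resolved"
    truth = topology_of_tree(
        tree_from_tuples((((("YP", "H1706"), "GAL"), "PIM"), "TUB"), 0.1))
    assert r.topologies[r.best_topology - 1] == truth
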