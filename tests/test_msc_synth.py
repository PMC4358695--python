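"""The coalescent generator: closed-form topology frequencies, sequence
evolution sanity, determinism, planted tracts and fixtures."""

import numpy as np
import pytest
from scipy.stats import binomtest

from discordia.discordance import classify_topology
from discordia.msc_synth import (IntrogressionEvent, SpeciesNetworkModel,
                                 concordance_probability, coverage_fixture,
                                 sample_gene_tree, simulate_alignment,
                                 synthesize_genome, synthesize_topology_mixture)
from discordia.structvar import (CoverageTrack, subtract_reference_gaps,
                                 zero_coverage_intervals)
from discordia.trees import Clade, root_with_outgroup, tree_from_tuples


def topology_counts(model, n, seed):
    rng = np.random.default_rng(seed)
    counts = {}
    for _ in range(n):
        g = sample_gene_tree(model, 0, (), rng)
        lab = classify_topology(root_with_outgroup(g, "TUB")).label
        counts[lab] = counts.get(lab, 0) + 1
    return counts


def test_model_validation():
    with pytest.raises(ValueError):
        SpeciesNetworkModel(node_times=(2, 1, 3, 4))  # not increasing
    with pytest.raises(ValueError):
        SpeciesNetworkModel(pop_sizes=0.0)
    with pytest.raises(ValueError):
        SpeciesNetworkModel(mu=-1e-9)
    m = SpeciesNetworkModel()
    assert m.internal_branch_T == pytest.approx(1.0)


def test_concordance_matches_pamilo_nei_closed_form():
    """P(concordant rooted triple) = 1 - (2/3)exp(-T) at T = 1."""
    n = 10_000
    counts = topology_counts(SpeciesNetworkModel.with_internal_branch(1.0), n, 7)
    p = concordance_probability(1.0)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(counts["T1"] / n - p) < 3 * se


def test_minor_topologies_equal_under_pure_ils():
    """The two lineage-sorting minor topologies are exchangeable: a
    two-sided binomial test on their split does not reject at alpha=0.01.

    This is also the null of the heirloom-control logic: with no planted
    events the introgression-like classes arise equally often."""
    counts = topology_counts(SpeciesNetworkModel.with_internal_branch(0.3), 10_000, 11)
    t2, t3 = counts.get("T2", 0), counts.get("T3", 0)
    assert binomtest(t2, t2 + t3, 0.5).pvalue > 0.01


def test_no_ils_limit():
    counts = topology_counts(SpeciesNetworkModel.with_internal_branch(30.0), 300, 3)
    assert counts == {"T1": 300}


def test_introgressed_window_groups_donor_and_recipient():
    """Lineage replacement with long post-event branches yields the
    donor-recipient cherry with frequency -> 1."""
    m = SpeciesNetworkModel.with_internal_branch(3.0, tight=1e-4)
    ev = IntrogressionEvent("PIM", "H1706", "chr1", 0, m.recomb_free_window)
    rng = np.random.default_rng(5)
    labs = []
    for _ in range(200):
        g = sample_gene_tree(m, 0, [ev], rng)
        labs.append(classify_topology(root_with_outgroup(g, "TUB")).label)
    assert np.mean([l == "INTROG_H1706" for l in labs]) > 0.9


def test_sample_gene_tree_errors():
    m = SpeciesNetworkModel()
    with pytest.raises(ValueError, match="outside"):
        sample_gene_tree(m, 10, (), 0, n_windows=10)
    with pytest.raises(ValueError, match="differ"):
        IntrogressionEvent("PIM", "PIM", "chr1", 0, 1000)


def test_jc_divergence_matches_expectation():
    """Two taxa at total distance d: P(diff) = (3/4)(1 - exp(-4d/3))."""
    d = 0.1
    tree = Clade(None, 0.0, [Clade("A", 0.0), Clade("B", d)])
    L = 100_000
    seqs = simulate_alignment(tree, L, rng=1)
    p = sum(a != b for a, b in zip(seqs["A"], seqs["B"])) / L
    expected = 0.75 * (1 - np.exp(-4 * d / 3))
    assert abs(p - expected) < 3 * np.sqrt(expected * (1 - expected) / L)


def test_zero_branch_lengths_identical_sequences():
    tree = tree_from_tuples((("A", "B"), ("C", "D")), 0.0)
    seqs = simulate_alignment(tree, 500, rng=2)
    assert len(set(seqs.values())) == 1


def test_alignment_seed_determinism():
    tree = tree_from_tuples((("A", "B"), ("C", "D")), 0.1)
    assert simulate_alignment(tree, 300, rng=9) == simulate_alignment(tree, 300, rng=9)


def test_simulate_alignment_errors():
    tree = tree_from_tuples(("A", "B"), 0.1)
    with pytest.raises(ValueError):
        simulate_alignment(tree, 0)
    with pytest.raises(ValueError):
        simulate_alignment(Clade("A"), 100)
    bad = tree_from_tuples(("A", "B"), -0.1)
    with pytest.raises(ValueError, match="negative"):
        simulate_alignment(bad, 100)


def test_genome_maf_byte_determinism(tmp_path):
    m = SpeciesNetworkModel.with_internal_branch(1.0, recomb_free_window=500)
    for name in ("a.maf", "b.maf"):
        synthesize_genome(m, 6, 500, rng_seed=42).write_maf(tmp_path / name)
    assert (tmp_path / "a.maf").read_bytes() == (tmp_path / "b.maf").read_bytes()


def test_planted_tract_truth_labels():
    """Every window of a planted tract is introgression-type in truth."""
    W = 500
    m = SpeciesNetworkModel.with_internal_branch(3.0, tight=1e-4,
                                                 recomb_free_window=W)
    ev = IntrogressionEvent("PIM", "H1706", "chr1", 3 * W, 13 * W)
    g = synthesize_genome(m, 20, W, [ev], rng_seed=8)
    in_tract = [l for i, l in enumerate(g.truth_windows) if 3 <= i < 13]
    assert np.mean([l == "INTROG_H1706" for l in in_tract]) > 0.8
    assert g.truth_tracts == [("chr1", 3 * W, 13 * W, "PIM", "H1706")]


def test_event_interval_snapped_outward():
    m = SpeciesNetworkModel.with_internal_branch(1.0, recomb_free_window=500)
    ev = IntrogressionEvent("PIM", "H1706", "chr1", 750, 1100)
    with pytest.warns(UserWarning, match="snapped"):
        g = synthesize_genome(m, 5, 500, [ev], rng_seed=1)
    assert g.truth_tracts[0][1:3] == (500, 1500)


def test_mixture_generator_truth_fractions():
    fr = {"T1": 0.7, "T3": 0.2, "T2": 0.1}
    n = 1000
    g = synthesize_topology_mixture(fr, n, window_len=50, rng_seed=4)
    labels, counts = np.unique(g.truth_windows, return_counts=True)
    got = dict(zip(labels, counts / n))
    for k, p in fr.items():
        assert abs(got.get(k, 0) - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_coverage_fixture_rules():
    fx = coverage_fixture(deletions=[(100, 200)], ref_gaps=[], genome_len=1000)
    track = CoverageTrack(fx.chrom, fx.coverage)
    assert zero_coverage_intervals(track) == [(100, 200)]

    # a deletion nested in a reference gap leaves no candidates downstream
    fx2 = coverage_fixture(deletions=[(100, 150)], ref_gaps=[(80, 200)],
                           genome_len=1000)
    cands = zero_coverage_intervals(CoverageTrack(fx2.chrom, fx2.coverage))
    assert subtract_reference_gaps(cands, fx2.ref_gaps) == []

    # a 10 bp deletion is present in the track but filtered downstream
    fx3 = coverage_fixture(deletions=[(500, 510)], ref_gaps=[], genome_len=1000)
    assert (500, 510, 0) in fx3.coverage
    assert zero_coverage_intervals(CoverageTrack(fx3.chrom, fx3.coverage)) == []


def test_coverage_fixture_roundtrip(tmp_path):
    fx = coverage_fixture([(50, 80)], [(10, 20)], 200,
                          genes=[("g1", 40, 90)])
    paths = fx.write(tmp_path)
    from discordia import io as dio
    cov = dio.read_bedgraph(paths["coverage"])
    assert int(cov[cov.value == 0].iloc[0].start) == 50
    genes = dio.read_gff3_genes(paths["genes"])
    assert genes.iloc[0].tolist() == ["g1", "chr1", 40, 90]
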