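# Methods

`discordia` re-creates, at desk scale, the computational chain used to
dissect phylogenetic discordance among cultivated tomato (*Solanum
lycopersicum*: the reference line H1706 and the heirloom 'Yellow Pear',
YP) and its close wild relatives (*S. galapagense*, GAL;
*S. pimpinellifolium*, PIM) with potato (*S. tuberosum*, TUB) as the
outgroup. This note records the models, the defaults and the design
choices, and what the synthetic data do and do not establish.

## The species model and the coalescent generator

The species history is a ladder tree ((((YP,H1706),GAL),PIM),TUB) with
divergence times in generations, a diploid effective population size per
branch, and a substitution rate `mu` per site per generation
(`SpeciesNetworkModel`). Defaults are calibrated from the global
molecular clock used throughout the package (6.03e-9 synonymous
substitutions per site per year, one generation per year): splits at
10 kyr (the two cultivated lines), 0.2 Myr (GAL), 0.45 Myr (PIM) and
11.07 Myr (TUB), matching the clock dates the pipeline itself produces
from the printed pairwise dS values. With Ne = 125,000 on every branch,
the internal branch between the GAL and PIM splits is T = 1 coalescent
unit — a regime with substantial incomplete lineage sorting (ILS).
Population sizes and generation time for tomato are calibration choices,
not inferences; nothing downstream depends on their absolute values,
only on branch lengths in coalescent units and substitutions.

Gene trees are drawn one per window under the multispecies coalescent:
one lineage per taxon, pairwise coalescence at rate 1/(2Ne) within each
species-tree branch, lineages pooled at each split. Windows are
recombination-free inside and independent of each other — the same
"one tree per locus" treatment the windowed genome scan assumes. For a
rooted triple separated by an internal branch of T coalescent units the
probability that the gene tree matches the species tree is
1 − (2/3)e^(−T), with the two minor resolutions equally likely at
(1/3)e^(−T) each; `SpeciesNetworkModel.with_internal_branch(T)` builds a
model in which this closed form holds exactly (all other internal
branches effectively coalesce instantly), and the test suite checks the
simulator against it at T ∈ {0.5, 1, 2}.

Introgression is modelled as **lineage replacement**: for windows inside
a donor→recipient tract, the recipient's sampled lineage starts in the
donor population and coalesces there. This is the simplest mechanism
that produces contiguous runs of donor-like topologies (the tract
signature) without introducing a migration-rate parameter; its
per-window penetrance grows with the donor branch length in coalescent
units. Truth labels record the class of the *true* gene tree per
window, so weak-signal regimes are honestly labelled.

Sequences evolve along the gene tree under JC69 (or HKY85) with
ancestral states at equilibrium; branch lengths are coalescent times
times `mu`. A second generator, `synthesize_topology_mixture`, bypasses
the coalescent and draws each window's topology i.i.d. from prescribed
class fractions with a uniform branch length — the controlled
composition used to test fraction recovery.

What the generator does **not** emulate: intra-window recombination,
indels and alignment error, within-taxon heterozygosity, rate variation
across sites and branches, demographic change, and base-compositional
heterogeneity. Passing tests therefore demonstrate correctness of the
inference machinery under its own model assumptions, not robustness to
real-data artifacts.

## Windowed genome phylogenies

The whole-genome alignment (MAF) is tiled into fixed reference windows
(100 kb by default; shorter terminal windows are kept). For each window
all 15 unrooted five-taxon topologies are fitted exhaustively: branch
lengths (7 per topology) are optimized by bounded L-BFGS-B with analytic
gradients (dP/dt = QP) to tolerance 1e-6, under JC69 by default or HKY85
with per-window empirical base frequencies and an estimated kappa. The
per-topology weight exp(ℓ_i − ℓ_max)/Σ_j exp(ℓ_j − ℓ_max) is reported as
an approximate posterior under equal topology priors. This replaces
per-locus Bayesian MCMC: at five taxa the topology space is enumerable,
the decision surface (which topology is best, and whether its weight
clears 0.9) is the same, and the whole computation is deterministic and
testable against a brute-force state-enumeration oracle. Site
resampling (nonparametric bootstrap) is available as an alternative
support measure.

A window is `unresolved` when any taxon exceeds 80% missing data in the
window span (the threshold is configurable; the source analysis reports
undeducible loci without stating a cutoff), when fewer than 4
parsimony-informative sites remain, or when the top two topology
log-likelihoods tie within 1e-6.

Trees are rooted on the outgroup (TUB) by placing the root at the
attachment node of the outgroup branch, which preserves all ingroup
branch lengths exactly.

## Topology classes, fractions and tracts

Rooted four-taxon ingroup trees map to: T1 (((YP,H1706),GAL),PIM) — the
species topology; T2 ((YP,H1706),(GAL,PIM)); T3 (((YP,H1706),PIM),GAL);
INTROG_H1706 (PIM sister to H1706, the cultivated cherry broken);
INTROG_YP (PIM sister to YP); OTHER (cherry broken without a PIM
pairing); UNRESOLVED. The map is total over all 15 rooted shapes and
invariant to branch lengths. Under pure ILS the two introgression-like
classes are exchangeable, which is exactly why the heirloom line works
as a negative control: a genuine wild introgression into the reference
line shows up as an excess of INTROG_H1706 windows.

Genome summaries are tabulated two ways, because both framings are
standard: the fraction of the genome whose windows *best support* each
class (these sum to 1), and the fraction in windows whose support also
clears a threshold (0.9 by default). Both bp-weighted fractions and
locus counts are emitted, since with equal window sizes they coincide
and with ragged terminal windows they need not.

Tract calling merges maximal runs of target-class, threshold-passing
windows, bridging at most `merge_gap` interrupting windows (default 1)
and requiring at least `min_windows` hits; support is the
length-weighted mean. The merging parameters are deliberately
configurable — the source analysis reports loci, not a merging rule.

## Molecular evolution of coding sequence

Coding alignments must be in frame; terminal stop codons are trimmed,
any internal stop rejects the gene, and gap/ambiguous codons are masked
and excluded pairwise.

Pairwise rates come from two estimators. `ng86` is Nei–Gojobori
counting: synonymous site fractions per codon (changes to stops count as
nonsynonymous, so N + S = 3L), multi-hit differences averaged over all
minimal substitution pathways excluding those through stops, and a
Jukes–Cantor correction of pN and pS. `ml_pairwise` maximizes the
likelihood of (t, kappa, omega) under a Goldman–Yang codon model on the
61 sense codons with F1x4 frequencies estimated from the data; dN and dS
derive from the fitted rate-flow decomposition (so dN/dS equals the
fitted omega identically). Genes with dS = 0 get an undefined omega and
are flagged rather than averaged; fitted omega > 99 is flagged as
overflow, mirroring the usual reporting convention for such tables.
At low divergence (t ≤ 0.3) the two estimators agree within 20%
relative error on simulated data; counting is expected to sit below the
ML value when kappa > 1 because it ignores the transition bias when
counting sites.

Gene trees per gene use the same exhaustive 15-topology engine under the
Kimura two-parameter model with 100 site-resampling bootstrap
replicates; a topology is "supported" at ≥ 75/100.

The branch-site test fits model A on the species tree with the stem of
the cultivated (YP,H1706) clade as the foreground branch: site classes
with 0 < omega0 ≤ 1 and omega1 = 1 in the background, plus foreground
classes with omega2 ≥ 1 free (alternative) or fixed at 1 (null). Two
numerical choices keep the test fast and honestly nested: branch lengths
and kappa are estimated once under a single-omega model and then held
fixed during both site-class optimizations (a standard two-phase
scheme), and the alternative optimization starts from the null optimum,
with omega2 = 1 lying in the closure of the alternative so
lnL_alt ≥ lnL_null always. Site-class rate matrices share a *neutral*
time scale (normalized by the omega = 1 rate) so that a positively
selected class genuinely evolves faster rather than merely shifting its
substitution spectrum. The statistic 2Δℓ is referred to the boundary
null — a 50:50 mixture of a point mass at 0 and chi-square(1) — whose 5%
critical value is 2.705 ≈ 2.71; the test is conservative by
construction, and the simulated type-I error at 100-codon alignments
sits well below 5%. Bayes Empirical Bayes identification of the
selected sites is out of scope.

Divergence dates follow the global clock T = dS/(2·mu) with
mu = 6.03e-9/site/year, reported in MYA rounded half-up to two decimals.
Applied to the printed pairwise dS table this reproduces 0.44, 1.38 and
11.07 MYA; the smallest entry (dS = 0.0024) yields 0.1990 → 0.20 MYA
under this formula while the original table prints 0.19, which implies
an unrounded upstream dS — the implementation follows the stated formula
and documents the discrepancy rather than matching the printed digit.

Ortholog pairs for these analyses pass a reciprocal-best-hit filter:
each sequence must be the other's single top-scoring hit (ties discard
the pair) with at least 50% coverage of the reference gene.

## Deletion calling

Deletion candidates are maximal zero-coverage runs longer than 15 bp,
excluding chromosome 0 (the unanchored bin). Candidates overlapping
reference-assembly gaps or gaps recovered by self-mapping the reference
line are removed whole — "matching gaps were removed" is ambiguous
between trimming and removal; removal is the default and trimming is
available as a mode. A candidate is *confirmed* only if no de novo
contig hit at ≥ 90% identity overlaps it; otherwise the region is
classified divergent, not deleted. A gene is deleted when ≥ 90% of its
genomic span (full span, not exon union — the simplest reading) lies in
confirmed deletions, every contig hit to it covers < 50% of the gene,
and no reciprocal-best contig hit exists. The deletion-length histogram
(10 bp bins) reports the modal bin; on real data that mode sits at the
scaffolding-spacer length, which is an observation about the reference
assembly, not something derivable here.

Interval arithmetic is implemented directly on sorted half-open pairs
and pinned to a per-base boolean-array oracle by property tests.
Contaminant screening of unmapped contigs is reduced to an exclusion
list supplied by the caller; insertion prediction is out of scope.

## Problem sizes and numerical conventions

The test suite and the acceptance script use scaled problem sizes chosen
so every stage still exercises its full code path: 2,000 windows of
1 kb with strong per-window signal for fraction recovery, a 17-window
tract in a 500-window genome of 2 kb windows for tract recovery, 10,000
coalescent draws per closed-form check, 20 replicates of 5,000 codons
for dN/dS recovery, and 100 null replicates of 100 codons for the
branch-site calibration. Coordinates are 0-based half-open everywhere
except at the GFF3 boundary (1-based inclusive). All randomness flows
through explicitly seeded `numpy` generators; identical seeds give
byte-identical MAF output. Optimizer settings: L-BFGS-B, three fallback
starts, branch lengths bounded to [0, 10], kappa to [0.2, 50].

## Known limitations

- The likelihood-weight "posterior" equals a Bayesian posterior only
  under equal topology priors and a point estimate of branch lengths;
  it is sharper than an MCMC posterior on short windows.
- The branch-site implementation fixes branch lengths from the
  single-omega fit; severe among-gene rate variation would argue for
  joint re-optimization.
- Lineage replacement is an all-or-nothing introgression model; it
  cannot represent partial ancestry fractions within a window.
- The generator's independence between windows understates the spatial
  autocorrelation real recombination produces, so tract-boundary
  precision on real data will be worse than on synthetic genomes.
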