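"""Molecular evolution of coding sequence: pairwise dN/dS, gene-tree
bootstrap, a branch-site positive-selection test, and global-clock dating.

Pairwise rates come in two flavours: Nei–Gojobori counting with
Jukes–Cantor correction (``ng86``) and maximum likelihood under a
Goldman–Yang codon model with F1x4 frequencies (``ml_pairwise``). The
branch-site test compares model A (a class of sites with omega >= 1 on a
designated foreground branch) against the same model with that omega fixed
at 1; twice the log-likelihood difference is referred to the boundary null
(a 50:50 mixture of a point mass at zero and chi-square with 1 df), whose
5% critical value is 2.71. Divergence dates follow the global molecular
clock T = dS / (2 mu) with mu = 6.03e-9 synonymous substitutions per site
per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from . import codon as C
from .models import encode_sequences, K80
from .pruning import compress_patterns, tip_partials
from .trees import Clade, DEFAULT_TAXA, enumerate_topologies, tree_from_tuples
from .window_scan import _fit_all_topologies, _informative_sites

CLOCK_RATE = 6.03e-9  # synonymous substitutions per site per year
LRT_THRESHOLD = 2.71
BOOTSTRAP_SUPPORT_MIN = 75


class CdsRejected(ValueError):
    """Raised when a coding alignment fails validation."""


@dataclass
class CodonAlignment:
    taxa: tuple
    codes: np.ndarray  # (ntaxa, ncodons) sense-codon indices, -1 = masked

    @property
    def n_codons(self) -> int:
        return self.codes.shape[1]

    def pair(self, a: str, b: str) -> "CodonAlignment":
        ia, ib = self.taxa.index(a), self.taxa.index(b)
        return CodonAlignment((a, b), self.codes[[ia, ib]])

    def comparable_columns(self) -> np.ndarray:
        return self.codes[:, (self.codes >= 0).all(axis=0)]


def validate_cds(seqs: dict[str, str]) -> CodonAlignment:
    """Validate an in-frame coding alignment.

    Terminal stop codons are trimmed; any internal stop codon rejects the
    alignment; gap or ambiguous codons are masked. Lengths must be equal
    and divisible by three.
    """
    taxa = tuple(seqs)
    lens = {len(s) for s in seqs.values()}
    if len(lens) != 1:
        raise CdsRejected("sequences have unequal lengths")
    (L,) = lens
    if L % 3:
        raise CdsRejected("alignment length not divisible by 3")
    n = L // 3
    rows = []
    stop_at_end = False
    for t in taxa:
        s = seqs[t].upper()
        codons = [s[k:k + 3] for k in range(0, L, 3)]
        if codons and codons[-1] in C.STOPS:
            stop_at_end = True
        for k, cd in enumerate(codons[:-1]):
            if cd in C.STOPS:
                raise CdsRejected(f"premature stop codon {cd} at codon {k + 1} in {t}")
        rows.append(codons)
    if stop_at_end:
        n -= 1
        rows = [r[:-1] for r in rows]
    codes = np.full((len(taxa), n), -1, np.int64)
    for i, r in enumerate(rows):
        for k, cd in enumerate(r):
            if cd in C.STOPS:  # terminal column kept for some taxa
                raise CdsRejected(f"premature stop codon in {taxa[i]}")
            codes[i, k] = C.CODON_INDEX.get(cd, -1)
    return CodonAlignment(taxa, codes)


# ---------------------------------------------------------------------------
# Pairwise rates


@dataclass
class PairwiseRates:
    dN: float
    dS: float
    omega: float
    N_sites: float
    S_sites: float
    t: float = float("nan")
    kappa: float = float("nan")
    method: str = "ng86"
    flags: set = field(default_factory=set)


def ng86(pair: CodonAlignment) -> PairwiseRates:
    """Nei–Gojobori counting estimate with Jukes–Cantor correction.

    Sites are averaged over both sequences; multi-hit codon differences are
    averaged over all minimal substitution pathways, excluding pathways
    through stop codons.
    """
    cols = pair.comparable_columns()
    if cols.shape[1] < 10:
        raise ValueError("fewer than 10 comparable codons")
    a, b = cols
    S_a = sum(C.ng86_site_counts(int(i)) for i in a)
    S_b = sum(C.ng86_site_counts(int(i)) for i in b)
    S = 0.5 * (S_a + S_b)
    N = 3.0 * cols.shape[1] - S
    Sd = Nd = 0.0
    for i, j in zip(a, b):
        s, n = C.ng86_path_counts(int(i), int(j))
        Sd += s
        Nd += n
    flags: set = set()
    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0
    dN = _jc(pN, flags, "dN_undefined")
    dS = _jc(pS, flags, "dS_undefined")
    if dS == 0.0:
        flags.add("dS_zero")
        omega = float("nan")
    elif np.isnan(dS):
        omega = float("nan")
    else:
        omega = dN / dS
        if omega > 99:
            flags.add("omega_overflow")
    return PairwiseRates(dN, dS, omega, N, S, method="ng86", flags=flags)


def _jc(p: float, flags: set, flag: str) -> float:
    if p >= 0.75:
        flags.add(flag)
        return float("nan")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def ml_pairwise(pair: CodonAlignment, kappa_init: float = 2.0,
                pi=None) -> PairwiseRates:
    """Maximum-likelihood (t, kappa, omega) under GY94 with F1x4 frequencies,
    with dN and dS from the fitted rate-flow decomposition."""
    cols = pair.comparable_columns()
    if cols.shape[1] < 10:
        raise ValueError("fewer than 10 comparable codons")
    if pi is None:
        nt = "".join(C.SENSE_CODONS[i] for i in cols.ravel())
        counts = np.array([nt.count(b) for b in "ACGT"], float) + 1.0
        pi = C.f1x4_frequencies(counts / counts.sum())
    pats, counts = np.unique(cols, axis=1, return_counts=True)
    i_idx, j_idx = pats
    w = counts.astype(float)

    if np.all(i_idx == j_idx):  # identical sequences: boundary optimum
        m = C.GY94(kappa_init, 1.0, pi)
        Nn, Ss = m.site_fractions()
        L = cols.shape[1]
        return PairwiseRates(0.0, 0.0, float("nan"), Nn * L, Ss * L, t=0.0,
                             kappa=kappa_init, method="ml",
                             flags={"dS_zero"})

    def nll(x):
        t, kappa, omega = np.exp(x)
        m = C.GY94(kappa, omega, pi)
        P = m.pmat(t)
        site = m.pi[i_idx] * P[i_idx, j_idx]
        if np.any(site <= 0) or not np.all(np.isfinite(site)):
            return 1e10
        return -float(w @ np.log(site))

    x0 = np.log([0.2, kappa_init, 0.5])
    bounds = [(np.log(1e-6), np.log(30.0)),
              (np.log(0.1), np.log(100.0)),
              (np.log(1e-6), np.log(1e4))]
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    flags: set = set()
    if not res.success:
        out = ng86(pair)
        out.flags.add("ml_failed")
        return out
    t, kappa, omega = np.exp(res.x)
    m = C.GY94(kappa, omega, pi)
    dN, dS = m.rates_from_t(t)
    Nn, Ss = m.site_fractions()
    L = cols.shape[1]
    if dS <= 1e-9:
        flags.add("dS_zero")
        omega_out = float("nan")
    else:
        omega_out = omega
        if omega_out > 99:
            flags.add("omega_overflow")
    return PairwiseRates(float(dN), float(dS), float(omega_out),
                         Nn * L, Ss * L, t=float(t), kappa=float(kappa),
                         method="ml", flags=flags)


# ---------------------------------------------------------------------------
# Gene trees with bootstrap


@dataclass
class GeneTreeResult:
    best_topology: tuple          # canonical cherry-pair topology
    bootstrap_count: int
    n_reps: int
    supported: bool
    counts: np.ndarray            # per-topology bootstrap counts (sum = n_reps)
    flags: set = field(default_factory=set)


def gene_tree_bootstrap(seqs: dict[str, str], n_reps: int = 100,
                        kappa: float = 2.0, rng=None,
                        taxa=DEFAULT_TAXA) -> GeneTreeResult:
    """ML topology over the 15 five-taxon trees under K80, with
    nonparametric (site-resampling) bootstrap support.

    ``supported`` means the best topology appears in at least 75 of 100
    (rescaled: 75%) replicates.
    """
    taxa = tuple(t for t in taxa if t in seqs)
    if len(taxa) != 5:
        raise ValueError("five taxa required")
    codes = encode_sequences([seqs[t] for t in taxa])
    pats, counts = compress_patterns(codes)
    topologies = enumerate_topologies(taxa)
    model = K80(kappa)
    flags: set = set()
    if _informative_sites(pats, counts) < 4:
        flags.add("uninformative")
    tips = tip_partials(pats)
    ll, params = _fit_all_topologies(tips, counts, topologies, taxa, model, False)
    best = int(np.argmax(ll))
    rng = np.random.default_rng(rng)
    n_total = int(counts.sum())
    p = counts / counts.sum()
    boot = np.zeros(len(topologies), int)
    for _ in range(n_reps):
        bc = rng.multinomial(n_total, p).astype(float)
        keep = bc > 0
        ll_b, _ = _fit_all_topologies(tips[:, :, keep], bc[keep], topologies,
                                      taxa, model, False, x0s=params)
        boot[int(np.argmax(ll_b))] += 1
    count = int(boot[best])
    supported = (count / n_reps) >= (BOOTSTRAP_SUPPORT_MIN / 100) and not flags
    return GeneTreeResult(topologies[best], count, n_reps, supported, boot, flags)


# ---------------------------------------------------------------------------
# Branch-site likelihood-ratio test


@dataclass
class BranchSiteResult:
    lnL_null: float
    lnL_alt: float
    stat: float
    significant: bool
    foreground: frozenset
    params_null: dict = field(default_factory=dict)
    params_alt: dict = field(default_factory=dict)


def branch_site_critical_value(alpha: float = 0.05) -> float:
    """5% critical value of the boundary null for 2Δℓ: the null distribution
    is a 50:50 mixture of a point mass at 0 and chi-square(1), so the
    alpha-level cut is the (1 − 2·alpha) quantile of chi-square(1)."""
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    return float(chi2.ppf(1.0 - 2.0 * alpha, df=1))


_SPECIES_TREE_TUPLES = ((("YP", "H1706"), ("PIM", "TUB")), "GAL")


def default_species_tree(branch_length: float = 0.1) -> Clade:
    """The species tree in its unrooted five-taxon representation."""
    t = tree_from_tuples(_SPECIES_TREE_TUPLES, branch_length)
    t.length = 0.0
    return t


def _branches(tree: Clade) -> list[Clade]:
    out = []
    stack = list(tree.children)
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _mixture_loglik(tree, codes, taxa, counts, kappa, pi, p0, p1, w0, w2,
                    fg_set):
    """Model A likelihood: classes (p0: w0/w0), (p1: 1/1),
    (2a: w0 background, w2 foreground), (2b: 1 background, w2 foreground)."""
    p2 = max(1.0 - p0 - p1, 0.0)
    denom = p0 + p1
    props = [p0, p1, p2 * p0 / denom, p2 * p1 / denom]
    m_w0 = C.GY94(kappa, w0, pi, scale="neutral")
    m_w1 = C.GY94(kappa, 1.0, pi, scale="neutral")
    m_w2 = m_w1 if w2 == 1.0 else C.GY94(kappa, w2, pi, scale="neutral")
    branches = _branches(tree)

    def mats(bg_model, fg_model):
        out = {}
        for b in branches:
            m = fg_model if (b.leaf_names() == fg_set and not b.is_leaf) or \
                            (b.is_leaf and frozenset([b.label]) == fg_set) else bg_model
            out[id(b)] = m.pmat(b.length)
        return out

    class_mats = [(mats(m_w0, m_w0), m_w0.pi),
                  (mats(m_w1, m_w1), m_w1.pi),
                  (mats(m_w0, m_w2), m_w0.pi),
                  (mats(m_w1, m_w2), m_w1.pi)]
    return C.codon_tree_loglik_mixture(tree, codes, taxa, counts, props,
                                       class_mats)


def _fit_m0(tree, codes, taxa, counts, pi):
    """Single-omega fit of branch lengths, kappa and omega (used to anchor
    branch lengths before the site-class optimization)."""
    branches = _branches(tree)
    nb = len(branches)

    def nll(x):
        bl = np.exp(x[:nb])
        kappa, omega = np.exp(x[nb]), np.exp(x[nb + 1])
        m = C.GY94(kappa, omega, pi, scale="neutral")
        mats = {}
        for b, t in zip(branches, bl):
            b.length = t
            mats[id(b)] = m.pmat(t)
        return -C.codon_tree_loglik_mixture(tree, codes, taxa, counts, [1.0],
                                            [(mats, m.pi)])

    x0 = np.log(np.r_[np.full(nb, 0.05), 2.0, 0.4])
    bounds = [(np.log(1e-5), np.log(10.0))] * nb + \
             [(np.log(0.2), np.log(50.0)), (np.log(1e-4), np.log(50.0))]
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200})
    bl = np.exp(res.x[:nb])
    for b, t in zip(branches, bl):
        b.length = t
    return float(np.exp(res.x[nb])), float(np.exp(res.x[nb + 1])), -res.fun


def _softmax3(a0, a1):
    e = np.exp([a0, a1, 0.0])
    p = e / e.sum()
    return float(p[0]), float(p[1])


def branch_site_lrt(seqs: dict[str, str] | CodonAlignment,
                    species_tree: Clade | None = None,
                    foreground=frozenset(("YP", "H1706")),
                    threshold: float = LRT_THRESHOLD) -> BranchSiteResult:
    """Branch-site test for positive selection on the foreground branch.

    Branch lengths and kappa are fitted once under a single-omega model and
    held fixed while the site-class parameters are optimized — first the
    null (omega2 = 1), then the alternative starting from the null optimum,
    which keeps the models numerically nested.
    """
    aln = seqs if isinstance(seqs, CodonAlignment) else validate_cds(seqs)
    fg = frozenset([foreground]) if isinstance(foreground, str) else frozenset(foreground)
    tree = (species_tree or default_species_tree()).copy()
    taxa = aln.taxa
    if not any((b.leaf_names() == fg and not b.is_leaf) or
               (b.is_leaf and frozenset([b.label]) == fg)
               for b in _branches(tree)):
        raise ValueError(f"foreground branch {set(fg)} not found in the tree")
    cols = aln.comparable_columns()
    pats, counts = np.unique(cols, axis=1, return_counts=True)
    counts = counts.astype(float)
    nt = "".join(C.SENSE_CODONS[i] for i in cols.ravel())
    ntc = np.array([nt.count(b) for b in "ACGT"], float) + 1.0
    pi = C.f1x4_frequencies(ntc / ntc.sum())

    kappa, _, _ = _fit_m0(tree, pats, taxa, counts, pi)

    def nll_null(x):
        p0, p1 = _softmax3(x[0], x[1])
        w0 = 1.0 / (1.0 + np.exp(-x[2]))
        return -_mixture_loglik(tree, pats, taxa, counts, kappa, pi,
                                p0, p1, w0, 1.0, fg)

    x0 = np.array([1.0, -1.0, 0.0])
    bnd = [(-12.0, 12.0)] * 2 + [(-12.0, 12.0)]
    res0 = minimize(nll_null, x0, method="L-BFGS-B", bounds=bnd)
    lnL_null = -res0.fun
    p0n, p1n = _softmax3(res0.x[0], res0.x[1])
    w0n = 1.0 / (1.0 + np.exp(-res0.x[2]))

    def nll_alt(x):
        p0, p1 = _softmax3(x[0], x[1])
        w0 = 1.0 / (1.0 + np.exp(-x[2]))
        w2 = 1.0 + np.exp(x[3])
        return -_mixture_loglik(tree, pats, taxa, counts, kappa, pi,
                                p0, p1, w0, w2, fg)

    best = None
    for y0 in (-3.0, 0.5):
        xa = np.r_[res0.x, y0]
        res1 = minimize(nll_alt, xa, method="L-BFGS-B",
                        bounds=bnd + [(-15.0, 6.0)])
        if best is None or res1.fun < best.fun:
            best = res1
    lnL_alt = max(-best.fun, lnL_null)  # omega2 = 1 lies in the closure
    stat = 2.0 * (lnL_alt - lnL_null)
    p0a, p1a = _softmax3(best.x[0], best.x[1])
    return BranchSiteResult(
        lnL_null, lnL_alt, stat, stat > threshold, fg,
        params_null={"p0": p0n, "p1": p1n, "omega0": w0n, "kappa": kappa},
        params_alt={"p0": p0a, "p1": p1a,
                    "omega0": 1.0 / (1.0 + np.exp(-best.x[2])),
                    "omega2": 1.0 + float(np.exp(best.x[3])), "kappa": kappa})


# ---------------------------------------------------------------------------
# Global-clock dating


@dataclass
class ClockEstimate:
    dS: float
    mu: float
    T_years: float
    T_MYA: float


def clock_date(dS: float, mu: float = CLOCK_RATE) -> ClockEstimate:
    """Divergence time T = dS / (2 mu); MYA rounded half-up to 2 decimals."""
    if dS < 0:
        raise ValueError("dS must be non-negative")
    T_years = dS / (2.0 * mu)
    T_MYA = float(Decimal(T_years / 1e6).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))
    return ClockEstimate(dS, mu, T_years, T_MYA)


# ---------------------------------------------------------------------------
# Reciprocal-best-hit ortholog filter


def rbh_ortholog_filter(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame,
                        min_coverage: float = 0.5) -> pd.DataFrame:
    """Retain reciprocal best hits with reference coverage >= min_coverage.

    Hit tables need columns (query, target, coverage, score). A query whose
    top score is tied between several targets is discarded (not one-to-one).
    """
    def best(hits):
        out = {}
        for q, grp in hits.groupby("query"):
            top = grp["score"].max()
            winners = grp[grp["score"] == top]
            if len(winners) == 1:
                out[q] = winners.iloc[0]
        return out

    best_ab, best_ba = best(hits_ab), best(hits_ba)
    rows = []
    for q, hit in best_ab.items():
        t = hit["target"]
        back = best_ba.get(t)
        if back is None or back["target"] != q:
            continue
        if hit["coverage"] < min_coverage:
            continue
        rows.append({"query": q, "target": t, "coverage": hit["coverage"],
                     "score": hit["score"]})
    return pd.DataFrame(rows, columns=["query", "target", "coverage", "score"])
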