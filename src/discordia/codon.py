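"""Codon state space and Goldman–Yang-style codon models.

The state space is the 61 sense codons of the standard genetic code (stop
codons are excluded from the states, so simulated sequences can never
contain one). Rates allow single-nucleotide changes only, with a
transition/transversion ratio kappa, target-codon frequencies pi_j, and a
nonsynonymous multiplier omega; matrices are normalized to one expected
substitution per codon per unit branch length. Matrix exponentials come
from the cached symmetric eigendecomposition (the model is reversible).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np

from Bio.Data.CodonTable import standard_dna_table

from .trees import Clade

STOPS = tuple(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}
N_CODONS = len(SENSE_CODONS)  # 61

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _pair_tables():
    """Single-nt-difference structure: (i, j) -> (is_transition, is_synonymous)."""
    ts = np.zeros((N_CODONS, N_CODONS), bool)
    single = np.zeros((N_CODONS, N_CODONS), bool)
    syn = np.zeros((N_CODONS, N_CODONS), bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            ts[i, j] = _is_transition(ci[k], cj[k])
            syn[i, j] = AA[ci] == AA[cj]
    return single, ts, syn


SINGLE_NT, TRANSITION, SYNONYMOUS = _pair_tables()


def f1x4_frequencies(nt_freqs) -> np.ndarray:
    """Codon frequencies from nucleotide frequencies (F1x4), renormalized
    over the sense codons."""
    ntf = {b: f for b, f in zip("ACGT", np.asarray(nt_freqs, float))}
    pi = np.array([ntf[c[0]] * ntf[c[1]] * ntf[c[2]] for c in SENSE_CODONS])
    return pi / pi.sum()


class GY94:
    """Codon substitution model with parameters (kappa, omega, pi).

    ``scale='self'`` normalizes the generator to one expected substitution
    per codon per unit branch length under *this* omega — the convention
    for pairwise divergence estimates. ``scale='neutral'`` normalizes by
    the omega=1 rate instead, so site classes with different omegas share
    a time scale and a class under positive selection genuinely evolves
    faster — the convention for site-class mixtures.
    """

    def __init__(self, kappa: float = 2.0, omega: float = 1.0, pi=None,
                 scale: str = "self"):
        if kappa <= 0 or omega < 0:
            raise ValueError("kappa must be positive, omega non-negative")
        if scale not in ("self", "neutral"):
            raise ValueError("scale must be 'self' or 'neutral'")
        self.kappa = float(kappa)
        self.omega = float(omega)
        self.scale = scale
        self.pi = (np.full(N_CODONS, 1.0 / N_CODONS) if pi is None
                   else np.asarray(pi, float))
        if self.pi.shape != (N_CODONS,) or np.any(self.pi < 0):
            raise ValueError("pi must be 61 non-negative frequencies")
        self.pi = self.pi / self.pi.sum()
        self._decompose()

    def _decompose(self):
        R = np.where(SINGLE_NT, np.where(TRANSITION, self.kappa, 1.0), 0.0)
        Q1 = R * self.pi[None, :]
        Q = Q1 * np.where(SYNONYMOUS, 1.0, self.omega)
        np.fill_diagonal(Q, 0.0)
        if self.scale == "self":
            scale = (self.pi[:, None] * Q).sum()
        else:
            np.fill_diagonal(Q1, 0.0)
            scale = (self.pi[:, None] * Q1).sum()
        np.fill_diagonal(Q, -Q.sum(axis=1))
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        Q /= scale
        self.Q = Q
        d = np.sqrt(np.maximum(self.pi, 1e-300))
        B = Q * d[:, None] / d[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2)
        self._lam = lam
        self._left = V / d[:, None]
        self._right = (V * d[:, None]).T

    def pmat(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        e = np.exp(self._lam * t)
        P = (self._left * e[None, :]) @ self._right
        return np.clip(P, 0.0, None)

    def flux_fractions(self) -> tuple[float, float]:
        """(synonymous, nonsynonymous) mutational-opportunity flux, i.e. the
        omega-free fluxes FS and FN used in the dN/dS decomposition."""
        R = np.where(SINGLE_NT, np.where(TRANSITION, self.kappa, 1.0), 0.0)
        M = R * self.pi[None, :] * self.pi[:, None]
        FS = float(M[SYNONYMOUS & SINGLE_NT].sum())
        FN = float(M[~SYNONYMOUS & SINGLE_NT].sum())
        return FS, FN

    def rates_from_t(self, t: float) -> tuple[float, float]:
        """(dN, dS) per nonsynonymous/synonymous *site* for divergence ``t``
        expected substitutions per codon under this model."""
        FS, FN = self.flux_fractions()
        denom = 3.0 * (FS + self.omega * FN)
        dS = t * (FS + FN) / denom
        dN = self.omega * dS
        return dN, dS

    def site_fractions(self) -> tuple[float, float]:
        """(N_sites, S_sites) per codon from mutational opportunity."""
        FS, FN = self.flux_fractions()
        S = 3.0 * FS / (FS + FN)
        return 3.0 - S, S


def codons_to_string(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def string_to_codons(seq: str) -> np.ndarray:
    """Codon indices; -1 for gap/ambiguous/stop codons."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = np.empty(len(seq) // 3, np.int64)
    for k in range(0, len(seq), 3):
        out[k // 3] = CODON_INDEX.get(seq[k:k + 3].upper(), -1)
    return out


def simulate_codon_pair(omega: float, t: float, kappa: float = 2.0,
                        n_codons: int = 500, rng=None,
                        pi=None) -> tuple[str, str]:
    """An in-frame codon alignment of two sequences at divergence ``t``
    (expected substitutions per codon between them)."""
    if n_codons < 10:
        raise ValueError("n_codons must be at least 10")
    if t < 0:
        raise ValueError("negative divergence")
    rng = np.random.default_rng(rng)
    model = GY94(kappa, omega, pi)
    anc = rng.choice(N_CODONS, size=n_codons, p=model.pi)
    P = model.pmat(t)
    cum = P.cumsum(axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_codons)
    der = (u[:, None] > cum[anc]).sum(axis=1)
    return codons_to_string(anc), codons_to_string(der)


def simulate_codon_alignment(tree: Clade, n_codons: int,
                             site_classes=((1.0, 1.0, 1.0),),
                             kappa: float = 2.0, pi=None,
                             foreground: frozenset | str | None = None,
                             rng=None) -> dict[str, str]:
    """Evolve codon sequences down a tree with site classes.

    ``site_classes``: (proportion, background omega, foreground omega)
    triples; ``foreground`` names the branch (a tip label or the frozenset
    of tip labels it subtends) that uses the foreground omega. Branch
    lengths are expected substitutions per codon.
    """
    rng = np.random.default_rng(rng)
    props = np.array([c[0] for c in site_classes], float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("site class proportions must sum to 1")
    models_bg = [GY94(kappa, c[1], pi, scale="neutral") for c in site_classes]
    models_fg = [GY94(kappa, c[2], pi, scale="neutral") for c in site_classes]
    cls = rng.choice(len(site_classes), size=n_codons, p=props)
    anc = np.array([rng.choice(N_CODONS, p=m.pi) for m in
                    (models_bg[c] for c in cls)])
    out: dict[str, str] = {}

    def is_foreground(node: Clade) -> bool:
        if foreground is None:
            return False
        if isinstance(foreground, str):
            return node.is_leaf and node.label == foreground
        return node.leaf_names() == foreground

    def evolve(node: Clade, states: np.ndarray):
        for child in node.children:
            mods = models_fg if is_foreground(child) else models_bg
            new = states.copy()
            for c in range(len(site_classes)):
                sel = np.flatnonzero(cls == c)
                if sel.size == 0:
                    continue
                P = mods[c].pmat(child.length)
                cum = P.cumsum(axis=1)
                cum[:, -1] = 1.0
                u = rng.random(sel.size)
                new[sel] = (u[:, None] > cum[states[sel]]).sum(axis=1)
            if child.is_leaf:
                out[child.label] = codons_to_string(new)
            else:
                evolve(child, new)

    evolve(tree, anc)
    return out


# ---------------------------------------------------------------------------
# Codon pruning (for the branch-site test)


def codon_tree_loglik_mixture(tree: Clade, codes: np.ndarray, taxa,
                              counts, class_props, class_mats) -> float:
    """Log-likelihood under a site-class mixture.

    ``class_mats[c]`` maps a branch key (id of the Clade node) to its
    61x61 transition matrix for class ``c``; ``codes`` is
    (ntaxa, npatterns) codon indices with -1 for missing.
    """
    order = {t: i for i, t in enumerate(taxa)}
    npat = codes.shape[1]
    tips = np.zeros((codes.shape[0], N_CODONS, npat))
    for s in range(N_CODONS):
        tips[:, s, :] = codes == s
    tips += (codes < 0)[:, None, :]

    def down(node: Clade, mats) -> np.ndarray:
        if node.is_leaf:
            return tips[order[node.label]]
        L = np.ones((N_CODONS, npat))
        for c in node.children:
            L *= mats[id(c)] @ down(c, mats)
        return L

    site = np.zeros(npat)
    for prop, mats, pi in class_props_iter(class_props, class_mats):
        site += prop * (pi @ down(tree, mats))
    if np.any(site <= 0) or not np.all(np.isfinite(site)):
        raise FloatingPointError("non-finite codon site likelihood")
    w = np.ones(npat) if counts is None else np.asarray(counts, float)
    return float(w @ np.log(site))


def class_props_iter(class_props, class_mats):
    for c, prop in enumerate(class_props):
        mats, pi = class_mats[c]
        yield prop, mats, pi


# ---------------------------------------------------------------------------
# Nei–Gojobori pathway counting tables


@lru_cache(maxsize=None)
def ng86_site_counts(codon_idx: int) -> float:
    """Synonymous site count of a sense codon (changes to stops count as
    nonsynonymous, so syn + nonsyn sites sum to 3)."""
    c = SENSE_CODONS[codon_idx]
    s = 0.0
    for k in range(3):
        for b in "ACGT":
            if b == c[k]:
                continue
            alt = c[:k] + b + c[k + 1:]
            if alt not in STOPS and AA.get(alt) == AA[c]:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def ng86_path_counts(i: int, j: int) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two sense
    codons over all minimal substitution pathways; pathways through stop
    codons are excluded (all-blocked pairs fall back to every pathway)."""
    ci, cj = SENSE_CODONS[i], SENSE_CODONS[j]
    diffs = [k for k in range(3) if ci[k] != cj[k]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = ci
        steps = []
        blocked = False
        for k in order:
            nxt = cur[:k] + cj[k] + cur[k + 1:]
            if nxt in STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        syn = sum(1.0 for a, b in steps
                  if a not in STOPS and b not in STOPS and AA.get(a) == AA.get(b))
        non = len(steps) - syn
        paths.append((blocked, syn, non))
    valid = [(s, n) for blocked, s, n in paths if not blocked]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    syn = sum(s for s, _ in valid) / len(valid)
    non = sum(n for _, n in valid) / len(valid)
    return syn, non
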