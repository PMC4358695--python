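"""Felsenstein pruning likelihoods for small trees.

Two entry points: a generic recursion over any :class:`~discordia.trees.Clade`
(used for oracles, pairwise collapses, arbitrary fixtures) and a fast path
specialized to the two-cherry shape shared by all unrooted five-taxon
topologies (used by the genome scan, where it is called millions of times).
Sites with gaps or ambiguity are marginalized as missing data.
"""

from __future__ import annotations

import numpy as np

from .models import MISSING, NucleotideModel
from .trees import Clade, center_taxon


def compress_patterns(codes: np.ndarray):
    """Collapse alignment columns to unique site patterns with multiplicities."""
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def tip_partials(codes: np.ndarray) -> np.ndarray:
    """Conditional likelihoods at the tips: (ntaxa, 4, npatterns).

    Missing states get a row of ones (marginalized).
    """
    ntaxa, npat = codes.shape
    L = np.zeros((ntaxa, 4, npat))
    for s in range(4):
        L[:, s, :] = codes == s
    L += (codes == MISSING)[:, None, :]
    return L


def _message(model: NucleotideModel, t: float, L: np.ndarray) -> np.ndarray:
    return model.pmat(t) @ L


def tree_loglik(tree: Clade, codes: np.ndarray, taxa, model: NucleotideModel,
                counts=None) -> float:
    """Log-likelihood of site patterns under an arbitrary rooted tree.

    ``codes`` is (ntaxa, npatterns) in the order of ``taxa``; ``counts``
    are pattern multiplicities (default 1 per column).
    """
    order = {t: i for i, t in enumerate(taxa)}
    tips = tip_partials(codes)

    def down(node: Clade) -> np.ndarray:
        if node.is_leaf:
            return tips[order[node.label]]
        L = np.ones((4, codes.shape[1]))
        for c in node.children:
            L *= _message(model, c.length, down(c))
        return L

    site = model.pi @ down(tree)
    if np.any(site <= 0) or not np.all(np.isfinite(site)):
        raise FloatingPointError("non-finite site likelihood")
    w = np.ones(codes.shape[1]) if counts is None else np.asarray(counts, float)
    return float(w @ np.log(site))


class TopologyLikelihood:
    """Likelihood of one unrooted five-taxon topology as a function of its
    seven branch lengths.

    Branch order matches :func:`discordia.trees.topology_tree`: four cherry
    tips, the central tip, then the two internal (stem) edges.
    """

    def __init__(self, pairs, taxa, tips: np.ndarray, counts: np.ndarray,
                 model: NucleotideModel):
        order = {t: i for i, t in enumerate(taxa)}
        (x, y), (u, v) = pairs
        w = center_taxon(pairs, taxa)
        self._tips = [tips[order[t]] for t in (x, y, u, v, w)]
        self._counts = counts
        self.model = model

    def loglik(self, b: np.ndarray) -> float:
        P = self.model.pmat(b)  # (7,4,4)
        Lx, Ly, Lu, Lv, Lw = self._tips
        n1 = (P[0] @ Lx) * (P[1] @ Ly)
        n2 = (P[2] @ Lu) * (P[3] @ Lv)
        root = (P[5] @ n1) * (P[6] @ n2) * (P[4] @ Lw)
        site = self.model.pi @ root
        if np.any(site <= 0) or not np.all(np.isfinite(site)):
            raise FloatingPointError("non-finite site likelihood")
        return float(self._counts @ np.log(site))

    def loglik_and_grad(self, b: np.ndarray):
        """Log-likelihood and its gradient in the seven branch lengths.

        Uses dP/dt = Q P(t): the derivative in branch k swaps that branch's
        message M = P L for Q M in the root product.
        """
        model = self.model
        P = model.pmat(b)
        Q, pi, w = model.Q, model.pi, self._counts
        m = [P[i] @ L for i, L in enumerate(self._tips)]
        n1, n2 = m[0] * m[1], m[2] * m[3]
        M1, M2 = P[5] @ n1, P[6] @ n2
        site = pi @ (M1 * M2 * m[4])
        if np.any(site <= 0) or not np.all(np.isfinite(site)):
            raise FloatingPointError("non-finite site likelihood")
        inv = w / site
        grad = np.empty(7)
        grad[0] = inv @ (pi @ ((P[5] @ ((Q @ m[0]) * m[1])) * M2 * m[4]))
        grad[1] = inv @ (pi @ ((P[5] @ (m[0] * (Q @ m[1]))) * M2 * m[4]))
        grad[2] = inv @ (pi @ (M1 * (P[6] @ ((Q @ m[2]) * m[3])) * m[4]))
        grad[3] = inv @ (pi @ (M1 * (P[6] @ (m[2] * (Q @ m[3]))) * m[4]))
        grad[4] = inv @ (pi @ (M1 * M2 * (Q @ m[4])))
        grad[5] = inv @ (pi @ ((Q @ M1) * M2 * m[4]))
        grad[6] = inv @ (pi @ (M1 * (Q @ M2) * m[4]))
        return float(w @ np.log(site)), grad


def pruning_loglik(tree: Clade, codes: np.ndarray, taxa, model: NucleotideModel,
                   counts=None) -> float:
    """Public pruning entry point (generic recursion)."""
    return tree_loglik(tree, codes, taxa, model, counts)
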