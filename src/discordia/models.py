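"""Nucleotide substitution models (JC69, K80, HKY85).

Rate matrices are normalized to one expected substitution per site per
unit branch length, and transition-probability matrices are computed from
a cached eigendecomposition (all three models are time-reversible).
Bases are coded A=0, C=1, G=2, T=3; code 4 means missing/gap.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}
MISSING = 4

# transitions: A<->G, C<->T
_TS = np.zeros((4, 4), bool)
_TS[0, 2] = _TS[2, 0] = _TS[1, 3] = _TS[3, 1] = True


class NucleotideModel:
    """Reversible 4-state model defined by (kappa, base frequencies)."""

    def __init__(self, kappa: float = 1.0, freqs=None, name: str = "custom"):
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        self.kappa = float(kappa)
        pi = np.full(4, 0.25) if freqs is None else np.asarray(freqs, float)
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ValueError("freqs must be four positive numbers")
        self.pi = pi / pi.sum()
        self.name = name
        self._decompose()

    def _decompose(self):
        R = np.where(_TS, self.kappa, 1.0)
        Q = R * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(self.pi * np.diag(Q)).sum()
        Q /= scale
        # symmetrize: B = D^{1/2} Q D^{-1/2}
        d = np.sqrt(self.pi)
        B = Q * d[:, None] / d[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2)
        self._lam = lam
        self._left = V / d[None, :].T  # D^{-1/2} V
        self._right = (V * d[:, None]).T  # V^T D^{1/2}
        self.Q = Q  # normalized generator; dP/dt = Q P(t)

    def pmat(self, t) -> np.ndarray:
        """P(t); vectorized over an array of branch lengths (…,4,4)."""
        t = np.asarray(t, float)
        if np.any(t < 0):
            raise ValueError("negative branch length")
        e = np.exp(np.multiply.outer(t, self._lam))
        P = np.einsum("ik,...k,kj->...ij", self._left, e, self._right)
        return np.clip(P, 0.0, 1.0)


def JC69() -> NucleotideModel:
    m = NucleotideModel(1.0, None, "JC69")
    return m


def K80(kappa: float = 2.0) -> NucleotideModel:
    return NucleotideModel(kappa, None, "K80")


def HKY85(kappa: float = 2.0, freqs=None) -> NucleotideModel:
    return NucleotideModel(kappa, freqs, "HKY85")


_BY_NAME = {"jc69": JC69, "k80": K80, "hky85": HKY85}


def get_model(name: str, **kw) -> NucleotideModel:
    try:
        return _BY_NAME[name.lower()](**kw)
    except KeyError:
        raise ValueError(f"unknown substitution model {name!r}") from None


def encode_sequences(seqs, length: int | None = None) -> np.ndarray:
    """Encode an iterable of equal-length strings to an (ntaxa, nsites) int array.

    Anything outside ACGT (gaps, N, ambiguity codes) becomes MISSING.
    """
    rows = []
    for s in seqs:
        a = np.frombuffer(s.upper().encode(), dtype=np.uint8)
        code = np.full(a.shape, MISSING, dtype=np.int8)
        for b, i in BASE_CODE.items():
            code[a == ord(b)] = i
        rows.append(code)
    arr = np.vstack(rows)
    if length is not None and arr.shape[1] != length:
        raise ValueError("sequence length mismatch")
    return arr


def jc69_distance(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0 or p >= 0.75:
        raise ValueError("proportion out of the correctable range [0, 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)
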