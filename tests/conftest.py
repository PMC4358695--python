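import numpy as np
import pytest

from discordia.trees import Clade
from discordia.window_scan import Block, GenomeAlignment

TAXA = ("YP", "H1706", "GAL", "PIM", "TUB")


def genome_to_alignment(genome) -> GenomeAlignment:
    """Wrap a SimulatedGenome as an in-memory GenomeAlignment."""
    blocks = [Block(c, s, seqs, next(iter(seqs)))
              for c, s, seqs in genome.maf_blocks()]
    return GenomeAlignment(blocks, genome.taxa)


def enumerate_rooted_quartets(labels=TAXA[:4]):
    """All 15 rooted binary trees on four labelled tips."""
    def build(leaves):
        if len(leaves) == 1:
            yield Clade(leaves[0])
            return
        rest = leaves[1:]
        n = len(rest)
        for mask in range(2 ** n - 1):
            left = [leaves[0]] + [rest[i] for i in range(n) if mask >> i & 1]
            right = [rest[i] for i in range(n) if not mask >> i & 1]
            for lt in build(left):
                for rt in build(right):
                    yield Clade(None, 0.0, [lt.copy(), rt.copy()])

    return list(build(list(labels)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
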