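import math

import pytest

from aachron import ProteinRecord, consensus_ranks, mean_positions
from aachron.simulate import FIG_EXAMPLE_SEQUENCE


@pytest.fixture
def example_protein():
    """The 13-residue worked example MAGHLMVTYRGTG."""
    return ProteinRecord(id="example", residues=FIG_EXAMPLE_SEQUENCE)


@pytest.fixture
def example_profile(example_protein):
    return mean_positions(example_protein)


@pytest.fixture
def consensus():
    return consensus_ranks()


def brute_pearson(x, y):
    """Independent Pearson oracle: direct covariance formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
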