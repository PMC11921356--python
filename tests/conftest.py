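import logging

import pytest

from cocult.growth import GrowthCurve, GrowthDataset
from cocult.interactions import classify_all
from cocult.simulate import pattern_fixture

logging.getLogger("cocult").setLevel(logging.ERROR)


def make_triad(co_maxima, monoA_maxima, monoB_maxima, pair=("A", "B"), carbon="c1"):
    """A minimal dataset with one (pair, carbon) triad of flat curves whose
    maxima equal the given values."""
    curves = []
    a, b = pair
    for strains, values in ((frozenset({a}), monoA_maxima),
                            (frozenset({b}), monoB_maxima),
                            (frozenset({a, b}), co_maxima)):
        for rep, v in enumerate(values, start=1):
            curves.append(GrowthCurve(strains=strains, carbon=carbon,
                                      replicate=rep, times=(1.0,), od=(v,)))
    return GrowthDataset(curves=curves)


@pytest.fixture(scope="session")
def pattern_sim():
    """The deterministic 6-pair x 14-carbon pattern dataset (seed 1)."""
    return pattern_fixture(seed=1)


@pytest.fixture(scope="session")
def pattern_calls(pattern_sim):
    return classify_all(pattern_sim.dataset)
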