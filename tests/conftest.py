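import io

import numpy as np
import pytest

from treeassoc import DistanceGrid, MarkedPattern, Window, read_census


@pytest.fixture
def window():
    return Window(100.0, 100.0)


@pytest.fixture
def grid():
    return DistanceGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_pattern(rng, window, n, label=""):
    return MarkedPattern(
        points=rng.uniform([0, 0], [window.width, window.height], size=(n, 2)),
        marks=rng.lognormal(2.3, 0.6, n),
        window=window,
        label=label,
    )


@pytest.fixture
def pattern_pair(rng, window):
    return random_pattern(rng, window, 30, "A"), random_pattern(rng, window, 25, "B")


TOY_CSV = """plot_id,tree_id,species,x,y,dbh,height
p1,t1,A,10.0,10.0,12.5,8.0
p1,t2,A,12.0,11.0,30.1,15.0
p1,t3,B,50.0,60.0,5.2,4.0
"""


@pytest.fixture
def toy_census(window):
    return read_census(io.StringIO(TOY_CSV), window)
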