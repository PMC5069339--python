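import numpy as np
import pytest

from tetramap.markers import FundamentalType
from tetramap.meiosis import MeiosisModel, random_marker_layout, simulate_cross


@pytest.fixture(scope="session")
def pop_all_types():
    """A random-bivalent F1 population with all nine types (40 loci, n=200)."""
    g1, g2 = random_marker_layout(40, 2.5, tuple(FundamentalType), seed=12345)
    return simulate_cross(g1, g2, MeiosisModel(q=0.0, p=0.0), 200, seed=54321)


@pytest.fixture(scope="session")
def pop_sxn_one_chromosome():
    """Simplex x nulliplex markers on one chromosome, n=250."""
    g1, g2 = random_marker_layout(16, 4.0, (FundamentalType.SxN,), seed=777)
    return simulate_cross(g1, g2, MeiosisModel(), 250, seed=778)
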