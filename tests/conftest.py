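import numpy as np
import pytest

from betaproc import Phylogeny
from betaproc.io import make_fixtures

FIXTURE_SEED = 7

# ((t1:1,t2:1):2,(t3:1.5,(t4:0.5,t5:0.5):1):1.5); -- shared by several suites
NEWICK5 = "((t1:1,t2:1):2,(t3:1.5,(t4:0.5,t5:0.5):1):1.5);"


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    make_fixtures(FIXTURE_SEED, out)
    return out


@pytest.fixture(scope="session")
def expected_values(fixture_dir):
    import json

    return json.loads((fixture_dir / "expected_values.json").read_text())


@pytest.fixture()
def tree5():
    return Phylogeny.from_newick(NEWICK5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
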