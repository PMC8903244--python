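import numpy as np
import pytest

import trafficpm as tp
from trafficpm.simulate import load_fixture

#: Fixed seed used across the suite (chosen once, a date).
SEED = 20220308


@pytest.fixture(scope="session")
def paper_fixture():
    """Packaged paper-scale synthetic dataset (182 rows, 117 cities)."""
    records, truth = load_fixture("paper_scale")
    return records, truth


@pytest.fixture(scope="session")
def curated_paper(paper_fixture):
    records, _ = paper_fixture
    kept, _ = tp.filter_records(records)
    curated, _ = tp.curate(kept)
    return curated


@pytest.fixture(scope="session")
def paper_fit(curated_paper):
    """Full-protocol fit (2 x 15,000 iterations, 5,000 burn-in)."""
    model = tp.JointMetaRegression.from_dataframe(curated_paper)
    return model.fit(cfg=tp.McmcConfig(n_chains=2, n_iter=15000, n_burn=5000,
                                       seed=SEED))


@pytest.fixture(scope="session")
def quick_fit(curated_paper):
    """Shorter fit for unit-level checks that only need reasonable draws."""
    model = tp.JointMetaRegression.from_dataframe(curated_paper)
    return model.fit(cfg=tp.McmcConfig(n_chains=2, n_iter=3000, n_burn=1000,
                                       seed=SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
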