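import numpy as np
import pytest

from streamcom import occurrence
from streamcom.fixtures import FixtureSpec, gen_fixture

#: The seven-species worked community (mean weights in grams).
TABLE1_WEIGHTS = [0.1, 0.3, 5.0, 8.0, 25.0, 120.0, 200.0]


def table1_community():
    return [(f"sp{i}", w) for i, w in enumerate(TABLE1_WEIGHTS)]


@pytest.fixture(scope="session")
def demo_fixture():
    """Default-sized synthetic fixture: 20 species, 5x5 grid, 3000 surveys."""
    return gen_fixture(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def recovery():
    """Trained occurrence models on a logistic-ground-truth fixture
    (20 species, 2000 surveys, 75/25 site split), shared across the
    model-recovery tests."""
    fx = gen_fixture(FixtureSpec(seed=1, n_species=20, n_surveys=2000))
    train, test = occurrence.split_surveys(fx.surveys, 0.25, seed=1)
    sets = occurrence.build_training_sets(train, fx.distribution)
    models = {
        sid: occurrence.train_occurrence_model(t, seed=1)
        for sid, t in sets.tables.items()
        if not t.degenerate
    }
    return {"fixture": fx, "train": train, "test": test, "models": models,
            "training_sets": sets}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
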