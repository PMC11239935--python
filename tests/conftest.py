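import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from eetss import (
    GeneratorConfig,
    LabeledCollection,
    MultivariateSeries,
    gen_correlation_shift,
)


@pytest.fixture
def toy_collection() -> LabeledCollection:
    """Two tiny 2-channel instances with binary labels."""
    a = MultivariateSeries(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
                           instance_id="a")
    b = MultivariateSeries(np.array([[7.0, 1.0], [8.0, 2.0]]), instance_id="b")
    return LabeledCollection((a, b), ("healthy", "disease"), positive_label="disease")


@pytest.fixture
def toy_ts_file(tmp_path, toy_collection):
    """A .ts file written by the suite itself, for round-trip checks."""
    from eetss.io import write_ts

    path = tmp_path / "toy.ts"
    write_ts(toy_collection, path, problem_name="toy")
    return path


@pytest.fixture(scope="session")
def small_strong_collection() -> LabeledCollection:
    """A small strong-effect dataset kept cheap for unit-level checks."""
    cfg = GeneratorConfig(n_instances=10, n=200, m=3, seed=11)
    return gen_correlation_shift(cfg)
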