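import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirensemble.tables import PredictorSpec, ScoreTable, default_specs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def specs5():
    return default_specs()


@pytest.fixture
def make_table():
    """Factory building a validated ScoreTable from per-column cell lists."""

    def _make(cells: dict, labels, specs=None, ids=None):
        n = len(labels)
        if specs is None:
            by_name = {s.name: s for s in default_specs()}
            specs = [by_name[name] for name in cells]
        raw = pd.DataFrame(cells, columns=list(cells), dtype=object)
        return ScoreTable(
            sample_ids=ids or [f"s{i}" for i in range(n)],
            labels=np.asarray(labels),
            predictors=specs,
            raw=raw,
        )

    return _make


@pytest.fixture
def binary_pair_specs():
    """Two simple Yes/No binary predictors for minimal fixtures."""
    return [
        PredictorSpec("A", "binary", positive_token="Yes", negative_tokens=frozenset({"No"})),
        PredictorSpec("B", "binary", positive_token="Yes", negative_tokens=frozenset({"No"})),
    ]
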