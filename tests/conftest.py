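import numpy as np
import pytest
from hypothesis import HealthCheck, settings, strategies as st

from freelists import DomainSpec, FreeListDataset, RespondentList, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

ITEMS = [f"it{i}" for i in range(12)]


def make_dataset(lists, label="test"):
    """Build a dataset from plain lists of labels (already normalized)."""
    return FreeListDataset(
        label,
        tuple(
            RespondentList(f"r{i}", tuple(dict.fromkeys(items)))
            for i, items in enumerate(lists, start=1)
        ),
    )


@st.composite
def random_lists(draw, max_respondents=8, alphabet=ITEMS):
    n = draw(st.integers(1, max_respondents))
    out = []
    for _ in range(n):
        items = draw(
            st.lists(st.sampled_from(alphabet), min_size=0, max_size=len(alphabet),
                     unique=True)
        )
        out.append(items)
    # at least one non-empty list so the dataset has items
    if not any(out):
        out[0] = [alphabet[0]]
    return out


@pytest.fixture
def heterogeneous_data():
    """Mid-sized synthetic dataset with a strong salience gradient."""
    return generate_dataset(
        DomainSpec(domain_size=100, n_respondents=40,
                   salience_law=("zipf", 1.0),
                   list_length_law=("lognormal", 12.0, 0.4), seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
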