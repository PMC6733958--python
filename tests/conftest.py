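import numpy as np
import pytest

from specnet import cohort_io, synthesis
from specnet.network import build_network


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_params():
    return synthesis.default_edition_params()


@pytest.fixture
def sydney_medalists(default_params):
    return next(
        p
        for p in default_params
        if p.edition_label == "Sydney 2000" and p.group_label == cohort_io.MEDALIST
    )


@pytest.fixture
def edition_records():
    """One synthetic edition: 8 finalists (3 medalists + 5 non-medalists)."""
    config = synthesis.default_config(seed=7)
    medal, rest = config.editions[0]
    rng = np.random.default_rng(7)
    records = synthesis.generate_cohort(medal, rng=rng, rank_start=1)
    records += synthesis.generate_cohort(rest, rng=rng, rank_start=4)
    return records


@pytest.fixture
def full_cohort():
    """Five synthetic editions, 40 records."""
    return synthesis.generate_editions(synthesis.default_config(seed=11))


def random_symmetric_nonnegative(rng, n, zero_diagonal=True):
    a = rng.uniform(0.0, 1.0, size=(n, n))
    m = (a + a.T) / 2.0
    if zero_diagonal:
        np.fill_diagonal(m, 0.0)
    return m


def network_from_matrix(weights, mode="absolute"):
    """Wrap a ready-made symmetric weight matrix in a CorrelationNetwork."""
    from specnet.network import CorrelationNetwork

    n = weights.shape[0]
    labels = tuple(f"v{i}" for i in range(n))
    return CorrelationNetwork(
        edition_label="test",
        group_label="medalist",
        node_labels=labels,
        weights=np.asarray(weights, dtype=float),
        signed_weights=np.asarray(weights, dtype=float),
        weight_mode=mode,
    )


def uniform_complete_network(n, w):
    weights = np.full((n, n), float(w))
    np.fill_diagonal(weights, 0.0)
    return network_from_matrix(weights)


@pytest.fixture
def small_network(rng):
    matrix = rng.normal(size=(8, 4))
    return build_network(matrix, ("a", "b", "c", "d"))
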