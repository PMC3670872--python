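"""Skeleton generator: conservation, connectivity, determinism, symmetry."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from mtcsim.synthetic import (
    ConfigError,
    GeneratorConfig,
    allocate_sample_sizes,
    generate_skeleton,
)


def test_default_config_conserves_published_totals(default_skeleton):
    net = default_skeleton
    assert net.n_trials == 117
    assert net.n_arms == 236
    assert net.n_participants == 25_928
    assert len(net.treatments) == 12
    sizes = sorted(len(t.arms) for t in net.trials)
    assert sizes.count(2) == 115 and sizes.count(3) == 2
    assert net.is_connected
    assert not net.any_responses


def test_even_allocation_of_published_total():
    sizes = allocate_sample_sizes(236, 25_928, seed=5, dispersion=0.0)
    assert sizes.sum() == 25_928
    values, counts = np.unique(sizes, return_counts=True)
    assert values.tolist() == [109, 110]
    assert counts.tolist() == [32, 204]


def test_even_split_of_two_arms():
    assert allocate_sample_sizes(2, 200, seed=0).tolist() == [100, 100]


@given(
    n_arms=st.integers(2, 60),
    extra=st.integers(0, 5000),
    dispersion=st.sampled_from([0.0, 0.1, 0.25, 1.0]),
    seed=st.integers(0, 2**20),
)
def test_allocation_always_positive_and_exact(n_arms, extra, dispersion, seed):
    total = n_arms + extra
    sizes = allocate_sample_sizes(n_arms, total, seed=seed, dispersion=dispersion)
    assert len(sizes) == n_arms
    assert sizes.sum() == total
    assert sizes.min() >= 1
    if dispersion == 0.0:
        assert sizes.max() - sizes.min() <= 1


def test_allocation_rejects_impossible_total():
    with pytest.raises(ValueError):
        allocate_sample_sizes(10, 9, seed=0)


def test_generator_deterministic_and_seed_sensitive():
    a = generate_skeleton(GeneratorConfig(seed=42))
    b = generate_skeleton(GeneratorConfig(seed=42))
    c = generate_skeleton(GeneratorConfig(seed=43))
    assert a == b
    assert a != c


@pytest.mark.parametrize("attachment", [0.0, 1.0])
def test_connectivity_and_conservation_across_seeds(attachment):
    cfg0 = GeneratorConfig(dispersion=0.25, attachment_exponent=attachment)
    for seed in range(100):
        net = generate_skeleton(
            GeneratorConfig(seed=seed, attachment_exponent=attachment,
                            dispersion=cfg0.dispersion)
        )
        assert net.is_connected
        assert (net.n_trials, net.n_arms, net.n_participants) == (117, 236, 25_928)


def test_label_symmetry_gives_isomorphic_graphs():
    base = generate_skeleton(GeneratorConfig(seed=7))
    relabeled = generate_skeleton(
        GeneratorConfig(seed=7, treatment_labels=tuple("ABCDEFGHIJKL"))
    )
    g1, g2 = base.comparison_graph(), relabeled.comparison_graph()
    mapping = dict(zip(base.treatments, relabeled.treatments))
    assert nx.utils.graphs_equal(nx.relabel_nodes(g1, mapping), g2)


def test_minimal_config_forces_even_single_trial():
    net = generate_skeleton(
        GeneratorConfig(
            n_treatments=2, n_trials=1, n_arms_total=2,
            n_participants_total=200, seed=0, dispersion=0.0,
        )
    )
    assert net.n_trials == 1
    assert [a.n for a in net.trials[0].arms] == [100, 100]


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_treatments=1),
        dict(n_arms_total=100),  # < 2 per trial
        dict(n_arms_total=500),  # would need 4-arm trials
        dict(n_participants_total=100),  # < 1 per arm
        dict(n_trials=5),  # cannot span 12 treatments
        dict(dispersion=-0.1),
    ],
)
def test_invalid_configs_are_rejected(kwargs):
    with pytest.raises(ConfigError):
        GeneratorConfig(**kwargs).validate()
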