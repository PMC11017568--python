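import numpy as np
import pytest

import echoscale as es


@pytest.fixture(scope="session")
def balanced_tree():
    return es.PhyloTree.from_newick("((A:1,B:1):0.5,(C:0.7,D:0.7):0.8);")


@pytest.fixture(scope="session")
def yule100():
    """A 100-tip unit-height Yule tree shared across simulation tests."""
    return es.simulate_yule_tree(100, seed=1001, scale_height=1.0)


@pytest.fixture(scope="session")
def yule300():
    """A 300-tip unit-height Yule tree for the recovery experiments."""
    return es.simulate_yule_tree(300, seed=1002, scale_height=1.0)


@pytest.fixture(scope="session")
def study_dataset():
    """A study-shaped synthetic dataset (314 tips, 4 traits, emission factor)."""
    ds, params = es.simulate_study_dataset(es.SimulationConfig(seed=20240))
    return ds, params


def random_tree(n_tips: int, rng: np.random.Generator) -> es.PhyloTree:
    """Random topology with random branch lengths (not ultrametric)."""
    newick = _random_subtree([f"s{i}" for i in range(n_tips)], rng) + ";"
    return es.PhyloTree.from_newick(newick)


def _random_subtree(labels, rng):
    if len(labels) == 1:
        return f"{labels[0]}:{rng.uniform(0.1, 2.0):.6f}"
    k = int(rng.integers(1, len(labels)))
    left = _random_subtree(labels[:k], rng)
    right = _random_subtree(labels[k:], rng)
    return f"({left},{right}):{rng.uniform(0.1, 2.0):.6f}"


@pytest.fixture
def trait_table_file(tmp_path):
    """A small well-formed trait table on disk."""
    path = tmp_path / "traits.csv"
    path.write_text(
        "species,mass_g,peak_khz,bandwidth_khz,duration_ms,family\n"
        "Myotis lucifugus,7.9,45.0,40.0,3.0,Vespertilionidae\n"
        "Rhinolophus ferrumequinum,22.0,82.0,8.0,40.0,Rhinolophidae\n"
        "Molossus molossus,13.0,38.0,10.0,9.0,Molossidae\n"
    )
    return path
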