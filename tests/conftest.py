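import numpy as np
import pytest

from ivgrn import FitConfig, IvConfig, discover_ivs, fit_network, simulate_dataset
from ivgrn.twostage import stage1_predict


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The standard recovery benchmark: 30 genes, 25 edges, n=500, seed 0."""
    return simulate_dataset(seed=0)


@pytest.fixture(scope="session")
def benchmark_ivmap(benchmark_dataset):
    ds = benchmark_dataset
    return discover_ivs(
        ds.expression, ds.genotypes, ds.gene_annotation, ds.variant_annotation,
        IvConfig(seed=0),
    )


@pytest.fixture(scope="session")
def benchmark_stage1(benchmark_dataset, benchmark_ivmap):
    return stage1_predict(benchmark_dataset.expression, benchmark_ivmap, FitConfig(seed=0))


@pytest.fixture(scope="session")
def benchmark_network(benchmark_dataset, benchmark_ivmap):
    return fit_network(benchmark_dataset.expression, benchmark_ivmap, FitConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A light fixture for pipeline-level tests: 12 genes, 10 edges, n=250."""
    return simulate_dataset(n=250, p=12, n_edges=10, reciprocal_pairs=1, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
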