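import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import fateflow as ff

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def make_counts_timecourse(n_per_day=40, n_genes=30, days=(0.0, 1.0, 2.0), seed=0,
                           compartment=False):
    """Small raw-count TimeCourse for unit tests."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes - 2)] + ["mt-a", "mt-b"]
    rows, obs = [], []
    for d in days:
        X = rng.poisson(60.0, size=(n_per_day, n_genes)).astype(float)
        rows.append(X)
        for i in range(n_per_day):
            obs.append({"cell": f"d{d}_c{i}", "timepoint": d,
                        "compartment": ["circulating", "tissue"][i % 2]})
    obs = pd.DataFrame(obs).set_index("cell")
    adata = ad.AnnData(X=np.vstack(rows),
                       obs=obs if compartment else obs[["timepoint"]],
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return ff.TimeCourse(adata, timepoint_key="timepoint",
                         compartment_key="compartment" if compartment else None)


@pytest.fixture
def tiny_tc():
    return make_counts_timecourse()


@pytest.fixture(scope="session")
def bench():
    """Benchmark time course with ground truth (simulated once per session)."""
    return ff.benchmark.prepare(seed=0)


@pytest.fixture(scope="session")
def raw_bench():
    return ff.default_benchmark(0)


@pytest.fixture(scope="session")
def kinetics_results(bench):
    return ff.benchmark.kinetics_recovery(bench)


@pytest.fixture(scope="session")
def trajectory_results(bench):
    return ff.benchmark.trajectory_recovery(bench)


@pytest.fixture(scope="session")
def migration_results(bench):
    return ff.benchmark.migration_recovery(bench)
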