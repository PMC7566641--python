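import numpy as np
import pandas as pd
import pytest

import imprintmeth as im


@pytest.fixture(scope="session")
def sim_bundle():
    """One desk-scale synthetic study shared across read-only tests."""
    return im.simulate_bundle(im.SimConfig.scaled(), seed=7)


@pytest.fixture(scope="session")
def filtered_table(sim_bundle):
    return im.coverage_filter(sim_bundle["table"], min_depth=5)


@pytest.fixture(scope="session")
def diff_results(filtered_table):
    return im.test_cpgs(filtered_table)


@pytest.fixture(scope="session")
def window_grid(sim_bundle):
    cfg = sim_bundle["config"]
    return im.make_windows(cfg.region, cfg.window_width)


def make_toy_table(meth, total, cohorts, pos=None, groups=None):
    """Small MethCallTable from explicit count matrices (samples x sites)."""
    meth = np.asarray(meth)
    total = np.asarray(total)
    n_samp, n_site = meth.shape
    if pos is None:
        pos = np.arange(n_site) * 100 + 1000
    sites = pd.DataFrame({"chrom": "chr11", "pos": pos})
    sites.index.name = "site"
    samples = pd.DataFrame(
        {
            "cohort": cohorts,
            "group": groups if groups is not None else [""] * n_samp,
        },
        index=[f"S{i}" for i in range(n_samp)],
    )
    return im.MethCallTable(sites, samples, meth, total)


@pytest.fixture
def toy_table():
    meth = [[2, 4, 0], [4, 8, 1]]
    total = [[10, 10, 5], [10, 10, 5]]
    return make_toy_table(meth, total, ["beta", "insulinoma"])


def jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
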