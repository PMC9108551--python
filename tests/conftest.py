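import numpy as np
import pytest

from meripscore import CoverageTrack, GeneModel, SampleDesign
from meripscore.simulate import SimConfig, simulate_experiment

import pandas as pd


@pytest.fixture
def gene_simple():
    return GeneModel("gA", "chr1", "+", ((100, 200),))


@pytest.fixture
def gene_spliced():
    return GeneModel("gB", "chr1", "+", ((0, 50), (100, 150)))


def make_track(sample_id, chrom, depths, lib_total=None):
    """Dense track starting at coordinate 0; lib_total defaults to sum(depths)."""
    arr = np.asarray(depths, dtype=np.float64)
    total = float(arr.sum()) if lib_total is None else lib_total
    return CoverageTrack.from_dense(sample_id, {chrom: arr}, lib_total=total)


def uniform_track(sample_id, chrom, length, depth, lib_total):
    return make_track(sample_id, chrom, np.full(length, depth, dtype=float), lib_total)


@pytest.fixture
def design_2x3():
    rows = []
    for cond in ("REF", "PERTURBED"):
        for rep in (1, 2, 3):
            rows.append((f"{cond.lower()}_ip_{rep}", "IP", cond, rep))
            rows.append((f"{cond.lower()}_input_{rep}", "INPUT", cond, rep))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "fraction", "condition", "replicate"])
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A tiny but complete simulated experiment shared across tests."""
    return simulate_experiment(SimConfig(n_genes=12, site_fraction=0.5, mean_depth=30, seed=7))


def scores_from_log2(site_rows):
    """Build a minimal score table from {site_id: {cond: (log2poi list, log2pom list)}}."""
    rows = []
    for site_id, conds in site_rows.items():
        for cond, (l2poi, l2pom) in conds.items():
            for rep, (a, b) in enumerate(zip(l2poi, l2pom), start=1):
                rows.append((site_id, "g0", cond, rep, 2.0**a, 2.0**b, ""))
    return pd.DataFrame(
        rows,
        columns=["site_id", "gene_id", "condition", "replicate", "poi", "pom", "qc_flags"],
    )
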