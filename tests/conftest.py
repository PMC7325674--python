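"""Shared fixtures: synthetic study data reused across the suite.

The paper-like convergence experiment is expensive (minutes), so it is run
once per session and shared by the resampling and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import phylosample as ps


@pytest.fixture(scope="session")
def small_fixture() -> ps.StudyFixture:
    return ps.generate_fixture_study("small", seed=1)


@pytest.fixture(scope="session")
def paperlike_experiment():
    """Full paper-like pipeline: fixture → filter → concat → resample → RF.

    48 taxa, 200 genes with heterogeneous missingness; gap-free block
    filtering, genes > 1000 bp, NJ engine; efforts 0.1%–30%, 30 replicates.
    """
    fixture = ps.generate_fixture_study("paper-like", seed=1)
    filtered = [ps.filter_gap_free_blocks(g, min_block_len=10, min_conserved_frac=0.5)
                for g in fixture.genes]
    selected = ps.select_genes(filtered, min_len=1000)
    bundle = ps.concatenate_supermatrix(selected, fixture.taxa)
    reference = ps.infer_tree(bundle.matrix, engine="nj")
    design = ps.ResamplingDesign(efforts=[0.001, 0.01, 0.10, 0.20, 0.30],
                                 replicates=30, master_seed=1, engine="nj")
    records = ps.run_convergence_experiment(bundle, reference, design)
    return {
        "fixture": fixture,
        "bundle": bundle,
        "reference": reference,
        "design": design,
        "records": records,
        "groups": ps.rf_groups(records),
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
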