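import numpy as np
import pandas as pd
import pytest

import stagesynergy as ss


def small_config(**overrides) -> ss.SimulationConfig:
    """Reduced study conditions for fast unit tests."""
    base = dict(
        samples_per_stage=(60, 60, 60),
        n_lncrna=40, n_mrna=80, n_icp=5,
        n_planted_specific=6, n_planted_uniform=6, n_null_pairs=20,
        n_decoy_pairs=5, n_decoy_ppi_edges=20,
        seed=11,
    )
    base.update(overrides)
    return ss.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One full simulated input bundle shared by read-only tests."""
    return ss.simulate_all(small_config())


@pytest.fixture(scope="session")
def small_expr(small_sim):
    return small_sim["expression"]


@pytest.fixture()
def tiny_expr():
    """Hand-sized two-stage expression matrix for exact-value tests."""
    rng = np.random.default_rng(7)
    genes = ["L1", "L2", "M1", "M2"]
    samples = [f"s{i}" for i in range(20)]
    values = pd.DataFrame(rng.standard_normal((4, 20)), index=genes, columns=samples)
    stages = pd.Series([1] * 10 + [2] * 10, index=samples)
    classes = pd.Series(["lncRNA", "lncRNA", "mRNA", "mRNA"], index=genes)
    icp = pd.Series([False, False, True, False], index=genes)
    return ss.StageLabeledExpression(values=values, sample_stage=stages,
                                     gene_class=classes, icp_flag=icp)
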