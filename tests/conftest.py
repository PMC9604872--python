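import pandas as pd
import pytest

from rulestrat import (
    AlleleFeatureTable,
    SimConfig,
    build_feature_table,
    degrade_to_validation,
    simulate_cohort,
)


def make_table(columns, status, sex=None, coords=None):
    """Build a small AlleleFeatureTable from plain dicts/lists.

    ``columns``: feature -> list of categorical string values;
    ``status``: list of "case"/"control"; ``coords``: feature -> (chrom, pos).
    """
    n = len(status)
    if sex is None:
        sex = ["F"] * n
    samples = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"S{i}" for i in range(n)],
            "sex": sex,
            "status": status,
        }
    )
    values = pd.DataFrame({f: pd.array(v, dtype=object) for f, v in columns.items()})
    return AlleleFeatureTable(samples, values, coords or {})


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_cases=60,
        n_controls=120,
        n_cases_val=40,
        n_controls_val=80,
        n_loci=4,
        variants_per_locus=10,
        block_size=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    table, truth = simulate_cohort(small_cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_feature_table(small_sim):
    table, truth = small_sim
    return build_feature_table(table, truth.hla_window)


@pytest.fixture(scope="session")
def paired_cohorts(small_cfg, small_sim):
    train, truth = small_sim
    valid = degrade_to_validation(train, small_cfg)
    return (
        build_feature_table(train, truth.hla_window),
        build_feature_table(valid, truth.hla_window),
        truth,
    )
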