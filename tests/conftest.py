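import numpy as np
import pytest

from jointglmm import AnalysisConfig, ChildRecord, default_codebook


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture()
def config():
    return AnalysisConfig()


def make_record(i=0, cluster="c0", weight=1.0, **kwargs):
    defaults = dict(
        child_id=f"ch{i}",
        cluster_id=cluster,
        household_id=f"{cluster}-h{i}",
        weight=weight,
    )
    defaults.update(kwargs)
    return ChildRecord(**defaults)


@pytest.fixture(scope="session")
def make_child():
    return make_record


def records_with_counts(counts, variable, levels, outcome):
    """Build unweighted records realizing an LxR contingency table.

    counts[level][j] children get covariate `level` and outcome value j.
    """
    records = []
    i = 0
    for level, per_outcome in zip(levels, counts):
        for value, n in enumerate(per_outcome):
            for _ in range(int(n)):
                records.append(make_record(
                    i=i, cluster=f"c{i % 7}",
                    covariates={variable: level}, **{outcome: value}))
                i += 1
    return records
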