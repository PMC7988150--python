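import numpy as np
import pandas as pd
import pytest

from pmikit import GroupedMatrix, SynthConfig, TimeCourseMatrix, generate_timecourse


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A scaled-down but otherwise default-structured synthetic study."""
    return SynthConfig(n_genes=800, n_neuronal=60, n_glial=80, n_housekeeping=16, seed=11)


@pytest.fixture(scope="session")
def small_timecourse(small_cfg):
    return generate_timecourse(small_cfg)


@pytest.fixture(scope="session")
def noiseless_cfg() -> SynthConfig:
    return SynthConfig(
        n_genes=400, n_neuronal=40, n_glial=50, n_housekeeping=10,
        noise_sd_log2=0.0, seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_timecourse(noiseless_cfg):
    return generate_timecourse(noiseless_cfg)


@pytest.fixture()
def tiny_timecourse() -> TimeCourseMatrix:
    df = pd.DataFrame(
        [[10.0, 9.0, 8.0, 6.0], [5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 4.0, 8.0]],
        index=["GA", "GB", "GC"],
        columns=[0.0, 2.0, 8.0, 24.0],
    )
    return TimeCourseMatrix(df)


def make_grouped(values, genes, n_a=2, n_b=2, levels=("fresh", "postmortem")) -> GroupedMatrix:
    values = np.asarray(values, dtype=float)
    samples = [f"{levels[0]}_{i+1}" for i in range(n_a)] + [
        f"{levels[1]}_{i+1}" for i in range(n_b)
    ]
    group_of = {s: levels[0] if i < n_a else levels[1] for i, s in enumerate(samples)}
    return GroupedMatrix(
        pd.DataFrame(values, index=genes, columns=samples), group_of=group_of, levels=levels
    )
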