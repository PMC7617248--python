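"""Shared fixtures: tiny hand-built studies and fast MCMC settings."""

import warnings

import pytest

from nmabridge import ArmRecord, MCMCSettings, Study, SubgroupDataset

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


def make_study(sid, arms, subgroup="P1", year=None, rob=None):
    """arms: iterable of (treatment, n, mean, sd)."""
    return Study(
        study_id=sid,
        subgroup=subgroup,
        arms=tuple(ArmRecord(sid, t, n, m, s) for t, n, m, s in arms),
        year=year,
        rob=rob,
    )


def make_dataset(studies, subgroup="P1"):
    return SubgroupDataset(subgroup=subgroup, studies=tuple(studies))


@pytest.fixture
def fast_mcmc():
    """Short chains for unit tests; conjugate Gibbs mixes in a few hundred."""
    return MCMCSettings(iterations=1500, burnin=400, seed=11)


@pytest.fixture
def two_arm_study():
    return make_study("s1", [("Placebo", 50, 0.0, 2.0), ("DrugA", 50, 1.0, 2.0)])


@pytest.fixture
def triangle_ds():
    """Three treatments, direct evidence on all three edges."""
    return make_dataset(
        [
            make_study("t1", [("Placebo", 80, 0.0, 2.0), ("DrugA", 80, 0.8, 2.0)]),
            make_study("t2", [("Placebo", 80, 0.1, 2.0), ("DrugB", 80, 1.1, 2.0)]),
            make_study("t3", [("DrugA", 80, 0.0, 2.0), ("DrugB", 80, 0.45, 2.0)]),
            make_study("t4", [("Placebo", 80, -0.1, 2.0), ("DrugA", 80, 0.75, 2.0)]),
        ]
    )
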