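import pytest

from rtexclude import SimConfig, run_experiment

#: Seed and replication of the shared reduced-scale study run.  500 pairs per
#: difference level per approach keeps the whole grid near two minutes while
#: giving aggregate bias estimates a Monte-Carlo SE around 0.0015.
STUDY_SEED = 2021
STUDY_REPS = 500


@pytest.fixture(scope="session")
def study():
    """Reduced-replication run of the full study grid.

    101 difference levels x 500 pairs x both contamination approaches x all
    ten exclusion rules, from a fixed master seed.  Shared by every test
    that checks aggregate behaviour.
    """
    return run_experiment(SimConfig(reps_per_diff=STUDY_REPS, master_seed=STUDY_SEED))


@pytest.fixture(scope="session")
def tiny_study():
    """A minimal but complete run for shape, determinism and IO tests."""
    cfg = SimConfig(
        diff_grid=(0.0, 50.0, 100.0), reps_per_diff=30, master_seed=7
    )
    return run_experiment(cfg)
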