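import numpy as np
import pytest

from curesurv.simulate import SyntheticConfig, study_replica_cohort


@pytest.fixture(scope="session")
def replica():
    """The deterministic 201-record study-replica cohort (fixed seed)."""
    return study_replica_cohort(seed=1)


@pytest.fixture(scope="session")
def replica_survival(replica):
    """(times, events) of the 189 analyzed patients (postop deaths excluded)."""
    from curesurv.cohort import exclude_postoperative_deaths

    analyzed = exclude_postoperative_deaths(replica)
    return (
        analyzed.df["time_months"].to_numpy(dtype=float),
        analyzed.df["event"].to_numpy(dtype=int),
    )


@pytest.fixture()
def tiny_csv(tmp_path):
    """Write a minimal 3-row cohort file and return its path."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "id,time_months,event,postop_death,age,lauren,stage,her2_membrane\n"
        "a,1.0,1,0,60,intestinal,IA,2\n"
        "b,2.0,0,0,70,diffuse,II,0\n"
        "c,3.0,1,0,55,,IVM1,NA\n"
    )
    return path


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


def draw_survival(config, seed):
    """Seeded survival draw used across recovery tests."""
    from curesurv.simulate import simulate_survival

    return simulate_survival(config, seed=seed)
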