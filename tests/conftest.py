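import numpy as np
import pandas as pd
import pytest

from markovcea import LifeTable, MarkovCohortModel
from markovcea.defaults import default_cohort_config


@pytest.fixture(scope="session")
def packaged_table() -> LifeTable:
    return LifeTable.packaged_synthetic()


@pytest.fixture(scope="session")
def reference_model(packaged_table) -> MarkovCohortModel:
    """Base-case model on the packaged reference inputs and synthetic table."""
    return MarkovCohortModel.from_reference_inputs(life_table=packaged_table)


def constant_table(qx: float, age_min: int = 0, age_max: int = 200) -> LifeTable:
    """Life table with the same annual death probability at every age/sex."""
    frames = []
    for sex in ("M", "F"):
        frames.append(
            pd.DataFrame(
                {"age": np.arange(age_min, age_max + 1), "sex": sex, "qx": qx}
            )
        )
    return LifeTable(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully populated synthetic cohort (fast to generate)."""
    from markovcea import generate_cohort

    cfg = default_cohort_config(n_intervention=30, n_comparator=30, seed=7)
    return generate_cohort(cfg)
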