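import numpy as np
import pandas as pd
import pytest

import dabench


@pytest.fixture
def small_ct():
    """2 features x 3 samples hand table."""
    return dabench.CountTable(
        pd.DataFrame(
            [[11, 11, 0], [5, 0, 20]],
            index=["fA", "fB"],
            columns=["s1", "s2", "s3"],
        )
    )


@pytest.fixture(scope="session")
def template_16s_small():
    return dabench.builtin_template("16s", n_features=150)


@pytest.fixture(scope="session")
def sim_strong(template_16s_small):
    """NB simulation with a strong injected signal (fold 5, n=20/group)."""
    design = dabench.SimulationDesign(
        distribution="NB", n_per_group=20, fold_effect=5.0,
        da_proportion=0.10, seed=11,
    )
    return dabench.simulate_dataset(design, template_16s_small, replicate_index=0)


@pytest.fixture(scope="session")
def sim_null(template_16s_small):
    """Null NB simulation (no injection), 40 samples."""
    design = dabench.SimulationDesign(distribution="NB", n_per_group=20, seed=13)
    return dabench.simulate_dataset(
        design, template_16s_small, replicate_index=0, inject=False
    )


@pytest.fixture(scope="session")
def annotations_150():
    rng = np.random.default_rng(99)
    tpl = dabench.builtin_template("16s", n_features=150)
    return pd.Series(
        rng.choice(
            ["aerobic", "anaerobic", "facultative", "unassigned"],
            size=150, p=[0.3, 0.3, 0.2, 0.2],
        ),
        index=pd.Index(tpl.feature_ids),
    )
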