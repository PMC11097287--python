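import numpy as np
import pandas as pd
import pytest

from ratddm.presets import default_config, sample_session_config
from ratddm.task import generate_session


@pytest.fixture(scope="session")
def control_session() -> pd.DataFrame:
    """One complete control session at group-mean parameters."""
    cfg = default_config("control", seed=3, session_time_budget=np.inf)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_study() -> pd.DataFrame:
    """Eight sessions (4 control, 4 inhibition) with generous engagement,
    suitable for preparing a small hierarchical fit."""
    rng = np.random.default_rng(11)
    logs = []
    for i in range(8):
        cond = "control" if i % 2 == 0 else "inhibition"
        cfg = sample_session_config(
            cond,
            rng,
            free_choice_fraction=0.55,
            p_initiate=0.95,
            p_complete_given_initiated=0.97,
            session_time_budget=np.inf,
        )
        logs.append(generate_session(cfg, session_id=f"{cond}_{i}"))
    return pd.concat(logs, ignore_index=True)
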