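import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pwimeta.core_data import TrialTable, make_trial_frame

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_table() -> TrialTable:
    """Two participants x two items, both conditions, with some errors."""
    frame = make_trial_frame(
        study="s1",
        participant=["p1", "p1", "p1", "p1", "p2", "p2", "p2", "p2", "p2", "p2"],
        item=["i1", "i2", "i1", "i2", "i1", "i2", "i1", "i2", "i1", "i2"],
        condition=["related", "related", "unrelated", "unrelated"] * 2 + ["related", "unrelated"],
        rt=[650.0, 720.0, 610.0, 700.0, 580.0, 630.0, 560.0, 615.0, 900.0, 880.0],
        correct=[True, True, True, False, True, True, True, True, True, True],
    )
    return TrialTable(data=frame)


def balanced_table(
    n_participants: int,
    per_condition: int,
    rng: np.random.Generator,
    study: str = "s1",
    effect: float = 25.0,
) -> TrialTable:
    """Participants with `per_condition` trials per condition; related RTs
    shifted by `effect` ms."""
    rows = []
    for p in range(n_participants):
        base = rng.normal(650, 60, per_condition)
        for cond, shift in (("related", effect), ("unrelated", 0.0)):
            rts = np.abs(base + shift + rng.normal(0, 40, per_condition)) + 1.0
            for t, rt in enumerate(rts):
                rows.append((study, f"p{p}", f"i{t}", cond, rt, True))
    frame = pd.DataFrame(rows, columns=["study", "participant", "item", "condition", "rt", "correct"])
    return TrialTable(data=frame)
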