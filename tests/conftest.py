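"""Shared fixtures: small synthetic sessions generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cinda.synth import BehaviorSpec, gen_behavior, gen_spikes

EMPTY_TRIALS = pd.DataFrame(
    {c: pd.Series(dtype=float) for c in ("go_cue", "center_out", "side_in")}
    | {"outcome": pd.Series(dtype=int), "choice": pd.Series(dtype=object)}
)


def homogeneous_train(
    rate: float, shape: float, duration: float, seed: int
) -> np.ndarray:
    """Stationary gamma-renewal spike train (no event kernels)."""
    train, _ = gen_spikes(
        EMPTY_TRIALS, rate, shape, [], seed=seed, duration=duration
    )
    return train.spike_times


@pytest.fixture(scope="session")
def behavior_300():
    """One 300-trial bandit session shared by read-only tests."""
    trials, gt = gen_behavior(BehaviorSpec(n_blocks=9), seed=11, n_trials=300)
    return trials, gt


@pytest.fixture(scope="session")
def session_duration_300(behavior_300):
    trials, _ = behavior_300
    return float(trials["side_in"].max()) + 10.0
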