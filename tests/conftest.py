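import numpy as np
import pytest

from lamflow import SimConfig, make_ground_truth, simulate_session


@pytest.fixture(scope="session")
def attention_session():
    """One simulated attention-task penetration (shared, read-only)."""
    cfg = SimConfig(
        task="attention",
        conditions=("target", "distractor"),
        n_trials_per_condition=12,
        seed=42,
    )
    gt = make_ground_truth(cfg, "attention_like")
    rec, trials = simulate_session(gt, cfg)
    return gt, cfg, rec, trials


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
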