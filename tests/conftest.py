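import numpy as np
import pandas as pd
import pytest

import revlearn as rl


@pytest.fixture(scope="session")
def default_schedule() -> rl.TrialSchedule:
    return rl.make_schedule(rl.TaskDesign(), seed=1)


@pytest.fixture(scope="session")
def small_cell() -> pd.DataFrame:
    """15 subjects x 80 stable trials simulated from the RP model."""
    rng = np.random.default_rng(7)
    rows = []
    for s in range(15):
        params = rl.RLParams(
            alpha_pos=float(np.clip(rng.normal(0.35, 0.12), 0.02, 0.98)),
            alpha_neg=float(np.clip(rng.normal(0.25, 0.10), 0.02, 0.98)),
            beta=float(np.clip(rng.normal(4.0, 1.0), 0.3, 9.5)),
        )
        sched = rl.make_schedule(rl.stable_design(), seed=1000 + s)
        rows.append(
            rl.simulate_choices(
                sched, params, "RP", seed=2000 + s, subject=f"s{s:02d}",
                group="OT", context="stable",
            )
        )
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="session")
def small_fit(small_cell) -> rl.PosteriorFit:
    """A quick hierarchical RP fit reused by several tests."""
    cfg = rl.FitConfig(chains=2, warmup=300, draws=300, seed=11)
    return rl.fit_hierarchical(small_cell, "RP", config=cfg)
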