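import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import rewardbias as rb


@pytest.fixture(scope="session")
def table1_params() -> rb.ModelParams:
    """Group-level generative parameters used throughout the simulations."""
    return rb.ModelParams(beta0=0.81, beta1=4.01, alpha=0.02)


@pytest.fixture(scope="session")
def default_config() -> rb.TaskConfig:
    return rb.TaskConfig()


@pytest.fixture(scope="session")
def schedule(default_config) -> rb.TrialSchedule:
    return rb.build_trial_schedule(default_config, seed=7)


@pytest.fixture(scope="session")
def agent_dataset(schedule, table1_params) -> pd.DataFrame:
    """One context-dependent agent simulated on the default schedule."""
    return rb.simulate_agent(schedule, table1_params, rb.CONTEXT_DEPENDENT,
                             seed=11, participant_id="a01")


@pytest.fixture(scope="session")
def small_cohort(table1_params) -> dict[str, pd.DataFrame]:
    """Six context-dependent agents on full-length schedules."""
    return rb.simulate_cohort(table1_params, rb.CONTEXT_DEPENDENT,
                              n_agents=6, seed=42)


def simulate_glm_cohort(seed: int, n_participants: int = 10,
                        n_per_run: int = 28, sigma_u: float = 0.5,
                        b_coherence: float = 4.0, b_context: float = 0.0,
                        b_context_by_run: float = 0.0) -> pd.DataFrame:
    """Choices from a random-intercept logistic model (no learning), for
    testing the hierarchical regression: eta = b_coh*S + context effects + u_i.

    ``b_context_by_run`` adds a context effect growing linearly with run,
    emulating bias acquisition."""
    rng = np.random.default_rng(seed)
    levels = np.array([-0.64, -0.12, -0.04, 0.0, 0.04, 0.12, 0.64])
    rows = []
    for i in range(n_participants):
        u = rng.normal(0.0, sigma_u)
        for run in range(1, 6):
            coh = rng.choice(levels, n_per_run)
            ctx = rng.integers(0, 2, n_per_run)
            eta = (b_coherence * coh + b_context * ctx
                   + b_context_by_run * (run - 1) * (2 * ctx - 1) + u)
            y = (rng.random(n_per_run) < expit(eta)).astype(int)
            rows.append(pd.DataFrame({
                "participant_id": f"p{i:02d}", "run": run, "coherence": coh,
                "context": ctx, "choice": y,
            }))
    return pd.concat(rows, ignore_index=True)
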