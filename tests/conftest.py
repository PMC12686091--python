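import numpy as np
import pandas as pd
import pytest

from implicit_precision.synthetic_data import (
    PopulationSpec,
    TaskTemplate,
    simulate_task_data,
)


@pytest.fixture(scope="session")
def latency_template() -> TaskTemplate:
    return TaskTemplate("IAT", "latency", 30, 30)


@pytest.fixture(scope="session")
def small_cell(latency_template):
    """One simulated measure x domain cell: 12 participants, known truth."""
    pop = PopulationSpec(n_participants=12, mu_delta=80.0, tau_delta=60.0, seed=11)
    trials, truth = simulate_task_data(latency_template, pop, domain="race")
    return trials, truth


@pytest.fixture()
def tiny_trials() -> pd.DataFrame:
    """Hand-built 2-participant trial table with roles assigned."""
    rows = []
    rng = np.random.default_rng(5)
    for pid, shift in [("p1", 0.0), ("p2", 120.0)]:
        for role, base in [("A", 500.0), ("B", 500.0 + shift)]:
            for t in range(8):
                rows.append(
                    {
                        "participant_id": pid,
                        "measure": "IAT",
                        "domain": "race",
                        "block_label": f"critical_{role}",
                        "block_role": role,
                        "trial_index": t + 1 + (8 if role == "B" else 0),
                        "latency_ms": base + rng.normal(0, 60),
                        "accuracy": 1.0,
                        "response_value": np.nan,
                    }
                )
    df = pd.DataFrame(rows)
    df["response_value"] = df["latency_ms"]
    return df
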