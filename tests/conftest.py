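import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from hfpefsim.analysis import percent_changes
from hfpefsim.baroreflex import group_baroreflex
from hfpefsim.experiments import run_grid
from hfpefsim.network import run_to_steady_state
from hfpefsim.parameters import group_preset


@pytest.fixture(scope="session")
def grid():
    """Full study grid: 2 groups x 2 conditions x (baseline + 4 devices)."""
    summaries, failures = run_grid()
    assert not failures, f"grid cells failed: {failures}"
    return summaries


@pytest.fixture(scope="session")
def change_panel(grid):
    baselines = {(g, c): v for (g, c, d), v in grid.items() if d == "baseline"}
    device_summaries = {k: v for k, v in grid.items() if k[2] != "baseline"}
    return percent_changes(device_summaries, baselines)


@pytest.fixture(scope="session")
def sol_g1_rest():
    """Converged Group 1 resting baseline solution (full time series)."""
    return run_to_steady_state(group_preset(1), group_baroreflex(1))
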