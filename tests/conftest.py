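import numpy as np
import pytest

from patchforage import (
    AgentPolicy,
    EnvironmentConfig,
    ForagingEventLog,
    generate_patch_layout,
    simulate_run,
)
from patchforage.records import Event, Sample


@pytest.fixture(scope="session")
def default_config():
    return EnvironmentConfig()


@pytest.fixture(scope="session")
def layout(default_config):
    return generate_patch_layout(default_config, seed=1)


@pytest.fixture(scope="session")
def giveup_log(layout):
    """One full run of a give-up-time forager (shared, read-only)."""
    return simulate_run(layout, AgentPolicy(kind="give_up_time", giveup_s=6.0), seed=9)


@pytest.fixture(scope="session")
def mvt_instrument_policy():
    """The planted-offset instrument: deliberate sweep traveler, systematic harvester."""

    def make(offset: float) -> AgentPolicy:
        return AgentPolicy(
            kind="mvt_offset",
            olt_offset_s=offset,
            travel_strategy="sweep",
            within_patch_strategy="lawnmower",
            travel_speed=15.0,
        )

    return make


def make_log(
    events: list[tuple],
    duration: float = 60.0,
    dt: float = 0.05,
    participant_id: str = "T1",
    run_index: str = "pre",
) -> ForagingEventLog:
    """Hand-built event log on a uniform sample grid (stationary agent).

    ``events`` are (t, type, patch_id) tuples; positions are synthetic
    since reward-rate analysis only consumes times.
    """
    n = int(round(duration / dt))
    samples = [Sample(k * duration / n, "aerial", None, 300.0, 300.0) for k in range(n + 1)]
    evs = [Event(t, typ, pid) for (t, typ, pid) in events]
    log = ForagingEventLog(
        participant_id=participant_id,
        run_index=run_index,
        duration=duration,
        samples=samples,
        events=evs,
    )
    log.validate()
    return log


def harvest_visit_events(
    t_enter: float,
    reward_times: list[float],
    t_exit: float,
    patch_id: int = 0,
) -> list[tuple]:
    evs = [(t_enter, "patch_enter", patch_id)]
    evs += [(t, "reward", patch_id) for t in reward_times]
    evs.append((t_exit, "patch_exit", patch_id))
    return evs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
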