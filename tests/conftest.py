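import numpy as np
import pandas as pd
import pytest

from itibias.agent import AgentSpec, simulate_agent_session
from itibias.history import ModelParams
from itibias.session import TRIAL_COLUMNS, Session


def make_session(stimulus, choice, light=None, with_times=False, iti=8.0):
    """Hand-rolled session from stimulus/choice lists; outcome follows the
    reward-iff-match coding."""
    n = len(stimulus)
    light = [False] * n if light is None else light
    rows = []
    t = 0.0
    for i, (s, c) in enumerate(zip(stimulus, choice)):
        o = -1 if c == s else 1
        if with_times:
            t_stim, t_go = t + iti, t + iti + 3.0
            if c != 0:
                t_move, t_target = t_go + 0.3, t_go + 0.45
                t_reward = t_target if o == -1 else np.nan
                t = t_target + 0.5
            else:
                t_move = t_target = t_reward = np.nan
                t = t_go + 1.5
            times = (t_stim, t_go, t_move, t_target, t_reward)
        else:
            times = (np.nan,) * 5
        rows.append((i + 1, s, c, o, bool(light[i]), False, *times, "test"))
    return Session(pd.DataFrame(rows, columns=TRIAL_COLUMNS), iti_seconds=iti)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def history_agent_session():
    """A history-driven agent session reused by model-fit tests."""
    rng = np.random.default_rng(777)
    spec = AgentSpec(params=ModelParams(w_s=1.0, w_o=1.5, tau_o=2.0, w_c=-1.0, tau_c=10.0))
    return simulate_agent_session(spec, 400, rng=rng)


@pytest.fixture(scope="session")
def small_recording():
    """Small synthetic recording with bias-, outcome-, movement-tuned and
    untuned cells, shared across neural analysis tests."""
    from itibias.neural_sim import CellSpec, generate_population

    rng = np.random.default_rng(424242)
    spec = AgentSpec(params=ModelParams(w_s=1.0, w_o=1.5, tau_o=2.0, w_c=-0.8,
                                        tau_c=10.0, constant=0.2))
    session = simulate_agent_session(spec, 180, rng=rng)
    cells = (
        [CellSpec(tuning={"bias": 18.0 * (1 if i % 2 else -1)},
                  baseline_rate=20.0, noise_sd=0.03) for i in range(6)]
        + [CellSpec(tuning={"n1_outcome": 25.0 * (1 if i % 2 else -1)},
                    baseline_rate=20.0, noise_sd=0.03) for i in range(4)]
        + [CellSpec(tuning={"movement": 150.0}, baseline_rate=5.0, noise_sd=0.03)]
        + [CellSpec(tuning={}, baseline_rate=20.0, noise_sd=0.03) for _ in range(3)]
    )
    return generate_population(session, cells, rng=rng)
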