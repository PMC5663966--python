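"""Pseudo-random stimulus engine, light-trial assignment, chance-level simulation.

The task draws the drifting-grating direction at random with two constraints
that discourage one-sided responding: after an error the same stimulus is
repeated, and after three consecutive rewarded trials on one direction the
stimulus switches to the other direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class TaskError(ValueError):
    pass


@dataclass
class StimulusRuleState:
    """State carried between trials by the stimulus rules.

    ``consecutive_rewards_same_dir`` counts uninterrupted rewards on the
    identical stimulus; any error (including no-response trials, which are
    coded as errors) or stimulus change resets it.
    """

    last_outcome: Optional[int] = None
    consecutive_rewards_same_dir: int = 0
    last_stimulus: Optional[int] = None

    def update(self, stimulus: int, outcome: int) -> None:
        """Record a completed trial."""
        if outcome == -1:  # reward
            if self.last_stimulus == stimulus and self.consecutive_rewards_same_dir > 0:
                self.consecutive_rewards_same_dir += 1
            else:
                self.consecutive_rewards_same_dir = 1
        else:
            self.consecutive_rewards_same_dir = 0
        self.last_outcome = int(outcome)
        self.last_stimulus = int(stimulus)


def next_stimulus(state: StimulusRuleState, rng: np.random.Generator) -> int:
    """Draw the next stimulus under the task's pseudo-random rules."""
    if state.last_outcome == 1 and state.last_stimulus is not None:
        return state.last_stimulus
    if state.consecutive_rewards_same_dir >= 3 and state.last_stimulus is not None:
        return -state.last_stimulus
    return int(rng.choice((-1, 1)))


def assign_light_trials(
    n_trials: int,
    fraction: float = 0.15,
    min_gap: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Pseudo-random light-on flags with >= ``min_gap`` off-trials between
    consecutive on-trials.

    Samples uniformly among all feasible configurations with exactly
    round(fraction * n_trials) on-trials, via the gap bijection: on-positions
    p_1 < ... < p_k with p_{i+1} - p_i > min_gap map one-to-one onto k
    distinct values in a contracted range.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_trials < 1:
        raise TaskError("n_trials must be >= 1")
    if not 0.0 <= fraction <= 1.0:
        raise TaskError("fraction must lie in [0, 1]")
    k = int(round(fraction * n_trials))
    flags = np.zeros(n_trials, dtype=bool)
    if k == 0:
        return flags
    span = n_trials - (k - 1) * min_gap
    if span < k:
        raise TaskError(
            f"cannot place {k} light-on trials in {n_trials} trials with min_gap={min_gap}"
        )
    base = np.sort(rng.choice(span, size=k, replace=False))
    positions = base + np.arange(k) * min_gap
    flags[positions] = True
    return flags


def simulate_rule_stimuli(
    chooser,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the stimulus rules against an arbitrary chooser callable.

    ``chooser(stimulus, rng) -> choice`` in {-1, 0, +1}. Returns (stimuli,
    choices) arrays. Outcomes follow the coding: reward iff choice == stimulus.
    """
    state = StimulusRuleState()
    stimuli = np.empty(n_trials, dtype=int)
    choices = np.empty(n_trials, dtype=int)
    for n in range(n_trials):
        s = next_stimulus(state, rng)
        c = int(chooser(s, rng))
        outcome = -1 if c == s else 1
        state.update(s, outcome)
        stimuli[n] = s
        choices[n] = c
    return stimuli, choices


def estimate_chance_level(session, n_sim: int = 1000, rng=None) -> dict:
    """Chance-level discrimination for a session under the stimulus rules.

    Estimates the session's constant choice preference as
    P(choice +1) = 1/2 (P(+1 | stim +1) + P(+1 | stim -1)) over
    target-reaching trials, then simulates a fixed-probability chooser under
    the same pseudo-random stimulus rules ``n_sim`` times.
    """
    rng = np.random.default_rng() if rng is None else rng
    stim = session.stimulus
    choice = session.choice
    reaching = choice != 0
    stim, choice = stim[reaching], choice[reaching]
    probs = []
    for s in (1, -1):
        m = stim == s
        if not m.any():
            raise TaskError(f"stimulus {s:+d} never shown among reaching trials")
        probs.append(np.mean(choice[m] == 1))
    p_forward = 0.5 * (probs[0] + probs[1])
    n_trials = int(reaching.sum())

    def chooser(_stim, r):
        return 1 if r.random() < p_forward else -1

    fracs = np.empty(n_sim)
    for i in range(n_sim):
        stimuli, choices = simulate_rule_stimuli(chooser, n_trials, rng)
        fracs[i] = np.mean(choices == stimuli)
    return {
        "p_forward": float(p_forward),
        "chance_mean": float(fracs.mean()),
        "chance_distribution": fracs,
    }
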