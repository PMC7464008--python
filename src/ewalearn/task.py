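"""Two-armed probabilistic reversal-learning task structure.

The task presents two stimuli for a fixed number of trials; one stimulus is
"correct" (high reward probability) at any time, and the contingency flips
exactly once at the reversal boundary. Feedback is probabilistic: choosing
the correct stimulus yields positive feedback with probability
``p_reward_correct`` (default 0.8), choosing the other stimulus with
probability ``p_reward_incorrect`` (default 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TaskConfig", "generate_task", "simulate_feedback"]


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of the reversal-learning task.

    Parameters
    ----------
    n_trials
        Total number of trials (default 80).
    reversal_trial
        1-based index of the first trial of the reversal phase (default 41,
        i.e. 40 discrimination trials followed by 40 reversal trials).
    p_reward_correct
        Probability of positive feedback when the currently correct
        stimulus is chosen.
    p_reward_incorrect
        Probability of positive feedback when the other stimulus is chosen.
    n_stimuli
        Number of stimuli (two-armed task: 2).
    """

    n_trials: int = 80
    reversal_trial: int = 41
    p_reward_correct: float = 0.8
    p_reward_incorrect: float = 0.2
    n_stimuli: int = 2

    def __post_init__(self) -> None:
        if not 1 < self.reversal_trial <= self.n_trials:
            raise ValueError(
                f"reversal_trial must lie in (1, n_trials]; got "
                f"{self.reversal_trial} with n_trials={self.n_trials}"
            )
        for name in ("p_reward_correct", "p_reward_incorrect"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability; got {p}")
        if self.n_stimuli < 2:
            raise ValueError("n_stimuli must be at least 2")

    @property
    def n_discrimination(self) -> int:
        """Number of trials in the discrimination (pre-reversal) phase."""
        return self.reversal_trial - 1

    @property
    def n_reversal(self) -> int:
        """Number of trials in the reversal phase."""
        return self.n_trials - self.reversal_trial + 1

    def phase_of(self, trial: int) -> str:
        """Phase label ('discrimination' or 'reversal') of a 1-based trial."""
        return "discrimination" if trial < self.reversal_trial else "reversal"


def generate_task(
    config: TaskConfig = TaskConfig(), seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Return the per-trial identity of the currently correct stimulus.

    The initially correct stimulus is drawn at random; the contingency then
    flips exactly once at ``config.reversal_trial``.

    Returns
    -------
    ndarray of shape (n_trials,) with entries in {0, 1}.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    first = int(rng.integers(config.n_stimuli))
    schedule = np.empty(config.n_trials, dtype=np.int64)
    schedule[: config.n_discrimination] = first
    schedule[config.n_discrimination :] = (first + 1) % config.n_stimuli
    return schedule


def simulate_feedback(
    choice: int,
    correct_stimulus: int,
    config: TaskConfig,
    rng: np.random.Generator,
) -> int:
    """Draw binary feedback for one choice under the task's reward schedule."""
    p = config.p_reward_correct if choice == correct_stimulus else config.p_reward_incorrect
    return int(rng.random() < p)
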