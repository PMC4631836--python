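"""Precision-clamp schedules: simulated dopamine depletion and stimulation.

A clamp overrides the expected precision at selected epochs of selected
trials, optionally contingent on the action taken earlier in the trial.
Clamping touches nothing but the precision pathway — state estimation and
Dirichlet learning receive the clamped value through the ordinary update
equations and are otherwise untouched, mirroring the Markov-blanket
separation between precision and the model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ClampSchedule", "depletion_schedule", "stimulation_schedule"]


@dataclass
class ClampSchedule:
    """Per-epoch precision overrides over a range of trials.

    Parameters
    ----------
    epoch_values : dict
        Map from 0-based epoch index to the clamp value (> 0). Epochs not in
        the map are left free.
    trial_range : tuple or None
        Half-open (start, stop) range of 0-based trial indices over which
        the schedule applies; ``None`` means every trial.
    contingent_on : int or None
        If set, the clamp applies only on trials where this control index
        was the action taken at the choice transition.
    """

    epoch_values: dict = field(default_factory=dict)
    trial_range: tuple | None = None
    contingent_on: int | None = None

    def __post_init__(self) -> None:
        for epoch, value in self.epoch_values.items():
            if value <= 0:
                raise ValueError(f"clamp value must be positive (epoch {epoch}: {value})")

    def clamp_value(
        self, trial: int, epoch: int, chosen_action: int | None = None
    ) -> float | None:
        """Clamp for (trial, epoch), or ``None`` if precision is free.

        ``chosen_action`` is the control taken at the trial's choice
        transition (``None`` before the choice is made); it is consulted
        only when the schedule is action-contingent.
        """
        if self.trial_range is not None:
            start, stop = self.trial_range
            if not start <= trial < stop:
                return None
        if self.contingent_on is not None and chosen_action != self.contingent_on:
            return None
        return self.epoch_values.get(epoch)

    @classmethod
    def none(cls) -> "ClampSchedule":
        """An empty schedule: precision is always inferred."""
        return cls(epoch_values={})


def depletion_schedule(
    value: float = 0.1, trial_range: tuple | None = None, T: int = 6
) -> ClampSchedule:
    """Clamp precision to a low value at every epoch (simulated depletion).

    With precision pinned near zero the policy posterior is nearly uniform
    at every epoch, so behavior becomes outcome-insensitive while state
    estimation and learning continue unimpeded.
    """
    return ClampSchedule(
        epoch_values={t: value for t in range(T)}, trial_range=trial_range
    )


def stimulation_schedule(
    value: float = 16.0,
    contingent_on: int | None = None,
    trial_range: tuple | None = None,
    T: int = 6,
) -> ClampSchedule:
    """Clamp precision at the final epoch only (simulated midbrain stimulation).

    The default clamp of 16 exceeds the unclamped ceiling (the prior-mean
    precision), forcing the agent to explain the impossibly high confidence —
    which it can only do by inferring it reached a valuable (win) state. If
    ``contingent_on`` is given, stimulation follows only that action.
    """
    return ClampSchedule(
        epoch_values={T - 1: value},
        trial_range=trial_range,
        contingent_on=contingent_on,
    )
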