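"""Rule-based adaptive agent: difficulty adaptation, role switching, forcing.

The agent observes per-session quiz accuracy and a 1-5 self-reported anxiety
slider and applies fixed threshold rules:

* accuracy > 80%  -> advance one difficulty level
* accuracy < 60%  -> drop one difficulty level and give remedial hints
* slider > 3      -> switch role away from the default tutor: to the
  empathetic peer supporter when the student is also struggling
  (accuracy < 60%), otherwise to the motivator (who awards a reward badge)
* otherwise       -> tutor

Thresholds are strict, so boundary values (exactly 80% or slider 3) trigger
nothing.  At most ``max_adaptations`` (default 3) adaptations — nonzero
difficulty deltas or role changes — are applied per session; once the cap is
reached further observations in the same session are ignored.

``session_forcing`` maps the post-decision agent state to the forcing pair
(I, S) that drives the kinetic model.  The map is a package design choice
(nothing in the underlying study pins it down numerically) and every
constant is exposed in :class:`AgentConfig`: intensity rises with non-tutor
support roles and with the amount of within-session adaptation; stress is
proportional to relative difficulty and is relieved by the peer supporter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

__all__ = [
    "Role",
    "AgentConfig",
    "AgentState",
    "SessionObservation",
    "AgentAction",
    "decide",
    "apply_action",
    "session_forcing",
]


class Role(str, Enum):
    TUTOR = "tutor"
    PEER_SUPPORTER = "peer_supporter"
    MOTIVATOR = "motivator"


@dataclass(frozen=True)
class AgentConfig:
    """Thresholds and forcing-map constants, all overridable."""

    levels: int = 5
    advance_threshold: float = 0.80
    remediate_threshold: float = 0.60
    anxiety_threshold: int = 3
    max_adaptations: int = 3
    base_intensity: float = 0.5
    role_intensity_bonus: float = 0.1
    adaptation_intensity_bonus: float = 0.05
    support_stress_relief: float = 0.1

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not (0 <= self.remediate_threshold <= self.advance_threshold <= 1):
            raise ValueError("need 0 <= remediate <= advance <= 1")
        if not (1 <= self.anxiety_threshold <= 5):
            raise ValueError("anxiety_threshold must be in [1, 5]")


DEFAULT_AGENT_CONFIG = AgentConfig()


@dataclass(frozen=True)
class AgentState:
    """Current difficulty level, active role and per-session adaptation count."""

    difficulty: int = 3
    role: Role = Role.TUTOR
    adaptations_this_session: int = 0

    def validate(self, config: AgentConfig) -> None:
        if not (1 <= self.difficulty <= config.levels):
            raise ValueError(f"difficulty {self.difficulty} outside [1, {config.levels}]")
        if not (0 <= self.adaptations_this_session <= config.max_adaptations):
            raise ValueError("adaptation count outside [0, max_adaptations]")


@dataclass(frozen=True)
class SessionObservation:
    """One decision input: quiz accuracy in [0,1] and anxiety slider in 1..5."""

    quiz_accuracy: float
    anxiety_slider: int

    def __post_init__(self):
        if not (0.0 <= self.quiz_accuracy <= 1.0):
            raise ValueError("quiz_accuracy must lie in [0, 1]")
        if self.anxiety_slider not in (1, 2, 3, 4, 5):
            raise ValueError("anxiety_slider must be an integer in 1..5")


@dataclass(frozen=True)
class AgentAction:
    """Decided difficulty delta, role, and support flags."""

    difficulty_delta: int = 0
    new_role: Role = Role.TUTOR
    remedial_hints: bool = False
    reward_badge: bool = False

    def __post_init__(self):
        if self.difficulty_delta not in (-1, 0, 1):
            raise ValueError("difficulty_delta must be -1, 0 or +1")
        if self.remedial_hints and self.difficulty_delta != -1:
            raise ValueError("remedial hints accompany only a difficulty reduction")


def decide(
    obs: SessionObservation,
    state: AgentState,
    config: AgentConfig = DEFAULT_AGENT_CONFIG,
) -> AgentAction:
    """Pure threshold-rule decision; inert when the session cap is reached."""
    state.validate(config)
    if state.adaptations_this_session >= config.max_adaptations:
        return AgentAction(0, state.role, False, False)

    if obs.quiz_accuracy > config.advance_threshold:
        delta, hints = 1, False
    elif obs.quiz_accuracy < config.remediate_threshold:
        delta, hints = -1, True
    else:
        delta, hints = 0, False

    if obs.anxiety_slider > config.anxiety_threshold:
        role = (
            Role.PEER_SUPPORTER
            if obs.quiz_accuracy < config.remediate_threshold
            else Role.MOTIVATOR
        )
    else:
        role = Role.TUTOR
    return AgentAction(delta, role, hints, reward_badge=(role is Role.MOTIVATOR))


def apply_action(
    state: AgentState, action: AgentAction, config: AgentConfig = DEFAULT_AGENT_CONFIG
) -> AgentState:
    """Apply an action: clamp difficulty to [1, levels], count adaptations.

    An adaptation is any applied nonzero difficulty delta or role change; the
    per-session count never exceeds ``max_adaptations``.
    """
    new_difficulty = min(max(state.difficulty + action.difficulty_delta, 1), config.levels)
    adapted = (new_difficulty != state.difficulty) or (action.new_role != state.role)
    return AgentState(
        difficulty=new_difficulty,
        role=action.new_role,
        adaptations_this_session=min(
            state.adaptations_this_session + int(adapted), config.max_adaptations
        ),
    )


def session_forcing(
    state: AgentState, config: AgentConfig = DEFAULT_AGENT_CONFIG
) -> tuple[float, float]:
    """Map post-action agent state to the forcing pair (I, S), both in [0,1]."""
    I = (
        config.base_intensity
        + config.role_intensity_bonus * (state.role is not Role.TUTOR)
        + config.adaptation_intensity_bonus * state.adaptations_this_session
    )
    S = state.difficulty / config.levels - config.support_stress_relief * (
        state.role is Role.PEER_SUPPORTER
    )
    return min(max(I, 0.0), 1.0), min(max(S, 0.0), 1.0)
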