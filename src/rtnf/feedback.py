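"""Feedback command generation and the simulated robot.

The physical humanoid robot of the original system is replaced by an event
log and a state timeline.  The rules are those of the neurofeedback
protocol: during a task block, a correct classification raises the matching
robot arm (left for imagined left-hand movement, right for right) by a
configured angle (default 85 degrees from horizontal) and lowers it again
before the next volume; an incorrect classification leaves the robot
stationary, and during rest blocks the robot is always stationary.

Online model arbitration is block-conditional: during an LGO block the
Rest-vs-LGO model is consulted, during an RGO block the Rest-vs-RGO model —
the block identity is part of the protocol, so no arbitration scheme has to
be invented.  The LGO-vs-RGO model is evaluated offline only by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import ClassifierModel, DecisionTrace, DetrendConfig, stream_classify
from .errors import InvalidConfigError
from .paradigm import Condition, Paradigm

__all__ = [
    "Action",
    "FeedbackCommand",
    "FeedbackConfig",
    "RobotState",
    "command_for_volume",
    "run_session",
    "SessionResult",
]


class Action(str, Enum):
    RAISE_LEFT = "RAISE_LEFT"
    RAISE_RIGHT = "RAISE_RIGHT"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


# which arm answers which imagined movement
_ARM_FOR_TASK = {Condition.LGO: Action.RAISE_LEFT, Condition.RGO: Action.RAISE_RIGHT}

# which decoding model is consulted during which task block
MODEL_FOR_BLOCK = {Condition.LGO: "REST_vs_LGO", Condition.RGO: "REST_vs_RGO"}


@dataclass(frozen=True)
class FeedbackConfig:
    raise_angle_deg: float = 85.0
    feedback_enabled: bool = True     # False = non-NF run: classify, no commands
    classify_rest: bool = True        # feed rest-block volumes to the classifier


@dataclass(frozen=True)
class FeedbackCommand:
    volume: int
    action: Action
    angle_deg: float

    def __post_init__(self) -> None:
        expected = 0.0 if self.action is Action.NONE else None
        if expected is not None and self.angle_deg != expected:
            raise InvalidConfigError("NONE commands must carry angle 0")


@dataclass
class RobotState:
    """Arm angles (degrees from horizontal) at one instant."""

    volume: int
    left_deg: float = 0.0
    right_deg: float = 0.0


def command_for_volume(
    true_block: Condition,
    predicted: Condition,
    config: FeedbackConfig = FeedbackConfig(),
) -> FeedbackCommand:
    """The per-volume feedback rule.

    Task block and the prediction matches the block's task -> raise the
    matching arm at the configured angle (then lower before the next
    volume); any misclassification, any rest-block volume, or feedback
    disabled -> no command.
    """
    if (
        config.feedback_enabled
        and true_block in _ARM_FOR_TASK
        and predicted == true_block
    ):
        return FeedbackCommand(-1, _ARM_FOR_TASK[true_block], config.raise_angle_deg)
    return FeedbackCommand(-1, Action.NONE, 0.0)


@dataclass
class SessionResult:
    """Everything one streamed run produces."""

    traces: dict[str, DecisionTrace]
    commands: list[FeedbackCommand]
    timeline: list[RobotState]

    def command_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "volume": [c.volume for c in self.commands],
                "action": [str(c.action) for c in self.commands],
                "angle_deg": [c.angle_deg for c in self.commands],
            }
        )

    def n_raise(self) -> int:
        return sum(c.action is not Action.NONE for c in self.commands)

    def write(self, outdir: str | Path, prefix: str = "run") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for contrast, trace in self.traces.items():
            trace.to_tsv(outdir / f"{prefix}_desc-{contrast}_trace.tsv")
        self.command_log().to_csv(
            outdir / f"{prefix}_commands.tsv", sep="\t", index=False
        )


def run_session(
    models: dict[str, ClassifierModel],
    series: np.ndarray,
    paradigm: Paradigm,
    config: FeedbackConfig = FeedbackConfig(),
    detrend: DetrendConfig = DetrendConfig(),
) -> SessionResult:
    """Stream one preprocessed run through the decoders and the feedback rule.

    Every model classifies every volume (each with its own detrend state);
    the feedback command for a task-block volume comes from the model
    matching that block's task.  In non-feedback mode the traces are
    identical and the command log is empty of raise events.
    """
    labels = paradigm.labels
    needed = {MODEL_FOR_BLOCK[c] for c in np.unique(labels) if c in MODEL_FOR_BLOCK}
    missing = needed - set(models)
    if missing:
        raise InvalidConfigError(f"missing models for block contrasts: {sorted(missing)}")

    traces = {
        name: stream_classify(model, series, labels, detrend)
        for name, model in models.items()
    }

    commands: list[FeedbackCommand] = []
    timeline: list[RobotState] = []
    for t, cond in enumerate(labels):
        if cond in MODEL_FOR_BLOCK:
            predicted = traces[MODEL_FOR_BLOCK[cond]].predicted[t]
            cmd = command_for_volume(cond, predicted, config)
        else:
            cmd = command_for_volume(cond, Condition.REST, config)
        cmd = FeedbackCommand(t, cmd.action, cmd.angle_deg)
        commands.append(cmd)
        # instantaneous raise-and-lower within the volume interval: the arms
        # are back at horizontal (0 deg) before the next volume is acquired
        timeline.append(
            RobotState(
                volume=t,
                left_deg=cmd.angle_deg if cmd.action is Action.RAISE_LEFT else 0.0,
                right_deg=cmd.angle_deg if cmd.action is Action.RAISE_RIGHT else 0.0,
            )
        )
        timeline.append(RobotState(volume=t, left_deg=0.0, right_deg=0.0))

    for name, trace in traces.items():
        trace.command = np.array(
            [
                str(commands[t].action)
                if MODEL_FOR_BLOCK.get(labels[t]) == name
                else str(Action.NONE)
                for t in range(len(labels))
            ],
            dtype=object,
        )
    return SessionResult(traces=traces, commands=commands, timeline=timeline)
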