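"""Block-design paradigm construction and per-volume labelling.

The study protocol is a 30-s block design alternating rest and motor-imagery
task blocks (imagined left / right hand gripping-and-opening, LGO / RGO):
9 rest blocks interleaved with 8 task blocks, acquired at TR = 2 s, giving
255 volumes per run.  Every downstream stage (phantom, decoder, GLM) consumes
the per-volume condition labels defined here.

Blocks are half-open intervals [onset, onset + duration): volume *i* takes the
condition of the block containing time ``i * tr_s``, so no volume is ever
double-labelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

__all__ = [
    "Condition",
    "Block",
    "Paradigm",
    "make_paradigm",
    "labels_with_delay",
]


class Condition(str, Enum):
    """Experimental condition of a block / volume."""

    REST = "REST"
    LGO = "LGO"   # imagined left-hand gripping and opening
    RGO = "RGO"   # imagined right-hand gripping and opening

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


TASK_CONDITIONS = (Condition.LGO, Condition.RGO)


@dataclass(frozen=True)
class Block:
    """One contiguous block of a single condition.

    Parameters
    ----------
    condition : Condition
    onset_s : float
        Block onset in seconds from run start (>= 0).
    duration_s : float
        Block duration in seconds (> 0).
    """

    condition: Condition
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise InvalidConfigError(f"block onset must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise InvalidConfigError(f"block duration must be > 0, got {self.duration_s}")


@dataclass
class Paradigm:
    """An ordered block schedule plus its per-volume condition labels.

    Attributes
    ----------
    blocks : list of Block
        Contiguous, non-overlapping, onset-sorted.
    tr_s : float
        Repetition time in seconds.
    n_volumes : int
        Number of volumes; total duration must be an integer multiple of tr_s.
    labels : ndarray of Condition, shape (n_volumes,)
        labels[i] is the condition of the block containing time ``i * tr_s``
        (half-open interval convention).
    """

    blocks: list[Block]
    tr_s: float
    n_volumes: int = field(init=False)
    labels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise InvalidConfigError(f"tr_s must be > 0, got {self.tr_s}")
        if not self.blocks:
            raise InvalidConfigError("paradigm needs at least one block")
        t = 0.0
        for b in self.blocks:
            if abs(b.onset_s - t) > 1e-9:
                raise InvalidConfigError(
                    f"blocks must be contiguous: expected onset {t}, got {b.onset_s}"
                )
            t += b.duration_s
        n, rem = divmod(t, self.tr_s)
        if abs(rem) > 1e-9 and abs(rem - self.tr_s) > 1e-9:
            raise InvalidConfigError(
                f"total duration {t}s is not an integer multiple of tr_s={self.tr_s}s"
            )
        self.n_volumes = int(round(t / self.tr_s))
        labels = np.empty(self.n_volumes, dtype=object)
        for b in self.blocks:
            i0 = int(np.ceil(b.onset_s / self.tr_s - 1e-9))
            i1 = int(np.ceil((b.onset_s + b.duration_s) / self.tr_s - 1e-9))
            labels[i0:i1] = b.condition
        self.labels = labels

    # -- convenience -------------------------------------------------------

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    def condition_counts(self) -> dict[Condition, int]:
        return {c: int(np.sum(self.labels == c)) for c in Condition}

    def boxcar(self, condition: Condition) -> np.ndarray:
        """Per-volume 0/1 indicator of ``condition``."""
        return (self.labels == condition).astype(float)

    # -- serialisation (BIDS-style events TSV) -----------------------------

    def to_events(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [b.onset_s for b in self.blocks],
                "duration": [b.duration_s for b in self.blocks],
                "trial_type": [b.condition.value for b in self.blocks],
            }
        )

    def to_events_tsv(self, path: str | Path) -> None:
        self.to_events().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_events(cls, events: pd.DataFrame, tr_s: float) -> "Paradigm":
        blocks = [
            Block(Condition(row.trial_type), float(row.onset), float(row.duration))
            for row in events.itertuples()
        ]
        return cls(blocks=blocks, tr_s=tr_s)

    @classmethod
    def from_events_tsv(cls, path: str | Path, tr_s: float) -> "Paradigm":
        return cls.from_events(pd.read_csv(path, sep="\t"), tr_s)


def make_paradigm(
    n_rest: int,
    n_task: int,
    block_s: float,
    tr_s: float,
    task_order: Sequence[Condition | str],
) -> Paradigm:
    """Build an alternating REST/task/REST/.../REST block schedule.

    Parameters
    ----------
    n_rest, n_task : int
        Number of rest and task blocks; the design must satisfy
        ``n_rest == n_task + 1`` (starts and ends with rest).
    block_s : float
        Duration of every block in seconds; must divide evenly by ``tr_s``.
    tr_s : float
        Repetition time in seconds.
    task_order : sequence of Condition (LGO/RGO), length ``n_task``
        The conditions of the task blocks, in order.  The study design is
        4 LGO + 4 RGO blocks; their within-run order is configurable.

    Returns
    -------
    Paradigm
        with ``(n_rest + n_task) * block_s / tr_s`` volumes.
    """
    if n_rest != n_task + 1:
        raise InvalidConfigError(
            f"alternating design requires n_rest == n_task + 1, got {n_rest}, {n_task}"
        )
    if len(task_order) != n_task:
        raise InvalidConfigError(
            f"task_order has {len(task_order)} entries for {n_task} task blocks"
        )
    ratio = block_s / tr_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise InvalidConfigError(f"block_s={block_s} is not a multiple of tr_s={tr_s}")
    order = [Condition(c) for c in task_order]
    for c in order:
        if c is Condition.REST:
            raise InvalidConfigError("task_order may only contain LGO/RGO")
    blocks: list[Block] = []
    t = 0.0
    for i in range(n_rest + n_task):
        cond = Condition.REST if i % 2 == 0 else order[i // 2]
        blocks.append(Block(cond, t, block_s))
        t += block_s
    return Paradigm(blocks=blocks, tr_s=tr_s)


def default_paradigm(task_order: Sequence[Condition | str] | None = None) -> Paradigm:
    """The study's run design: 9 rest + 8 task blocks of 30 s at TR = 2 s.

    Default task order alternates LGO/RGO (the protocol fixes 4 + 4 blocks
    but not their order).
    """
    if task_order is None:
        task_order = [Condition.LGO, Condition.RGO] * 4
    return make_paradigm(9, 8, 30.0, 2.0, task_order)


def labels_with_delay(p: Paradigm, shift_volumes: int) -> np.ndarray:
    """Labels delayed by ``shift_volumes`` volumes (hemodynamic-lag shift).

    The first ``shift_volumes`` entries take the first block's condition.
    """
    if not (0 <= shift_volumes < p.n_volumes):
        raise InvalidConfigError(
            f"shift_volumes must be in [0, {p.n_volumes}), got {shift_volumes}"
        )
    if shift_volumes == 0:
        return p.labels.copy()
    out = np.empty_like(p.labels)
    out[:shift_volumes] = p.blocks[0].condition
    out[shift_volumes:] = p.labels[: p.n_volumes - shift_volumes]
    return out
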