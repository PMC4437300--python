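"""Freezing-behavior scoring under an auditory fear-conditioning protocol.

Conditioning (day 1): 2 min habituation, then five trials of a 20 s tone
co-terminating with a 2 s foot shock, each followed by a 1 min observation
period.  Memory tests (day 2): 5 min re-exposure to the conditioning
context, and, in a new context, three tone presentations each scored over
the 20 s tone plus 1 min observation.

Freezing is an immobility bout longer than 2 s; per epoch the score is
the summed in-epoch time of qualifying bouts as a percentage of the epoch
duration.  The >2 s criterion applies to a bout's *full* duration before
intersection with the epoch, and abutting or overlapping bouts are merged
before the criterion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Epoch",
    "ProtocolSpec",
    "FreezingSession",
    "freezing_percent",
    "session_summary",
    "conditioning_day1",
    "context_test",
    "cue_test",
]

MIN_BOUT_S = 2.0  # strictly greater than 2 s qualifies


@dataclass(frozen=True)
class Epoch:
    label: str
    start_s: float
    end_s: float
    kind: str  # habituation | tone | observation | context

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError(f"epoch {self.label}: end must exceed start")


@dataclass
class ProtocolSpec:
    """Ordered, non-overlapping epochs of one behavioral session."""

    epochs: List[Epoch]

    def __post_init__(self):
        for prev, cur in zip(self.epochs, self.epochs[1:]):
            if cur.start_s < prev.end_s - 1e-9:
                raise ValueError(f"epochs {prev.label} and {cur.label} overlap")

    def epoch(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(f"no epoch labelled {label!r}")

    @property
    def scored(self) -> List[Epoch]:
        """Epochs that enter the summary (everything except the tones)."""
        return [e for e in self.epochs if e.kind != "tone"]

    @property
    def duration_s(self) -> float:
        return self.epochs[-1].end_s


def conditioning_day1(n_trials: int = 5, habituation_s: float = 120.0,
                      tone_s: float = 20.0, observation_s: float = 60.0) -> ProtocolSpec:
    """Day-1 protocol: habituation, then tone->observation per trial.

    The scored windows are habituation (H) and the inter-trial
    observation periods (T1..Tn); the tone epochs are kept in the
    protocol but excluded from the summary, matching scoring of freezing
    "between each trial".
    """
    epochs = [Epoch("H", 0.0, habituation_s, "habituation")]
    t = habituation_s
    for i in range(1, n_trials + 1):
        epochs.append(Epoch(f"tone{i}", t, t + tone_s, "tone"))
        t += tone_s
        epochs.append(Epoch(f"T{i}", t, t + observation_s, "observation"))
        t += observation_s
    return ProtocolSpec(epochs)


def context_test(duration_s: float = 300.0) -> ProtocolSpec:
    """Day-2 context test: a single 5 min re-exposure epoch."""
    return ProtocolSpec([Epoch("context", 0.0, duration_s, "context")])


def cue_test(n_trials: int = 3, pre_s: float = 120.0, tone_s: float = 20.0,
             observation_s: float = 60.0) -> ProtocolSpec:
    """Day-2 cue test in a novel context; each trial scored over tone + 1 min."""
    epochs = [Epoch("pre", 0.0, pre_s, "habituation")]
    t = pre_s
    for i in range(1, n_trials + 1):
        epochs.append(Epoch(f"cue{i}", t, t + tone_s + observation_s, "observation"))
        t += tone_s + observation_s
    return ProtocolSpec(epochs)


def _merge_bouts(bouts: Sequence[Tuple[float, float]]) -> List[Tuple[float, float]]:
    merged: List[List[float]] = []
    for s, e in sorted(bouts):
        if e <= s:
            raise ValueError(f"bout ({s}, {e}) has non-positive duration")
        if merged and s <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


@dataclass
class FreezingSession:
    """Protocol plus annotated immobility bouts (start, end in seconds)."""

    protocol: ProtocolSpec
    bouts: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.bouts = _merge_bouts(self.bouts)
        end = self.protocol.duration_s
        for s, e in self.bouts:
            if s < -1e-9 or e > end + 1e-9:
                raise ValueError(f"bout ({s}, {e}) outside the session")


def freezing_percent(session: FreezingSession, epoch_label: str) -> float:
    """Percent of an epoch spent in qualifying (> 2 s) freezing bouts."""
    epoch = session.protocol.epoch(epoch_label)
    length = epoch.end_s - epoch.start_s
    if length <= 0:
        raise ValueError(f"epoch {epoch_label} has zero length")
    frozen = 0.0
    for s, e in session.bouts:
        if e - s <= MIN_BOUT_S:  # full bout duration, before intersection
            continue
        frozen += max(0.0, min(e, epoch.end_s) - max(s, epoch.start_s))
    return 100.0 * frozen / length


def session_summary(session: FreezingSession) -> pd.DataFrame:
    """Freezing percentage per scored epoch, in protocol order."""
    rows = [
        {"epoch": e.label, "kind": e.kind,
         "freezing_percent": freezing_percent(session, e.label)}
        for e in session.protocol.scored
    ]
    return pd.DataFrame(rows)
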