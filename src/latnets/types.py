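"""Core domain containers shared across the pipeline.

The pipeline operates on trial-segmented multichannel recordings from a
three-period task (Waiting → Context → Response).  Each trial carries a
scenario label (context × response) and, after gaze screening, a perception
condition (C+ / C−).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

CONTEXTS = ("Ch", "Cm", "Cw")
RESPONSES = ("Rf", "Rn")
CONDITIONS = ("Cplus", "Cminus")

#: The six scenario trial types in canonical order.
TRIAL_TYPES = tuple(f"{c}{r}" for c in CONTEXTS for r in RESPONSES)


@dataclass(frozen=True)
class ScenarioLabel:
    """Per-trial scenario: context ∈ {Ch, Cm, Cw}, response ∈ {Rf, Rn},
    condition ∈ {Cplus, Cminus} (None until gaze screening has run)."""

    context: str
    response: str
    condition: Optional[str] = None

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def trial_type(self) -> str:
        return f"{self.context}{self.response}"

    def with_condition(self, condition: str) -> "ScenarioLabel":
        return replace(self, condition=condition)


@dataclass(frozen=True)
class TaskTimeline:
    """Task periods in seconds, trial-relative.

    waiting, context, response are period durations; the baseline interval
    (used for causality normalization) must lie inside the Waiting period.
    """

    waiting: float = 2.5
    context: float = 1.5
    response: float = 3.0
    baseline: tuple[float, float] = (0.25, 2.25)

    def __post_init__(self):
        if min(self.waiting, self.context, self.response) <= 0:
            raise ValueError("period durations must be positive")
        b0, b1 = self.baseline
        if not (0 <= b0 < b1 <= self.waiting):
            raise ValueError("baseline interval must lie within the Waiting period")

    @property
    def context_start(self) -> float:
        return self.waiting

    @property
    def response_start(self) -> float:
        return self.waiting + self.context

    @property
    def response_end(self) -> float:
        return self.waiting + self.context + self.response


@dataclass
class TrialRecording:
    """Trial-segmented multichannel recording.

    data : (n_trials, n_channels, n_samples), arbitrary signal units
    gaze : optional (n_trials, n_gaze_samples, 2) eye-position traces in
           degrees, sampled at ``gaze_fs``; NaN marks eyes-closed samples.
    """

    data: np.ndarray
    fs: float
    labels: list[ScenarioLabel]
    timeline: TaskTimeline = field(default_factory=TaskTimeline)
    gaze: Optional[np.ndarray] = None
    gaze_fs: float = 30.0
    subject: str = "S1"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.n_trials:
            raise ValueError("labels length must equal trial count")
        if self.gaze is not None and self.gaze.shape[0] != self.n_trials:
            raise ValueError("gaze trial count mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def trial_types(self) -> list[str]:
        return [lab.trial_type for lab in self.labels]

    def subset(self, indices: Sequence[int]) -> "TrialRecording":
        idx = np.asarray(indices, dtype=int)
        return TrialRecording(
            data=self.data[idx],
            fs=self.fs,
            labels=[self.labels[i] for i in idx],
            timeline=self.timeline,
            gaze=None if self.gaze is None else self.gaze[idx],
            gaze_fs=self.gaze_fs,
            subject=self.subject,
        )

    def with_data(self, data: np.ndarray, fs: Optional[float] = None) -> "TrialRecording":
        return TrialRecording(
            data=data,
            fs=self.fs if fs is None else fs,
            labels=list(self.labels),
            timeline=self.timeline,
            gaze=self.gaze,
            gaze_fs=self.gaze_fs,
            subject=self.subject,
        )
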