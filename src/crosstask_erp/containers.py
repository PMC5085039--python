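"""In-memory containers shared by the simulation and analysis modules.

All voltages are in microvolts (uV) at every interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import StimulusEvent
from .montage import EOG_CHANNEL, MASTOIDS


@dataclass
class ContinuousRecording:
    """Continuous multichannel voltage trace with embedded event markers.

    ``data`` is channels x samples in uV.  ``reference`` documents the
    current referencing scheme ("left-mastoid" as recorded,
    "linked-mastoids" after re-referencing).
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    events: list[StimulusEvent]
    participant: str = ""
    condition: str = ""
    reference: str = "left-mastoid"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples matching channel_names")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.data.shape[1]
        for ev in self.events:
            s = ev.onset_ms * self.sampling_rate / 1000.0
            if not (0 <= s < n):
                raise ValueError(f"event onset {ev.onset_ms} ms outside recording bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def scalp_channels(self) -> list[str]:
        """EEG channels entering analysis: everything except mastoids and EOG."""
        excluded = set(MASTOIDS) | {EOG_CHANNEL}
        return [c for c in self.channel_names if c not in excluded]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def get_channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def onset_sample(self, event: StimulusEvent) -> int:
        s = event.onset_ms * self.sampling_rate / 1000.0
        si = int(round(s))
        if abs(s - si) > 1e-9:
            raise ValueError(
                f"event onset {event.onset_ms} ms is not an integer sample at "
                f"{self.sampling_rate} Hz"
            )
        return si

    def copy(self) -> "ContinuousRecording":
        return replace(self, data=self.data.copy(), events=list(self.events),
                       channel_names=list(self.channel_names))


@dataclass
class EpochSet:
    """Stimulus-locked epochs: epochs x channels x time, with labels.

    ``times_ms[j]`` is the offset of sample j relative to stimulus onset;
    the default window is the half-open interval [-100, +900) ms.
    ``labels`` are 1 for targets, 0 for distractors.  ``kept`` is the
    artifact mask (True = kept); the data themselves are never altered by
    rejection.
    """

    data: np.ndarray
    times_ms: np.ndarray
    labels: np.ndarray
    channel_names: list[str]
    events: list[StimulusEvent]
    participant: str = ""
    condition: str = ""
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x time")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis does not match times_ms")
        if self.data.shape[0] != self.labels.size:
            raise ValueError("labels do not match epoch count")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0 (distractor) or 1 (target)")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times_ms must be strictly increasing")
        if self.kept is None:
            self.kept = np.ones(self.data.shape[0], dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def scalp_channels(self) -> list[str]:
        excluded = set(MASTOIDS) | {EOG_CHANNEL}
        return [c for c in self.channel_names if c not in excluded]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None

    def time_mask(self, tmin_ms: float, tmax_ms: float, *, closed: bool = False) -> np.ndarray:
        """Boolean mask over the time axis for [tmin, tmax) or [tmin, tmax]."""
        if closed:
            return (self.times_ms >= tmin_ms) & (self.times_ms <= tmax_ms)
        return (self.times_ms >= tmin_ms) & (self.times_ms < tmax_ms)

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset epochs by a boolean or index mask (copy)."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return EpochSet(
            data=self.data[idx].copy(),
            times_ms=self.times_ms.copy(),
            labels=self.labels[idx],
            channel_names=list(self.channel_names),
            events=[self.events[i] for i in idx],
            participant=self.participant,
            condition=self.condition,
            kept=self.kept[idx].copy(),
            sampling_rate=self.sampling_rate,
        )

    def kept_only(self) -> "EpochSet":
        return self.select(self.kept)


@dataclass
class FeatureMatrix:
    """Epochs x spatio-temporal features, ready for classification.

    ``feature_index`` maps each column to its (channel name, time point in
    ms); columns are channel-major.  ``epoch_index[i]`` is the row's epoch
    position in the source :class:`EpochSet`.
    """

    X: np.ndarray
    y: np.ndarray
    feature_index: list[tuple[str, float]]
    epoch_index: np.ndarray
    participant: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.size:
            raise ValueError("row count does not match labels")
        if self.X.shape[1] != len(self.feature_index):
            raise ValueError("feature_index does not match column count")
        self.epoch_index = np.asarray(self.epoch_index, dtype=int)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]
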