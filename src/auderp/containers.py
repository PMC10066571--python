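"""In-memory containers shared by every pipeline stage.

Voltages are stored in microvolts as float64 throughout.  Epochs span an
inclusive window [tmin, tmax] so the time axis has
``round((tmax - tmin) * srate) + 1`` samples and t = 0 is an exact sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class EventSchedule:
    """Ordered stimulus events.

    ``onsets`` are seconds from recording start and strictly increasing;
    ``labels`` are condition codes ("SON"/"OFN" for the own-name paradigm,
    "RW1","RW2","UW1","UW2","PW1","PW2" — category plus word position —
    for the priming paradigm).  ``metadata`` holds per-event arrays
    (voice index, name index, pair id, ...) keyed by name.
    """

    onsets: np.ndarray
    labels: list[str]
    block_index: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.block_index = np.asarray(self.block_index, dtype=int)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be 1-D")
        if len(self.labels) != self.onsets.size or self.block_index.size != self.onsets.size:
            raise ValueError("onsets, labels and block_index must have equal length")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onsets.size)

    def select(self, labels: set[str] | list[str]) -> "EventSchedule":
        labels = set(labels)
        keep = np.array([lb in labels for lb in self.labels], dtype=bool)
        meta = {k: np.asarray(v)[keep] for k, v in self.metadata.items()
                if np.ndim(v) == 1 and len(v) == len(self)}
        return EventSchedule(self.onsets[keep],
                             [lb for lb, k in zip(self.labels, keep) if k],
                             self.block_index[keep], meta)

    @property
    def duration_hint(self) -> float:
        """Time of the last onset (schedule length excludes stimulus tails)."""
        return float(self.onsets[-1]) if len(self) else 0.0


@dataclass
class Recording:
    """Continuous multi-channel recording with an event schedule.

    ``data`` is channels x samples in microvolts; rows follow
    ``layout.channel_names``.  ``non_scalp`` lists derived channels (the
    virtual EOG) excluded from the scalp average and statistics.
    """

    data: np.ndarray
    srate: float
    layout: "Any"
    events: EventSchedule
    non_scalp: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data row count must equal layout channel count")
        if len(self.events) and self.events.onsets[-1] >= self.duration:
            raise ValueError("event onsets must lie within [0, duration)")
        if len(self.events) and self.events.onsets[0] < 0:
            raise ValueError("event onsets must be nonnegative")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.srate

    @property
    def scalp_names(self) -> list[str]:
        return [n for n in self.layout.channel_names if n not in self.non_scalp]

    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.layout.channel_names)
                         if n not in self.non_scalp], dtype=int)

    def copy_with(self, data: np.ndarray, **prov: Any) -> "Recording":
        p = dict(self.provenance)
        p.update(prov)
        return Recording(data, self.srate, self.layout, self.events,
                         list(self.non_scalp), p)


def n_epoch_samples(tmin: float, tmax: float, srate: float) -> int:
    """Length of the inclusive epoch window [tmin, tmax] at ``srate``."""
    return int(round((tmax - tmin) * srate)) + 1


@dataclass
class EpochSet:
    """Trials x channels x time epochs with condition labels."""

    data: np.ndarray
    tmin: float
    tmax: float
    srate: float
    labels: list[str]
    layout: "Any"
    subject_id: str = ""
    rejected_mask: np.ndarray | None = None
    non_scalp: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        nt = n_epoch_samples(self.tmin, self.tmax, self.srate)
        if self.data.shape[2] != nt:
            raise ValueError(
                f"time axis has {self.data.shape[2]} samples, expected {nt} "
                f"for [{self.tmin}, {self.tmax}] s at {self.srate} Hz")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError("channel axis must match layout")
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.data.shape[0], dtype=bool)
        else:
            self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)
            if self.rejected_mask.shape != (self.data.shape[0],):
                raise ValueError("rejected_mask must be per-trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.srate

    def retained(self, label: str | None = None) -> np.ndarray:
        keep = ~self.rejected_mask
        if label is not None:
            keep = keep & np.array([lb == label for lb in self.labels])
        return np.flatnonzero(keep)

    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.layout.channel_names)
                         if n not in self.non_scalp], dtype=int)


@dataclass
class Erp:
    """Per-condition channels x time average."""

    data: np.ndarray
    tmin: float
    srate: float
    n_trials: int
    condition: str
    layout: "Any"
    subject_id: str = ""
    non_scalp: list[str] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x time")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[1]) / self.srate

    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.layout.channel_names)
                         if n not in self.non_scalp], dtype=int)


@dataclass
class GfpTrace:
    """Global field power: one nonnegative scalar per time sample."""

    values: np.ndarray
    tmin: float
    srate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("GFP values must be nonnegative")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.values.size) / self.srate
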