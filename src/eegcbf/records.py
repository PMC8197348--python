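"""Core in-memory containers for EEG and carotid-blood-flow signals.

All voltages are in microvolts (µV), flows in mL/min, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecord", "CBFTrace", "SubEpoch"]


@dataclass
class EEGRecord:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples : array of float
        Voltage samples in µV.
    fs : float
        Sampling rate in Hz (must be positive).
    t0 : float
        Time of the first sample, seconds.
    annotations : list of (label, start_s, end_s)
        Interval annotations; every interval must lie within the record span.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("EEGRecord samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("EEGRecord samples must be finite")
        end = self.t0 + self.duration
        for label, start, stop in self.annotations:
            # small tolerance for float round-off at the record edge
            if start < self.t0 - 1e-9 or stop > end + 1e-9 or stop < start:
                raise ValueError(
                    f"annotation {label!r} [{start}, {stop}] outside record "
                    f"span [{self.t0}, {end}]"
                )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice(self, start: float, stop: float) -> "EEGRecord":
        """Return the sub-record covering [start, stop) seconds."""
        i0 = int(round((start - self.t0) * self.fs))
        i1 = int(round((stop - self.t0) * self.fs))
        if i0 < 0 or i1 > self.samples.size or i1 <= i0:
            raise ValueError(f"slice [{start}, {stop}] outside record span")
        return EEGRecord(self.samples[i0:i1].copy(), self.fs, t0=start)


@dataclass
class CBFTrace:
    """Carotid blood flow trace (mL/min) with its pre-arrest baseline value."""

    samples: np.ndarray
    fs: float
    baseline_value: float = float("nan")
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def mean_flow(self, start: float, stop: float) -> float:
        """Mean flow over [start, stop) seconds."""
        i0 = int(round((start - self.t0) * self.fs))
        i1 = int(round((stop - self.t0) * self.fs))
        if i0 < 0 or i1 > self.samples.size or i1 <= i0:
            raise ValueError(f"window [{start}, {stop}] outside trace span")
        return float(np.mean(self.samples[i0:i1]))


@dataclass
class SubEpoch:
    """A 2-s analysis window cut from a pre-shock pause.

    ``source`` identifies the window as (animal_id, pause_index, offset_s)
    where offset_s is the window start relative to the pause start
    (0.0, 0.5 or 1.0 for the three overlapping sub-epochs).
    """

    samples: np.ndarray
    fs: float
    source: tuple[str, int, float] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        expected = int(round(2.0 * self.fs))
        if self.samples.size != expected:
            raise ValueError(
                f"sub-epoch must hold exactly 2 s of samples "
                f"({expected} at {self.fs} Hz), got {self.samples.size}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)
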