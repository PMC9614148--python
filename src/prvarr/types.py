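"""Core containers shared across the pipeline.

The pipeline moves through three representations: a raw or filtered
pressure waveform (:class:`ABPRecord`), the detected systolic peaks
(:class:`BeatSeries`), and the windowed beat-to-beat series on which
features are computed (:class:`PRVSegment`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Hard physiological ceiling on instantaneous pulse rate (beats per minute).
#: No two detected peaks may be closer than 60/MAX_RATE_BPM seconds.
MAX_RATE_BPM = 300.0


@dataclass
class ABPRecord:
    """A single-channel arterial blood pressure waveform.

    Parameters
    ----------
    samples : ndarray
        Pressure values (arbitrary units, typically mmHg).
    fs : float
        Sampling rate in Hz.
    annotations : ndarray, optional
        Ground-truth systolic peak positions (sample indices), when known
        (synthetic records and manually annotated data).
    transient_samples : int
        Leading span of ``samples`` dominated by the start-up transient of
        causal zero-state filtering; beat detection ignores this span.
    meta : dict
        Free-form provenance (record id, rhythm class, generator truth, ...).
    """

    samples: np.ndarray
    fs: float
    annotations: np.ndarray | None = None
    transient_samples: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations, dtype=np.int64)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return np.arange(self.samples.size) / self.fs


@dataclass
class BeatSeries:
    """Detected systolic peaks: sample positions and amplitudes (APM)."""

    peak_index: np.ndarray
    peak_amplitude: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_index = np.asarray(self.peak_index, dtype=np.int64)
        self.peak_amplitude = np.asarray(self.peak_amplitude, dtype=float)
        if self.peak_index.shape != self.peak_amplitude.shape:
            raise ValueError("peak_index and peak_amplitude must align")
        if self.peak_index.size >= 2:
            gaps = np.diff(self.peak_index)
            if np.any(gaps <= 0):
                raise ValueError("peak indices must be strictly increasing")
            min_gap = self.fs * 60.0 / MAX_RATE_BPM
            if np.any(gaps < min_gap - 1e-9):
                raise ValueError(
                    f"peak spacing below {min_gap:.1f} samples implies a rate "
                    f"above {MAX_RATE_BPM:.0f} bpm"
                )

    def __len__(self) -> int:
        return int(self.peak_index.size)


@dataclass
class PRVSegment:
    """A run of beats carrying the three per-beat series.

    ``prv`` is the instantaneous pulse rate in bpm, ``ppi`` the
    pulse-to-pulse interval in ms and ``apm`` the pulse amplitude at the
    leading peak of each interval; ``prv[i] * ppi[i] == 60000`` by
    construction.
    """

    prv: np.ndarray
    ppi: np.ndarray
    apm: np.ndarray
    label: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.prv = np.asarray(self.prv, dtype=float)
        self.ppi = np.asarray(self.ppi, dtype=float)
        self.apm = np.asarray(self.apm, dtype=float)
        if not (len(self.prv) == len(self.ppi) == len(self.apm)):
            raise ValueError("prv, ppi and apm must have equal length")
        if np.any(self.prv <= 0) or np.any(self.prv > MAX_RATE_BPM + 1e-9):
            raise ValueError(f"prv values must lie in (0, {MAX_RATE_BPM:.0f}] bpm")

    def __len__(self) -> int:
        return int(self.prv.size)


@dataclass
class ConfusionMatrix:
    """Class-by-class count table; ``counts[t, u]`` = true ``t`` predicted ``u``."""

    counts: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())
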