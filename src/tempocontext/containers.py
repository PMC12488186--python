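"""In-memory containers shared across analysis stages.

Angles are degrees in [0, 360), measured counterclockwise from the rightward
horizontal, with fixation at the origin. Times are seconds relative to
stimulus onset.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SensorEpochs:
    """Epoched multi-sensor recordings.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_sensors, n_times)
        Sensor amplitudes (arbitrary units).
    times : ndarray, shape (n_times,)
        Sample times in seconds relative to stimulus onset, strictly
        increasing.
    rate : float
        Sampling rate in Hz.
    angles : ndarray, shape (n_trials,)
        Per-trial stimulus angle in degrees, [0, 360).
    sensors : ndarray of str
        Sensor identifiers.
    labels : pandas.DataFrame or None
        Optional per-trial context labels, aligned to ``data``.
    """

    data: np.ndarray
    times: np.ndarray
    rate: float
    angles: np.ndarray
    sensors: np.ndarray = field(default=None)
    labels: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_sensors, n_times)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("data/time axis mismatch")
        if self.data.shape[0] != self.angles.size:
            raise ValueError("one angle per trial required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sensors is None:
            self.sensors = np.array([f"S{i:02d}" for i in range(self.data.shape[1])])
        if self.labels is not None and len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must align with trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]


@dataclass
class PupilEpochs:
    """Preprocessed pupil epochs (z-units, baselined, downsampled).

    ``data`` holds one row per retained event; ``rejected`` flags events whose
    epoch exceeded the masked-sample budget and were dropped from ``data``.
    """

    data: np.ndarray            # (n_epochs, n_samples)
    times: np.ndarray           # (n_samples,) seconds relative to event
    rate: float                 # Hz, after downsampling
    event_index: np.ndarray     # indices into the original event list
    rejected: np.ndarray        # boolean, per original event
    labels: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape[1] != self.times.size:
            raise ValueError("data/time axis mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]
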