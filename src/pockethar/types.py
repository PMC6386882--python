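"""Core domain types: sensors, activities, readings, traces, recordings.

A recording is what one 10-second (or longer) data-collection stint
produces: one timestamped tri-axial trace per sensor, plus an optional
activity label. Traces store their readings as numpy arrays (``n`` int64
timestamps in milliseconds and an ``(n, 3)`` float64 block of X/Y/Z
values) so that windowing and feature extraction stay vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional

import numpy as np

from pockethar.errors import CompletenessError, FormatError


class Sensor(str, Enum):
    """The three smartphone sensors the pipeline consumes."""

    ACCELEROMETER = "accelerometer"
    GYROSCOPE = "gyroscope"
    GRAVITY = "gravity"


#: Canonical sensor order used everywhere (feature layout, windows, files).
SENSORS: tuple[Sensor, ...] = (Sensor.ACCELEROMETER, Sensor.GYROSCOPE, Sensor.GRAVITY)


class Activity(str, Enum):
    """The six-activity label set."""

    WALKING = "walking"
    RUNNING = "running"
    SITTING = "sitting"
    STANDING = "standing"
    UPSTAIRS = "upstairs"
    DOWNSTAIRS = "downstairs"


#: Canonical activity order: rows/columns of confusion matrices, class
#: order of the perceptron output layer, and argmax tie-break priority.
ACTIVITIES: tuple[Activity, ...] = tuple(Activity)

#: Axis names in storage order.
AXES: tuple[str, str, str] = ("x", "y", "z")


@dataclass(frozen=True)
class SensorReading:
    """One timestamped tri-axial reading from a single sensor.

    ``timestamp_ms`` counts milliseconds since the start of the recording.
    Units are m/s^2 for accelerometer and gravity, rad/s for gyroscope.
    """

    timestamp_ms: int
    sensor: Sensor
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.timestamp_ms < 0:
            raise FormatError(f"negative timestamp {self.timestamp_ms}")
        if not all(np.isfinite(v) for v in (self.x, self.y, self.z)):
            raise FormatError("non-finite axis value in reading")


@dataclass
class SensorTrace:
    """All readings from one sensor over one recording, in time order."""

    sensor: Sensor
    timestamps_ms: np.ndarray  # (n,) int64, nondecreasing
    values: np.ndarray  # (n, 3) float64, columns X/Y/Z

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise FormatError(
                f"trace values must be (n, 3), got {self.values.shape}"
            )
        if self.timestamps_ms.shape[0] != self.values.shape[0]:
            raise FormatError("timestamp/value length mismatch in trace")
        self.validate()

    def validate(self) -> None:
        if len(self) and self.timestamps_ms[0] < 0:
            raise FormatError("negative timestamp in trace")
        if np.any(np.diff(self.timestamps_ms) < 0):
            bad = int(np.argmax(np.diff(self.timestamps_ms) < 0)) + 1
            raise FormatError(
                f"timestamps not nondecreasing for sensor "
                f"'{self.sensor.value}' at reading index {bad}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"non-finite value in '{self.sensor.value}' trace")

    def __len__(self) -> int:
        return int(self.timestamps_ms.shape[0])

    def readings(self) -> Iterator[SensorReading]:
        for t, (x, y, z) in zip(self.timestamps_ms, self.values):
            yield SensorReading(int(t), self.sensor, float(x), float(y), float(z))


@dataclass
class LabeledRecording:
    """One data-collection stint: one trace per required sensor.

    ``duration_ms`` is the nominal length of the stint; readings beyond it
    are permitted in memory but fall outside every window during
    segmentation. ``metadata`` carries free-form ``key=value`` annotations
    (simulation parameters, seeds) that round-trip through the CSV writer.
    """

    traces: Mapping[Sensor, SensorTrace]
    label: Optional[Activity] = None
    duration_ms: int = 0
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s.value for s in SENSORS if s not in self.traces]
        if missing:
            raise CompletenessError(
                f"recording is missing required sensor(s): {', '.join(missing)}"
            )
        for sensor, trace in self.traces.items():
            if trace.sensor is not sensor:
                raise FormatError(
                    f"trace filed under '{sensor.value}' holds "
                    f"'{trace.sensor.value}' readings"
                )
        if self.duration_ms <= 0:
            self.duration_ms = int(
                max((t.timestamps_ms[-1] for t in self.traces.values() if len(t)),
                    default=0)
            ) + 1

    def n_readings(self) -> dict[Sensor, int]:
        return {s: len(t) for s, t in self.traces.items()}
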