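"""Segmentation of recordings into fixed-length harmonized windows.

Smartphone sensors are event-driven: each sensor reports at its own
irregular cadence, so a 10-second stint yields a different number of
readings per sensor. Windowing makes every classification instance the
same shape by cutting the recording into consecutive, non-overlapping
10-second windows and keeping only the first ``readings_per_axis``
readings (by timestamp) of each sensor in each window — with defaults,
3 sensors x 3 axes x 100 readings = 900 scalars per window. Windows in
which any sensor delivered fewer readings than required are dropped and
counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from pockethar.errors import ConfigError
from pockethar.types import Activity, LabeledRecording, Sensor, SENSORS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowingConfig:
    """Window length, harmonized reading count, and sampling hint.

    ``stride_ms`` defaults to the window length (non-overlapping,
    disjoint stints); set it smaller for sliding windows.
    """

    window_ms: int = 10_000
    readings_per_axis: int = 100
    nominal_interval_ms: int = 50
    stride_ms: Optional[int] = None

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ConfigError("window_ms must be positive")
        if self.readings_per_axis < 2:
            raise ConfigError("readings_per_axis must be at least 2")
        if self.nominal_interval_ms <= 0:
            raise ConfigError("nominal_interval_ms must be positive")
        if self.stride_ms is not None and self.stride_ms <= 0:
            raise ConfigError("stride_ms must be positive when given")

    @property
    def effective_stride_ms(self) -> int:
        return self.window_ms if self.stride_ms is None else self.stride_ms


@dataclass
class SensorWindow:
    """One harmonized window: ``data[sensor, axis, i]``.

    ``data`` has shape (3, 3, N) in canonical sensor order
    (accelerometer, gyroscope, gravity) and axis order (X, Y, Z).
    """

    data: np.ndarray
    label: Optional[Activity] = None
    source_offset_ms: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[:2] != (3, 3):
            raise ConfigError(
                f"window data must have shape (3, 3, N), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("non-finite value in window")

    @property
    def n_readings_per_axis(self) -> int:
        return int(self.data.shape[2])

    @property
    def n_scalars(self) -> int:
        return int(self.data.size)

    def sensor_block(self, sensor: Sensor) -> np.ndarray:
        """The (3, N) axis block for one sensor."""
        return self.data[SENSORS.index(sensor)]


def segment(
    recording: LabeledRecording, config: WindowingConfig = WindowingConfig()
) -> list[SensorWindow]:
    """Cut a recording into harmonized windows.

    Window k covers timestamps in ``[k*stride, k*stride + window_ms)``.
    Within each window, each sensor's readings are taken in timestamp
    order (file/input order breaks ties) and truncated to the first
    ``readings_per_axis``; under-full windows are dropped and the count
    logged. A recording shorter than one window yields an empty list.
    """
    n = config.readings_per_axis
    stride = config.effective_stride_ms
    n_windows = 0
    if recording.duration_ms >= config.window_ms:
        n_windows = (recording.duration_ms - config.window_ms) // stride + 1

    windows: list[SensorWindow] = []
    dropped = 0
    for k in range(n_windows):
        start = k * stride
        end = start + config.window_ms
        blocks = np.empty((3, 3, n), dtype=np.float64)
        full = True
        for si, sensor in enumerate(SENSORS):
            trace = recording.traces[sensor]
            # timestamps are nondecreasing, so the window is a contiguous
            # slice and slicing preserves input order within ties
            lo = int(np.searchsorted(trace.timestamps_ms, start, side="left"))
            hi = int(np.searchsorted(trace.timestamps_ms, end, side="left"))
            if hi - lo < n:
                full = False
                break
            blocks[si] = trace.values[lo:lo + n].T
        if not full:
            dropped += 1
            continue
        windows.append(
            SensorWindow(data=blocks, label=recording.label, source_offset_ms=start)
        )
    if dropped:
        logger.info(
            "segment: dropped %d under-full window(s) of %d", dropped, n_windows
        )
    return windows
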