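"""The 120-dimensional hand-crafted feature vector of a sensor window.

Five feature families summarize each harmonized window:

* **average** — per-axis arithmetic mean, (1/N) * sum(x_i). 9 values.
* **avg_abs_diff** — per-axis mean absolute deviation from the axis
  mean, (1/N) * sum(|x_i - mu|). 9 values.
* **std_dev** — per-axis population standard deviation,
  sqrt((1/N) * sum((x_i - mu)^2)). 9 values.
* **avg_resultant** — per-sensor mean Euclidean norm of the (x, y, z)
  triples, (1/N) * sum(sqrt(x_i^2 + y_i^2 + z_i^2)); rotation-invariant
  signal-energy summary. 3 values.
* **histogram** — per-axis binned distribution: the window's own
  min..max range is split into ``num_bins`` equal-width intervals and
  each slot holds the fraction of readings falling in that interval.
  9 axes x 10 bins = 90 values.

Total 9 + 9 + 9 + 3 + 90 = 120. All statistics use population (1/N)
normalization. The canonical slot order is family-major, within each
family sensor-major (accelerometer, gyroscope, gravity), within each
sensor axis order X, Y, Z, histogram bins ascending; feature files and
trained models both depend on this fixed layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from pockethar.errors import ConfigError, DimensionError
from pockethar.types import Activity, AXES, SENSORS
from pockethar.windowing import SensorWindow

FAMILIES = ("average", "avg_abs_diff", "std_dev", "avg_resultant", "histogram")


@dataclass(frozen=True)
class FeatureExtractionConfig:
    """Histogram bin count; the rest of the layout is fixed."""

    num_bins: int = 10

    def __post_init__(self) -> None:
        if self.num_bins < 1:
            raise ConfigError("num_bins must be at least 1")

    @property
    def n_features(self) -> int:
        return 9 + 9 + 9 + 3 + 9 * self.num_bins


@dataclass
class FeatureVector:
    """Ordered feature values with a provenance tag per slot.

    Each tag is ``(sensor, axis, family, bin_index)``; ``axis`` is None
    for the per-sensor resultant family and ``bin_index`` is None outside
    the histogram family.
    """

    values: np.ndarray
    provenance: tuple[tuple[str, Optional[str], str, Optional[int]], ...]
    label: Optional[Activity] = None

    def __len__(self) -> int:
        return int(self.values.shape[0])


def _check_axis(axis: np.ndarray) -> np.ndarray:
    arr = np.asarray(axis, dtype=np.float64)
    if arr.ndim != 1 or arr.shape[0] < 1:
        raise DimensionError("axis must be a nonempty 1-D array")
    return arr


def average(axis: np.ndarray) -> float:
    """Arithmetic mean of one axis."""
    return float(np.mean(_check_axis(axis)))


def avg_abs_diff(axis: np.ndarray) -> float:
    """Mean absolute deviation from the axis mean."""
    arr = _check_axis(axis)
    return float(np.mean(np.abs(arr - arr.mean())))


def std_dev(axis: np.ndarray) -> float:
    """Population standard deviation (1/N normalization)."""
    return float(np.std(_check_axis(axis)))


def avg_resultant(triples: np.ndarray) -> float:
    """Mean Euclidean norm of (x, y, z) triples; one value per sensor.

    Input is strictly (N, 3), one row per reading.
    """
    arr = np.asarray(triples, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise DimensionError(f"expected (N, 3) triples, got {arr.shape}")
    return float(np.mean(np.linalg.norm(arr, axis=1)))


def histogram(axis: np.ndarray, num_bins: int = 10) -> np.ndarray:
    """Binned distribution of one axis over its own min..max range.

    The range is split into ``num_bins`` equal-width intervals, half-open
    ``[lo, hi)`` except the last, which is closed. Returns fractions
    summing to 1. Degenerate range (max == min): every reading sits on
    the inclusive lower edge of bin 0, so bin 0 receives all the mass.
    """
    arr = _check_axis(axis)
    if num_bins < 1:
        raise ConfigError("num_bins must be at least 1")
    lo = arr.min()
    hi = arr.max()
    fractions = np.zeros(num_bins, dtype=np.float64)
    if lo == hi:
        fractions[0] = 1.0
        return fractions
    edges = lo + np.arange(num_bins + 1) * ((hi - lo) / num_bins)
    edges[-1] = hi
    idx = np.searchsorted(edges, arr, side="right") - 1
    np.clip(idx, 0, num_bins - 1, out=idx)  # fold x == hi into the last bin
    np.add.at(fractions, idx, 1.0)
    return fractions / arr.shape[0]


def feature_provenance(
    config: FeatureExtractionConfig = FeatureExtractionConfig(),
) -> tuple[tuple[str, Optional[str], str, Optional[int]], ...]:
    """The (sensor, axis, family, bin) tag of every slot, in order."""
    tags: list[tuple[str, Optional[str], str, Optional[int]]] = []
    for family in ("average", "avg_abs_diff", "std_dev"):
        for sensor in SENSORS:
            for ax in AXES:
                tags.append((sensor.value, ax, family, None))
    for sensor in SENSORS:
        tags.append((sensor.value, None, "avg_resultant", None))
    for sensor in SENSORS:
        for ax in AXES:
            for b in range(config.num_bins):
                tags.append((sensor.value, ax, "histogram", b))
    return tuple(tags)


def extract_features(
    window: SensorWindow,
    config: FeatureExtractionConfig = FeatureExtractionConfig(),
) -> FeatureVector:
    """Compute the full feature vector of one harmonized window."""
    values: list[float] = []
    for family_fn in (average, avg_abs_diff, std_dev):
        for si in range(3):
            for ai in range(3):
                values.append(family_fn(window.data[si, ai]))
    for si in range(3):
        values.append(avg_resultant(window.data[si].T))
    for si in range(3):
        for ai in range(3):
            values.extend(histogram(window.data[si, ai], config.num_bins))
    vec = np.array(values, dtype=np.float64)
    if vec.shape[0] != config.n_features:
        raise DimensionError(
            f"feature vector has {vec.shape[0]} slots, expected {config.n_features}"
        )
    return FeatureVector(
        values=vec, provenance=feature_provenance(config), label=window.label
    )
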