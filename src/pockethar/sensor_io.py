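"""Text-format readers and writers.

Three stable, human-inspectable formats:

* **Sensor log CSV** — optional ``# key=value`` metadata comment lines,
  a ``timestamp_ms,sensor,x,y,z`` header, then one reading per row.
  Rows may interleave sensors, but each sensor's timestamps must be
  nondecreasing in file order. The writer emits rows merged across
  sensors by (timestamp, sensor) so that read/write round-trips are
  byte-identical.
* **Feature file** — one window per line: 120 comma-separated decimal
  values in the canonical feature order, then the activity label token.
* **Model JSON** — one document holding layer dimensions, weights,
  biases, feature-normalization statistics, the label order and the
  training configuration.

Reals are serialized with 12 significant digits, which makes
parse-then-format idempotent for everything this package writes.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np

from pockethar.errors import CompletenessError, DimensionError, FormatError
from pockethar.types import (
    ACTIVITIES,
    Activity,
    LabeledRecording,
    Sensor,
    SENSORS,
    SensorTrace,
)

HEADER = "timestamp_ms,sensor,x,y,z"

_SENSOR_BY_TOKEN = {s.value: s for s in Sensor}
_ACTIVITY_BY_TOKEN = {a.value: a for a in Activity}


def _fmt(v: float) -> str:
    return format(float(v), ".12g")


# ---------------------------------------------------------------------------
# sensor logs
# ---------------------------------------------------------------------------

def read_sensor_log(path: str | os.PathLike) -> LabeledRecording:
    """Parse a sensor-log CSV into a :class:`LabeledRecording`.

    Raises :class:`FormatError` naming the offending line for malformed
    rows, unknown sensor tokens, or per-sensor timestamp regressions, and
    :class:`CompletenessError` when a required sensor has no readings.
    """
    metadata: dict[str, str] = {}
    ts: dict[Sensor, list[int]] = {s: [] for s in SENSORS}
    vals: dict[Sensor, list[tuple[float, float, float]]] = {s: [] for s in SENSORS}
    header_seen = False

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if header_seen:
                    raise FormatError(
                        f"{path}:{lineno}: metadata comment after header"
                    )
                body = line[1:].strip()
                if "=" not in body:
                    raise FormatError(
                        f"{path}:{lineno}: metadata line is not 'key=value'"
                    )
                key, value = body.split("=", 1)
                metadata[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line != HEADER:
                    raise FormatError(
                        f"{path}:{lineno}: expected header '{HEADER}', "
                        f"got '{line}'"
                    )
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 comma-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                t = int(fields[0])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: timestamp '{fields[0]}' is not an integer"
                ) from None
            if t < 0:
                raise FormatError(f"{path}:{lineno}: negative timestamp {t}")
            sensor = _SENSOR_BY_TOKEN.get(fields[1])
            if sensor is None:
                raise FormatError(
                    f"{path}:{lineno}: unknown sensor token '{fields[1]}'"
                )
            try:
                xyz = tuple(float(f) for f in fields[2:5])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric axis value"
                ) from None
            if not all(np.isfinite(v) for v in xyz):
                raise FormatError(f"{path}:{lineno}: non-finite axis value")
            if ts[sensor] and t < ts[sensor][-1]:
                raise FormatError(
                    f"{path}:{lineno}: timestamp {t} for sensor "
                    f"'{sensor.value}' decreases (previous {ts[sensor][-1]})"
                )
            ts[sensor].append(t)
            vals[sensor].append(xyz)

    if not header_seen:
        raise FormatError(f"{path}: missing header line '{HEADER}'")

    empty = [s.value for s in SENSORS if not ts[s]]
    if empty:
        raise CompletenessError(
            f"{path}: no readings for required sensor(s): {', '.join(empty)}"
        )

    traces = {
        s: SensorTrace(
            s,
            np.array(ts[s], dtype=np.int64),
            np.array(vals[s], dtype=np.float64),
        )
        for s in SENSORS
    }

    label = None
    if "label" in metadata:
        token = metadata.pop("label")
        label = _ACTIVITY_BY_TOKEN.get(token)
        if label is None:
            raise FormatError(f"{path}: unknown activity label '{token}'")
    duration = 0
    if "duration_ms" in metadata:
        try:
            duration = int(metadata.pop("duration_ms"))
        except ValueError:
            raise FormatError(f"{path}: duration_ms is not an integer") from None

    return LabeledRecording(
        traces=traces, label=label, duration_ms=duration, metadata=metadata
    )


def write_sensor_log(recording: LabeledRecording, path: str | os.PathLike) -> None:
    """Write a recording as a sensor-log CSV; inverse of :func:`read_sensor_log`.

    Rows are merged across sensors by timestamp (canonical sensor order
    breaks ties), so two writes of the same recording are byte-identical.
    """
    for trace in recording.traces.values():
        trace.validate()
    lines: list[str] = []
    if recording.label is not None:
        lines.append(f"# label={recording.label.value}")
    lines.append(f"# duration_ms={recording.duration_ms}")
    for key in sorted(recording.metadata):
        lines.append(f"# {key}={recording.metadata[key]}")
    lines.append(HEADER)

    rows: list[tuple[int, int, str]] = []
    for si, sensor in enumerate(SENSORS):
        trace = recording.traces[sensor]
        for t, (x, y, z) in zip(trace.timestamps_ms, trace.values):
            rows.append(
                (int(t), si,
                 f"{int(t)},{sensor.value},{_fmt(x)},{_fmt(y)},{_fmt(z)}")
            )
    rows.sort(key=lambda r: (r[0], r[1]))  # stable: keeps per-sensor order
    lines.extend(r[2] for r in rows)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# feature files
# ---------------------------------------------------------------------------

def write_feature_file(
    rows: Sequence[tuple[np.ndarray | Sequence[float], Activity]],
    path: str | os.PathLike,
    n_features: int = 120,
) -> None:
    """Write (feature-vector, label) pairs, one comma-separated line each.

    The label token is the last field so the numeric columns stay
    contiguous. Raises :class:`DimensionError` if any vector does not
    have exactly ``n_features`` values.
    """
    lines = []
    for i, (vec, label) in enumerate(rows):
        values = np.asarray(getattr(vec, "values", vec), dtype=np.float64)
        if values.shape != (n_features,):
            raise DimensionError(
                f"row {i}: expected {n_features} feature values, "
                f"got shape {values.shape}"
            )
        lines.append(",".join(_fmt(v) for v in values) + "," + label.value)
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(line + "\n" for line in lines)


def read_feature_file(
    path: str | os.PathLike, n_features: int = 120
) -> list[tuple[np.ndarray, Activity]]:
    """Inverse of :func:`write_feature_file`."""
    out: list[tuple[np.ndarray, Activity]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != n_features + 1:
                raise DimensionError(
                    f"{path}:{lineno}: expected {n_features} values + label, "
                    f"got {len(fields)} fields"
                )
            label = _ACTIVITY_BY_TOKEN.get(fields[-1])
            if label is None:
                raise FormatError(
                    f"{path}:{lineno}: unknown activity label '{fields[-1]}'"
                )
            try:
                values = np.array([float(f) for f in fields[:-1]], dtype=np.float64)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric feature value") from None
            out.append((values, label))
    return out


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_model(model, path: str | os.PathLike) -> None:
    """Serialize an :class:`~pockethar.mlp_classifier.MLPModel` as JSON."""
    doc = {
        "format": "pockethar-mlp",
        "layer_dims": list(model.config.layer_dims),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "norm_mean": model.norm_mean.tolist(),
        "norm_scale": model.norm_scale.tolist(),
        "labels": [a.value for a in model.labels],
        "config": {
            "learning_rate": model.config.learning_rate,
            "epochs": model.config.epochs,
            "seed": model.config.seed,
            "normalize_features": model.config.normalize_features,
        },
        "training_loss": list(model.training_loss),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_model(path: str | os.PathLike):
    """Load a model JSON; validates all stored layer dimensions."""
    from pockethar.mlp_classifier import MLPConfig, MLPModel

    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "pockethar-mlp":
        raise FormatError(f"{path}: not a pockethar model file")
    dims = tuple(int(d) for d in doc["layer_dims"])
    weights = [np.array(w, dtype=np.float64) for w in doc["weights"]]
    biases = [np.array(b, dtype=np.float64) for b in doc["biases"]]
    if len(weights) != len(dims) - 1 or len(biases) != len(dims) - 1:
        raise FormatError(
            f"{path}: expected {len(dims) - 1} weight/bias layers for "
            f"dims {dims}"
        )
    for i, (w, b) in enumerate(zip(weights, biases)):
        want = (dims[i + 1], dims[i])
        if w.shape != want:
            raise FormatError(
                f"{path}: layer {i} weights have shape {w.shape}, "
                f"expected {want}"
            )
        if b.shape != (dims[i + 1],):
            raise FormatError(
                f"{path}: layer {i} biases have shape {b.shape}, "
                f"expected {(dims[i + 1],)}"
            )
    labels = tuple(_ACTIVITY_BY_TOKEN[t] for t in doc["labels"])
    if sorted(labels) != sorted(ACTIVITIES):
        raise FormatError(f"{path}: label set is not the six activities")
    norm_mean = np.array(doc["norm_mean"], dtype=np.float64)
    norm_scale = np.array(doc["norm_scale"], dtype=np.float64)
    if norm_mean.shape != (dims[0],) or norm_scale.shape != (dims[0],):
        raise FormatError(f"{path}: normalization statistics do not match input dim")
    if np.any(norm_scale <= 0):
        raise FormatError(f"{path}: non-positive normalization scale")
    cfg = doc.get("config", {})
    config = MLPConfig(
        layer_dims=dims,
        learning_rate=float(cfg.get("learning_rate", 0.1)),
        epochs=int(cfg.get("epochs", 100)),
        seed=int(cfg.get("seed", 0)),
        normalize_features=bool(cfg.get("normalize_features", True)),
    )
    return MLPModel(
        config=config,
        weights=weights,
        biases=biases,
        norm_mean=norm_mean,
        norm_scale=norm_scale,
        labels=labels,
        training_loss=[float(v) for v in doc.get("training_loss", [])],
    )
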