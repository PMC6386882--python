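"""Synthetic smartphone IMU recordings with realistic activity morphology.

The generator emulates a phone carried upright in a trouser pocket:

* **walking / running** — periodic accelerometer and gyroscope
  oscillations at the gait frequency riding on the gravity vector;
  running is faster and much larger in amplitude than walking.
* **sitting / standing** — near-constant, gravity-dominated traces
  whose posture vectors differ by an interchange of the Y and Z axes
  (phone vertical while standing, thigh horizontal while sitting).
* **upstairs / downstairs** — walking-like quasi-periodic traces at a
  slower cadence with an extra second harmonic on the vertical axis
  (the asymmetric step-up/step-down impact); their parameter ranges
  overlap each other and the low end of walking, so the two stair
  classes are deliberately the hardest to tell apart.

Acquisition is event-driven, as on a real handset: each sensor reports
at its own irregular cadence, so per-10-s reading counts differ by
sensor (defaults 164/124/124 for accelerometer/gyroscope/gravity) and
every generated recording exercises the first-N truncation path of the
windowing stage. All randomness is driven by explicit seeds; the same
seed reproduces a recording byte for byte.

The signal model is sinusoid-plus-Gaussian-noise rather than a
biomechanical gait simulation: the downstream classifier only consumes
windowed first/second-moment and histogram statistics, so matching
periodicity, amplitude and posture structure is what matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from pockethar.errors import ConfigError
from pockethar.types import (
    ACTIVITIES,
    Activity,
    LabeledRecording,
    Sensor,
    SENSORS,
    SensorTrace,
)

GRAVITY = 9.81

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)

#: Phone upright in a front trouser pocket: gravity mostly along Y.
UPRIGHT_POSTURE = _unit((0.10, 0.96, 0.26)) * GRAVITY
#: Seated, thigh horizontal: the Y and Z components interchange.
SEATED_POSTURE = _unit((0.10, 0.26, 0.96)) * GRAVITY

#: Per-axis share of the dynamic amplitude; the vertical axis (largest
#: gravity component) leads, the other two follow in axis order.
_AXIS_WEIGHTS = (1.0, 0.6, 0.45)

#: Second-harmonic share of the vertical oscillation for stair classes.
_STAIR_HARMONIC = {Activity.UPSTAIRS: 0.45, Activity.DOWNSTAIRS: 0.55}


@dataclass(frozen=True)
class ActivitySignalParams:
    """Signal morphology of one activity.

    ``gait_frequency_hz`` is the step cadence (0 for static postures),
    ``dynamic_amplitude`` the peak accelerometer oscillation in m/s^2,
    ``gyro_amplitude`` the peak angular rate in rad/s,
    ``posture_gravity`` the mean gravity vector (magnitude 9.81 m/s^2),
    ``noise_sd`` the additive Gaussian noise on accelerometer and
    gyroscope readings, and ``jitter_rel`` the relative spread of the
    per-recording frequency/phase perturbations.
    """

    activity: Activity
    gait_frequency_hz: float
    dynamic_amplitude: float
    gyro_amplitude: float
    posture_gravity: np.ndarray
    noise_sd: float = 0.15
    jitter_rel: float = 0.05

    def __post_init__(self) -> None:
        if self.gait_frequency_hz < 0 or self.dynamic_amplitude < 0:
            raise ConfigError("frequency and amplitude must be nonnegative")
        if self.gyro_amplitude < 0 or self.noise_sd < 0:
            raise ConfigError("gyro amplitude and noise sd must be nonnegative")
        g = np.asarray(self.posture_gravity, dtype=np.float64)
        if abs(np.linalg.norm(g) - GRAVITY) > 1e-6:
            raise ConfigError("posture gravity must have magnitude 9.81")
        object.__setattr__(self, "posture_gravity", g)

    @classmethod
    def for_activity(cls, activity: Activity) -> "ActivitySignalParams":
        """Default morphology for each of the six activities."""
        table = {
            Activity.WALKING: (1.8, 3.0, 1.5, UPRIGHT_POSTURE),
            Activity.RUNNING: (2.8, 8.0, 2.5, UPRIGHT_POSTURE),
            Activity.SITTING: (0.0, 0.0, 0.0, SEATED_POSTURE),
            Activity.STANDING: (0.0, 0.0, 0.0, UPRIGHT_POSTURE),
            Activity.UPSTAIRS: (1.5, 4.0, 1.2, UPRIGHT_POSTURE),
            Activity.DOWNSTAIRS: (1.5, 5.0, 1.4, UPRIGHT_POSTURE),
        }
        f, amp, gyro, posture = table[activity]
        return cls(
            activity=activity,
            gait_frequency_hz=f,
            dynamic_amplitude=amp,
            gyro_amplitude=gyro,
            posture_gravity=posture,
        )


@dataclass(frozen=True)
class AcquisitionParams:
    """Event-driven acquisition regime of the simulated handset."""

    duration_ms: int = 10_000
    nominal_interval_ms: int = 50
    readings_per_10s: dict[Sensor, int] = field(
        default_factory=lambda: {
            Sensor.ACCELEROMETER: 164,
            Sensor.GYROSCOPE: 124,
            Sensor.GRAVITY: 124,
        }
    )
    timestamp_jitter_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0 or self.nominal_interval_ms <= 0:
            raise ConfigError("duration and nominal interval must be positive")
        if any(self.readings_per_10s.get(s, 0) < 100 for s in SENSORS):
            raise ConfigError(
                "per-sensor reading counts must be at least 100 per 10 s"
            )


def _event_timestamps(
    rng: np.random.Generator, acq: AcquisitionParams, sensor: Sensor
) -> np.ndarray:
    """Jittered event timestamps, exact per-10-s-block reading counts."""
    block = 10_000
    per_block = acq.readings_per_10s[sensor]
    out = []
    start = 0
    while start < acq.duration_ms:
        span = min(block, acq.duration_ms - start)
        n = int(round(per_block * span / block))
        base = start + (np.arange(n) + 0.5) * span / n
        t = base + rng.normal(0.0, acq.timestamp_jitter_ms, size=n)
        t = np.clip(np.sort(t), start, start + span - 1)
        out.append(np.round(t).astype(np.int64))
        start += span
    ts = np.concatenate(out)
    return np.maximum.accumulate(ts)  # rounding must not break monotonicity


def generate_recording(
    params: ActivitySignalParams, acq: AcquisitionParams = AcquisitionParams()
) -> LabeledRecording:
    """Simulate one labeled recording; fully determined by ``acq.seed``."""
    rng = np.random.default_rng(acq.seed)
    g = params.posture_gravity
    vertical = int(np.argmax(np.abs(g)))
    # vertical axis takes the leading weight, the rest follow in order
    weights = np.empty(3)
    weights[vertical] = _AXIS_WEIGHTS[0]
    weights[[i for i in range(3) if i != vertical]] = _AXIS_WEIGHTS[1:]

    f = params.gait_frequency_hz * (1.0 + rng.normal(0.0, params.jitter_rel))
    f = max(f, 0.0)
    acc_phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    gyro_phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    harmonic = _STAIR_HARMONIC.get(params.activity, 0.0)
    harm_phase = rng.uniform(0.0, 2.0 * np.pi)

    traces: dict[Sensor, SensorTrace] = {}
    for sensor in SENSORS:
        ts = _event_timestamps(rng, acq, sensor)
        t = ts / 1000.0
        n = ts.shape[0]
        if sensor is Sensor.ACCELEROMETER:
            sig = np.tile(g, (n, 1))
            if f > 0 and params.dynamic_amplitude > 0:
                for ax in range(3):
                    sig[:, ax] += (
                        params.dynamic_amplitude
                        * weights[ax]
                        * np.sin(2.0 * np.pi * f * t + acc_phases[ax])
                    )
                if harmonic > 0:
                    sig[:, vertical] += (
                        harmonic
                        * params.dynamic_amplitude
                        * np.sin(4.0 * np.pi * f * t + harm_phase)
                    )
            sig += rng.normal(0.0, params.noise_sd, size=(n, 3))
        elif sensor is Sensor.GYROSCOPE:
            sig = np.zeros((n, 3))
            if f > 0 and params.gyro_amplitude > 0:
                for ax in range(3):
                    sig[:, ax] += (
                        params.gyro_amplitude
                        * weights[ax]
                        * np.sin(2.0 * np.pi * f * t + gyro_phases[ax])
                    )
            sig += rng.normal(0.0, params.noise_sd, size=(n, 3))
        else:  # gravity: low-pass posture component, small residual noise
            sig = np.tile(g, (n, 1))
            sig += rng.normal(0.0, 0.1 * params.noise_sd, size=(n, 3))
        traces[sensor] = SensorTrace(sensor, ts, sig)

    metadata = {
        "activity": params.activity.value,
        "gait_frequency_hz": format(f, ".6g"),
        "dynamic_amplitude": format(params.dynamic_amplitude, ".6g"),
        "gyro_amplitude": format(params.gyro_amplitude, ".6g"),
        "noise_sd": format(params.noise_sd, ".6g"),
        "seed": str(acq.seed),
    }
    return LabeledRecording(
        traces=traces,
        label=params.activity,
        duration_ms=acq.duration_ms,
        metadata=metadata,
    )


def _draw_params(
    activity: Activity, rng: np.random.Generator
) -> ActivitySignalParams:
    """Per-recording morphology draw around the class defaults.

    Stair parameters are drawn from ranges that overlap each other and
    the low end of walking, so stair/stair and stair/walking confusions
    occur naturally; the static postures get small orientation wobble.
    """
    base = ActivitySignalParams.for_activity(activity)
    if activity is Activity.WALKING:
        return replace(
            base,
            gait_frequency_hz=max(0.5, rng.normal(1.8, 0.09)),
            dynamic_amplitude=max(0.5, rng.normal(3.0, 0.25)),
            gyro_amplitude=max(0.1, rng.normal(1.5, 0.15)),
        )
    if activity is Activity.RUNNING:
        return replace(
            base,
            gait_frequency_hz=max(0.5, rng.normal(2.8, 0.14)),
            dynamic_amplitude=max(1.0, rng.normal(8.0, 0.6)),
            gyro_amplitude=max(0.1, rng.normal(2.5, 0.25)),
        )
    if activity is Activity.UPSTAIRS:
        return replace(
            base,
            gait_frequency_hz=rng.uniform(1.35, 1.65),
            dynamic_amplitude=rng.uniform(3.6, 4.6),
            gyro_amplitude=rng.uniform(1.0, 1.5),
        )
    if activity is Activity.DOWNSTAIRS:
        return replace(
            base,
            gait_frequency_hz=rng.uniform(1.35, 1.65),
            dynamic_amplitude=rng.uniform(4.4, 5.6),
            gyro_amplitude=rng.uniform(1.2, 1.7),
        )
    # static postures: small orientation wobble, renormalized to 9.81
    direction = base.posture_gravity / GRAVITY + rng.normal(0.0, 0.03, size=3)
    return replace(base, posture_gravity=_unit(direction) * GRAVITY)


def generate_dataset(
    n_per_class: int,
    seed: int = 0,
    acq: AcquisitionParams = AcquisitionParams(),
) -> list[LabeledRecording]:
    """Balanced labeled recordings: ``6 * n_per_class`` in total.

    Recording (class c, index i) is driven by a seed sequence spawned
    deterministically from ``seed``, so the dataset is reproducible byte
    for byte and independent of generation order.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be at least 1")
    recordings: list[LabeledRecording] = []
    for ci, activity in enumerate(ACTIVITIES):
        for i in range(n_per_class):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(ci, i))
            param_rng = np.random.default_rng(ss)
            params = _draw_params(activity, param_rng)
            rec_seed = int(param_rng.integers(0, 2**31))
            recordings.append(
                generate_recording(params, replace(acq, seed=rec_seed))
            )
    return recordings
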