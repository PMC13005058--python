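"""The 10-channel kinematic feature set and the 14-feature static baseline.

The model input channels are, in fixed order: vehicle speed (m/s), linear
accelerations along the three body axes (m/s^2), angular velocities about the
three axes (rad/s), and the three derived angular accelerations (rad/s^2) —
temporal gradients of the gyroscope channels that capture how abruptly angular
velocity changes within a maneuver.  Rapid within-turn fluctuations of these
derived channels reflect steering micro-adjustments associated with reduced
motor control.

The static baseline summarizes a trip as the mean and population SD of the
seven raw channels (14 features), the representation conventional telematics
classifiers consume.
"""

from __future__ import annotations

import numpy as np

from .preprocess import TripRecord

#: fixed model-input channel order
CHANNELS = [
    "speed", "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "gyro_x_acc", "gyro_y_acc", "gyro_z_acc",
]
N_CHANNELS = len(CHANNELS)

#: raw channels summarized by the static baseline (order fixed)
STATIC_BASE = ["acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z", "speed"]
STATIC_FEATURE_NAMES = [f"{c}_mean" for c in STATIC_BASE] + [f"{c}_sd" for c in STATIC_BASE]


def angular_acceleration(gyro_channel: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Temporal gradient of an angular-velocity series.

    Central differences on interior points, one-sided differences at the
    endpoints; output length equals input length.  Exact for linear inputs.
    """
    w = np.asarray(gyro_channel, dtype=float)
    if w.ndim != 1 or len(w) < 2:
        raise ValueError("need a 1-D series of length >= 2")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return np.gradient(w, dt)


def build_channel_set(trip: TripRecord, dt: float = 1.0) -> np.ndarray:
    """Assemble the S x 10 channel matrix of a synchronized trip.

    Columns follow :data:`CHANNELS`; the three derived angular-acceleration
    channels are computed from the merged 1 Hz gyroscope columns at ``dt``.
    """
    if trip.merged_1hz is None:
        raise ValueError("trip has no merged 1 Hz table; synchronize first")
    m = trip.merged_1hz
    cols = [m[c].to_numpy(float) for c in CHANNELS[:7]]
    if len(m) < 2:
        raise ValueError("trip too short for derived channels")
    for axis in ("gyro_x", "gyro_y", "gyro_z"):
        cols.append(angular_acceleration(m[axis].to_numpy(float), dt))
    return np.column_stack(cols)


def static_features(trip: TripRecord) -> np.ndarray:
    """14-feature static vector: 7 channel means then 7 population SDs."""
    if trip.merged_1hz is None:
        raise ValueError("trip has no merged 1 Hz table; synchronize first")
    m = trip.merged_1hz
    if len(m) < 2:
        raise ValueError("SD undefined for fewer than 2 rows")
    vals = m[STATIC_BASE].to_numpy(float)
    return np.concatenate([vals.mean(axis=0), vals.std(axis=0, ddof=0)])
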