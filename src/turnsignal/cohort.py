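"""Synthetic naturalistic-driving cohort generator.

Real MCI driving cohorts are small, private, and expensive to collect, so the
package ships a generator that emulates the statistical structure the analysis
assumes: per-participant trips recorded by a 1 Hz GPS (latitude, longitude,
speed) and 24 Hz accelerometer/gyroscope, routes built from waypoint polylines
whose corners produce detectable turning maneuvers, a sporadic per-trip
impairment signature for the MCI class, and injectable sensor malfunctions
(missing per-sensor trips, mid-trip cutoffs, blanked values) that exercise the
cleaning rules.

The impairment signature is a multiplicative inflation of the within-turn
fluctuation SD of speed and yaw rate: drivers with mild cognitive impairment
make frequent steering/speed micro-adjustments inside a maneuver, which shows
up as extra high-frequency variance around the turn peak.  ``effect_size = 1``
reproduces the null (the two classes are exchangeable); each MCI trip expresses
the signature with probability ``impaired_trip_fraction``, modelling the
episodic day-to-day variability of MCI.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: canonical sensor names and their CSV channel columns
SENSOR_CHANNELS = {
    "gps": ["lat", "lon", "speed"],
    "accel": ["acc_x", "acc_y", "acc_z"],
    "gyro": ["gyro_x", "gyro_y", "gyro_z"],
}
SENSORS = tuple(SENSOR_CHANNELS)


@dataclass(frozen=True)
class MalfunctionRates:
    """Per-trip probabilities of the three malfunction modes.

    ``missing_trip`` drops one sensor's recording of a trip entirely,
    ``cutoff`` truncates a sensor stream mid-trip, ``missing_values`` blanks a
    short block of one channel (NaNs) so the synchronizer must drop rows.
    """

    missing_trip: float = 0.0
    cutoff: float = 0.0
    missing_values: float = 0.0

    def __post_init__(self) -> None:
        for name in ("missing_trip", "cutoff", "missing_values"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    @property
    def any(self) -> bool:
        return (self.missing_trip, self.cutoff, self.missing_values) != (0, 0, 0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    Defaults mirror the analyzed-cohort structure: 12 cognitively healthy and 7
    MCI drivers, a wide spread of trips per participant, GPS at 1 Hz and IMU at
    24 Hz.  ``effect_size`` multiplies the within-turn speed/yaw-rate
    fluctuation SD for impaired trips; ``impaired_trip_fraction`` is the
    per-trip probability that an MCI participant's trip expresses the
    signature.
    """

    n_healthy: int = 12
    n_mci: int = 7
    trips_per_participant: tuple[int, int] = (3, 46)
    trip_duration_s: tuple[int, int] = (120, 600)
    turn_count_per_trip: tuple[int, int] = (2, 8)
    gps_rate_hz: float = 1.0
    imu_rate_hz: float = 24.0
    effect_size: float = 2.5
    impaired_trip_fraction: float = 1.0
    malfunction_rates: MalfunctionRates = field(default_factory=MalfunctionRates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_mci < 0:
            raise ValueError("participant counts must be >= 0")
        if self.gps_rate_hz <= 0 or self.imu_rate_hz <= 0:
            raise ValueError("sampling rates must be > 0")
        if self.effect_size < 1.0:
            raise ValueError("effect_size must be >= 1 (1 reproduces the null)")
        if not 0.0 <= self.impaired_trip_fraction <= 1.0:
            raise ValueError("impaired_trip_fraction must be in [0, 1]")
        for name in ("trips_per_participant", "trip_duration_s", "turn_count_per_trip"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a (lo, hi) range with 0 <= lo <= hi")


@dataclass
class SensorStream:
    """One modality's timestamped channel matrix at a declared sampling rate."""

    modality: str
    rate_hz: float
    timestamps: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # T x k

    def __post_init__(self) -> None:
        if self.modality not in SENSOR_CHANNELS:
            raise ValueError(f"unknown modality {self.modality!r}")
        k = len(SENSOR_CHANNELS[self.modality])
        if self.values.ndim != 2 or self.values.shape[1] != k:
            raise ValueError(
                f"{self.modality} stream must be T x {k}, got {self.values.shape}"
            )
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values length mismatch")

    @property
    def channels(self) -> list[str]:
        return SENSOR_CHANNELS[self.modality]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channels)
        df.insert(0, "timestamp", self.timestamps)
        return df

    def copy(self) -> "SensorStream":
        return SensorStream(
            self.modality, self.rate_hz, self.timestamps.copy(), self.values.copy()
        )


@dataclass
class Participant:
    participant_id: str
    age: int
    sex: str
    label: str  # "healthy" | "mci"


@dataclass
class RawCohort:
    """Generated cohort: participants, per-trip sensor streams, ground truth.

    ``streams[pid]`` is a list of trips; each trip is a dict mapping sensor
    name to :class:`SensorStream` (a sensor may be absent after malfunction
    injection).  ``ground_truth[pid]`` holds the per-trip impairment indicator
    and the planted corner positions (GPS sample indices), used only by
    recovery tests — the analysis pipeline never reads them.
    """

    config: CohortConfig
    participants: list[Participant]
    streams: dict[str, list[dict[str, SensorStream]]]
    ground_truth: dict[str, list[dict]]

    @property
    def n_trips(self) -> int:
        return sum(len(v) for v in self.streams.values())

    def labels(self) -> dict[str, str]:
        return {p.participant_id: p.label for p in self.participants}


# ---------------------------------------------------------------------------
# route / kinematics simulation
# ---------------------------------------------------------------------------

def _simulate_trip(
    rng: np.random.Generator,
    duration_s: int,
    n_turns: int,
    effect: float,
    config: CohortConfig,
) -> tuple[dict[str, SensorStream], list[int]]:
    """Simulate one trip's GPS + IMU streams from a waypoint polyline.

    Returns the three sensor streams (timestamps starting at 0) and the list of
    planted corner centers as GPS sample indices.
    """
    T = int(duration_s)
    t_gps = np.arange(T, dtype=np.float64)

    # straight segments separated by corners of 60-120 deg, each corner
    # traversed over ~4 s (heading rate well above the 10 deg/s threshold)
    corner_dur = 4
    margin = 20  # keep corners away from trip edges
    usable = T - 2 * margin - n_turns * corner_dur
    if n_turns > 0 and usable <= n_turns:
        n_turns = max(0, (T - 2 * margin) // (corner_dur + 10))
        usable = T - 2 * margin - n_turns * corner_dur
    corner_starts: list[int] = []
    if n_turns > 0:
        # space corner starts over the usable interior with >=6 s of straight
        cuts = np.sort(rng.choice(np.arange(1, max(usable, n_turns + 1)), size=n_turns, replace=False))
        corner_starts = [margin + int(c) + i * corner_dur for i, c in enumerate(cuts)]

    heading = np.empty(T)
    heading[:] = rng.uniform(-math.pi, math.pi)
    yaw_rate = np.zeros(T)
    corner_centers: list[int] = []
    for s in corner_starts:
        turn = math.radians(rng.uniform(60.0, 120.0)) * rng.choice([-1.0, 1.0])
        rate = turn / corner_dur
        yaw_rate[s : s + corner_dur] = rate
        corner_centers.append(s + corner_dur // 2)
    heading = heading[0] + np.concatenate([[0.0], np.cumsum(yaw_rate[:-1])])

    # speed: cruise with slow drift, slow-down through corners
    base = rng.uniform(8.0, 15.0)
    speed = base + np.cumsum(rng.normal(0.0, 0.05, T))
    turn_mask = np.zeros(T, dtype=bool)
    for c in corner_centers:
        turn_mask[max(0, c - 5) : c + 6] = True
    speed = np.where(turn_mask, speed * 0.7, speed)
    speed = np.clip(speed, 2.0, None)

    # within-turn fluctuation (steering/speed micro-adjustments); SD inflated
    # by `effect` on impaired trips.  Baselines sit at ~10% of typical corner
    # yaw rate so the signature is a salient, recoverable component.
    sd_speed, sd_yaw = 0.4, 0.04
    speed_noise = rng.normal(0.0, sd_speed, T) * np.where(turn_mask, effect, 1.0)
    yaw_noise = rng.normal(0.0, sd_yaw, T) * np.where(turn_mask, effect, 1.0)
    speed_obs = np.clip(speed + speed_noise, 0.0, None)
    yaw_obs = yaw_rate + yaw_noise

    # integrate the jittered kinematics so GPS positions carry the signature
    vx = speed_obs * np.cos(heading)
    vy = speed_obs * np.sin(heading)
    x = np.concatenate([[0.0], np.cumsum(vx[:-1])])  # metres
    y = np.concatenate([[0.0], np.cumsum(vy[:-1])])

    # local inverse equirectangular around a Phoenix-area reference
    ref_lat = math.radians(33.4 + rng.uniform(-0.2, 0.2))
    ref_lon = math.radians(-111.9 + rng.uniform(-0.2, 0.2))
    lat = np.degrees(ref_lat + (y / 1000.0) / EARTH_RADIUS_KM)
    lon = np.degrees(ref_lon + (x / 1000.0) / (EARTH_RADIUS_KM * math.cos(ref_lat)))

    gps = SensorStream(
        "gps", config.gps_rate_hz, t_gps, np.column_stack([lat, lon, speed_obs])
    )

    # IMU at 24 Hz: upsample 1 Hz kinematics, add high-frequency sensor noise;
    # within-turn noise inflated by `effect` (micro-adjustment signature)
    n_imu = int(round(T * config.imu_rate_hz / config.gps_rate_hz))
    t_imu = np.arange(n_imu) / config.imu_rate_hz
    up = lambda sig: np.interp(t_imu, t_gps, sig)  # noqa: E731
    turn_mask_imu = up(turn_mask.astype(float)) > 0.5
    boost = np.where(turn_mask_imu, effect, 1.0)

    accel_long = np.gradient(speed_obs, t_gps)
    gyro_z = up(yaw_obs) + rng.normal(0.0, 0.02, n_imu) * boost
    gyro_x = rng.normal(0.0, 0.01, n_imu)
    gyro_y = rng.normal(0.0, 0.01, n_imu)
    acc_x = up(accel_long) + rng.normal(0.0, 0.08, n_imu)
    acc_y = up(speed_obs * yaw_obs) + rng.normal(0.0, 0.08, n_imu) * boost
    acc_z = rng.normal(0.0, 0.05, n_imu)

    accel = SensorStream(
        "accel", config.imu_rate_hz, t_imu, np.column_stack([acc_x, acc_y, acc_z])
    )
    gyro = SensorStream(
        "gyro", config.imu_rate_hz, t_imu, np.column_stack([gyro_x, gyro_y, gyro_z])
    )
    return {"gps": gps, "accel": accel, "gyro": gyro}, corner_centers


def generate_cohort(config: CohortConfig) -> RawCohort:
    """Generate a labeled synthetic driving cohort.

    Deterministic for a fixed ``config.seed``: one generator is seeded once and
    every stochastic draw flows from it.  Trips within a participant are
    separated by gaps > 60 s so downstream gap-based segmentation recovers them.
    """
    rng = np.random.default_rng(config.seed)
    participants: list[Participant] = []
    streams: dict[str, list[dict[str, SensorStream]]] = {}
    truth: dict[str, list[dict]] = {}

    labels = ["healthy"] * config.n_healthy + ["mci"] * config.n_mci
    for i, label in enumerate(labels, start=1):
        pid = f"{i:03d}"
        participants.append(
            Participant(
                participant_id=pid,
                age=int(rng.integers(65, 86)),
                sex=str(rng.choice(["F", "M"])),
                label=label,
            )
        )
        n_trips = int(rng.integers(config.trips_per_participant[0],
                                   config.trips_per_participant[1] + 1))
        trips: list[dict[str, SensorStream]] = []
        info: list[dict] = []
        t0 = float(rng.integers(0, 86_400))
        for _ in range(n_trips):
            dur = int(rng.integers(config.trip_duration_s[0], config.trip_duration_s[1] + 1))
            n_turns = int(rng.integers(config.turn_count_per_trip[0],
                                       config.turn_count_per_trip[1] + 1))
            impaired = bool(
                label == "mci" and rng.random() < config.impaired_trip_fraction
            )
            effect = config.effect_size if impaired else 1.0
            trip, corners = _simulate_trip(rng, dur, n_turns, effect, config)
            for s in trip.values():  # shift onto the cohort timeline
                s.timestamps = s.timestamps + t0
            trips.append(trip)
            info.append({"impaired": impaired, "corners": corners, "duration_s": dur})
            t0 += dur + float(rng.integers(120, 3600))  # inter-trip gap > 60 s
        streams[pid] = trips
        truth[pid] = info

    cohort = RawCohort(config, participants, streams, truth)
    if config.malfunction_rates.any:
        cohort = inject_malfunctions(cohort, config.malfunction_rates,
                                     seed=int(rng.integers(0, 2**31 - 1)))
    return cohort


def inject_malfunctions(
    cohort: RawCohort, rates: MalfunctionRates, seed: int = 0
) -> RawCohort:
    """Corrupt a cohort's streams per the configured malfunction probabilities.

    Whole per-sensor trips are dropped, streams truncated mid-trip, or short
    value blocks blanked to NaN.  Ground truth is untouched.  Returns a new
    cohort; the input is not modified.
    """
    rng = np.random.default_rng(seed)
    new_streams: dict[str, list[dict[str, SensorStream]]] = {}
    for pid, trips in cohort.streams.items():
        out_trips: list[dict[str, SensorStream]] = []
        for trip in trips:
            new_trip: dict[str, SensorStream] = {}
            for sensor, stream in trip.items():
                if rng.random() < rates.missing_trip:
                    continue  # sensor failed to record this trip
                s = stream.copy()
                if rng.random() < rates.cutoff and len(s.timestamps) > 4:
                    keep = int(len(s.timestamps) * rng.uniform(0.3, 0.7))
                    s = SensorStream(s.modality, s.rate_hz,
                                     s.timestamps[:keep], s.values[:keep])
                if rng.random() < rates.missing_values and len(s.timestamps) > 4:
                    ch = int(rng.integers(0, s.values.shape[1]))
                    start = int(rng.integers(0, len(s.timestamps) - 2))
                    width = int(rng.integers(1, min(5, len(s.timestamps) - start)))
                    s.values[start : start + width, ch] = np.nan
                new_trip[sensor] = s
            out_trips.append(new_trip)
        new_streams[pid] = out_trips
    return RawCohort(cohort.config, cohort.participants, new_streams,
                     cohort.ground_truth)


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------

def export_csv(cohort: RawCohort, root_dir: str | Path) -> Path:
    """Write the cohort as ``root/participant_<id>/<sensor>/trip_<k>.csv``.

    Also writes ``participants.csv`` (id, age, sex, label) at the root.  The
    layout round-trips losslessly through :func:`read_csv_tree`.
    """
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    rows = [dataclasses.asdict(p) for p in cohort.participants]
    pd.DataFrame(rows, columns=["participant_id", "age", "sex", "label"]).to_csv(
        root / "participants.csv", index=False
    )
    for pid, trips in cohort.streams.items():
        for k, trip in enumerate(trips, start=1):
            for sensor, stream in trip.items():
                d = root / f"participant_{pid}" / sensor
                d.mkdir(parents=True, exist_ok=True)
                stream.to_frame().to_csv(d / f"trip_{k:03d}.csv", index=False,
                                         float_format="%.9f")
    return root


def read_csv_tree(root_dir: str | Path) -> RawCohort:
    """Read a cohort back from the :func:`export_csv` directory layout."""
    root = Path(root_dir)
    ptable = root / "participants.csv"
    if ptable.exists():
        pdf = pd.read_csv(ptable, dtype={"participant_id": str})
        participants = [Participant(r.participant_id, int(r.age), str(r.sex), str(r.label))
                        for r in pdf.itertuples()]
    else:
        participants = []
    streams: dict[str, list[dict[str, SensorStream]]] = {}
    known = {p.participant_id for p in participants}
    for pdir in sorted(root.glob("participant_*")):
        pid = pdir.name.removeprefix("participant_")
        if participants and pid not in known:
            continue
        trip_files: dict[str, dict[str, Path]] = {}
        for sensor in SENSORS:
            for f in sorted((pdir / sensor).glob("trip_*.csv")):
                trip_files.setdefault(f.stem, {})[sensor] = f
        trips = []
        for key in sorted(trip_files):
            trip: dict[str, SensorStream] = {}
            for sensor, f in trip_files[key].items():
                df = pd.read_csv(f)
                rate = {"gps": 1.0, "accel": 24.0, "gyro": 24.0}[sensor]
                trip[sensor] = SensorStream(
                    sensor, rate,
                    df["timestamp"].to_numpy(float),
                    df[SENSOR_CHANNELS[sensor]].to_numpy(float),
                )
            trips.append(trip)
        streams[pid] = trips
    if not participants:
        participants = [Participant(pid, 0, "?", "healthy") for pid in streams]
    return RawCohort(CohortConfig(), participants, streams, {})
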