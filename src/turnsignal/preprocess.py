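"""Trip segmentation, cross-sensor completeness checks, and 1 Hz synchronization.

Raw logger output arrives as per-sensor streams whose timestamps contain
inter-trip gaps, and sensors fail independently (missing trips, mid-trip
cutoffs, blanked values).  This module segments streams into trips on a
60-second gap rule, flags participants whose per-sensor trip counts disagree,
matches per-sensor trips by timestamp overlap, and merges the 24 Hz IMU
channels onto the 1 Hz GPS timeline by block averaging.  Only complete,
synchronized trips survive; every exclusion is logged with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import RawCohort, SensorStream, SENSORS, read_csv_tree

#: columns of the merged 1 Hz table (position + the 7 raw kinematic channels)
MERGED_COLUMNS = [
    "timestamp", "lat", "lon", "speed",
    "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z",
]

DEFAULT_GAP_S = 60.0
MIN_TRIP_ROWS = 30  # merged rows; shorter trips carry no turn window


@dataclass
class TripRecord:
    """A per-sensor-complete trip; after synchronization carries a 1 Hz table."""

    participant_id: str
    trip_id: str
    streams: dict[str, SensorStream]
    merged_1hz: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return 0 if self.merged_1hz is None else len(self.merged_1hz)


@dataclass
class MismatchReport:
    participant_id: str
    counts: dict[str, int]
    flagged: bool


@dataclass
class Exclusion:
    participant_id: str
    trip_id: str
    reason: str


def segment_trips(stream: SensorStream, gap_s: float = DEFAULT_GAP_S) -> list[tuple[int, int]]:
    """Split a stream into trips at timestamp gaps exceeding ``gap_s``.

    Returns half-open index ranges ``(start, stop)`` that partition the stream;
    a new range starts exactly where the delta between consecutive timestamps
    exceeds ``gap_s`` (deltas <= ``gap_s`` continue the same trip).
    """
    t = np.asarray(stream.timestamps, dtype=float)
    if len(t) == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > gap_s) + 1
    edges = [0, *breaks.tolist(), len(t)]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def check_mismatch(participant_id: str, trip_counts_by_sensor: dict[str, int]) -> MismatchReport:
    """Flag a participant whose per-sensor trip counts disagree.

    A missing sensor is treated as count 0 (and therefore flagged whenever any
    other sensor recorded trips).
    """
    counts = {s: int(trip_counts_by_sensor.get(s, 0)) for s in SENSORS}
    flagged = len(set(counts.values())) > 1
    return MismatchReport(participant_id, counts, flagged)


def synchronize(trip: TripRecord) -> TripRecord:
    """Merge the trip's IMU channels onto the GPS 1 Hz timeline.

    Every IMU sample with timestamp in ``[g, g + 1/gps_rate)`` is assigned to
    GPS second ``g`` and block-averaged per channel; ragged final blocks
    average over the available samples.  GPS seconds with no IMU samples, or
    rows containing any NaN, are dropped and the trip flagged.  Trips with
    fewer than 2 surviving rows are rejected.
    """
    missing = [s for s in SENSORS if s not in trip.streams]
    if missing:
        raise ValueError(f"trip {trip.trip_id}: missing sensors {missing}")
    gps = trip.streams["gps"]
    period = 1.0 / gps.rate_hz
    out = {"timestamp": gps.timestamps,
           "lat": gps.values[:, 0], "lon": gps.values[:, 1], "speed": gps.values[:, 2]}
    dropped = bool(np.isnan(gps.values).any())
    for sensor in ("accel", "gyro"):
        s = trip.streams[sensor]
        # block index of each high-rate sample on the GPS grid
        idx = np.searchsorted(gps.timestamps, s.timestamps + 1e-9 * period, side="right") - 1
        valid = (idx >= 0) & (s.timestamps < gps.timestamps[-1] + period)
        for j, ch in enumerate(s.channels):
            vals = s.values[valid, j]
            bins = idx[valid]
            n_rows = len(gps.timestamps)
            cnt = np.bincount(bins, minlength=n_rows).astype(float)
            # NaN samples poison their whole block: that second is dropped
            tot = np.bincount(bins, weights=vals, minlength=n_rows)
            with np.errstate(invalid="ignore"):
                out[ch] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
            if np.isnan(vals).any():
                dropped = True
    merged = pd.DataFrame(out, columns=MERGED_COLUMNS)
    n0 = len(merged)
    merged = merged.dropna().reset_index(drop=True)
    flags = list(trip.flags)
    if len(merged) < n0 or dropped:
        flags.append("rows_dropped")
    if len(merged) < 2:
        raise ValueError(f"trip {trip.trip_id}: incomplete")
    return TripRecord(trip.participant_id, trip.trip_id, trip.streams, merged, flags)


def _overlap(a: SensorStream, b: SensorStream) -> float:
    lo = max(a.timestamps[0], b.timestamps[0])
    hi = min(a.timestamps[-1], b.timestamps[-1])
    return hi - lo


def _match_trips(per_sensor: dict[str, list[SensorStream]]) -> list[dict[str, SensorStream]]:
    """Align per-sensor trip lists by timestamp overlap (GPS as anchor)."""
    anchors = per_sensor.get("gps", [])
    matched = []
    for g in anchors:
        trip = {"gps": g}
        for sensor in ("accel", "gyro"):
            best, best_ov = None, 0.0
            for s in per_sensor.get(sensor, []):
                ov = _overlap(g, s)
                if ov > best_ov:
                    best, best_ov = s, ov
            if best is not None and best_ov > 0:
                trip[sensor] = best
        matched.append(trip)
    return matched


def clean_cohort(
    raw: RawCohort | str | Path,
    gap_s: float = DEFAULT_GAP_S,
    min_rows: int = MIN_TRIP_ROWS,
) -> tuple[list[TripRecord], list[Exclusion], list[MismatchReport]]:
    """Run the full cleaning funnel over a cohort (in memory or a CSV tree).

    Per participant: segment each sensor stream on the gap rule, run the
    mismatch check, match per-sensor trips by timestamp overlap, synchronize,
    and retain only trips that are complete across all three sensors, NaN-free
    after merging, and at least ``min_rows`` merged rows long.  Returns the
    retained trips, the exclusion log, and the per-participant mismatch
    reports.
    """
    if not isinstance(raw, RawCohort):
        raw = read_csv_tree(raw)
    kept: list[TripRecord] = []
    excluded: list[Exclusion] = []
    reports: list[MismatchReport] = []
    for pid in sorted(raw.streams):
        trips = raw.streams[pid]
        # re-segment each sensor stream (files may hold concatenated trips)
        per_sensor: dict[str, list[SensorStream]] = {s: [] for s in SENSORS}
        for trip in trips:
            for sensor, stream in trip.items():
                for a, b in segment_trips(stream, gap_s):
                    per_sensor[sensor].append(
                        SensorStream(sensor, stream.rate_hz,
                                     stream.timestamps[a:b], stream.values[a:b])
                    )
        reports.append(check_mismatch(pid, {s: len(v) for s, v in per_sensor.items()}))
        for k, trip in enumerate(_match_trips(per_sensor), start=1):
            tid = f"{k:03d}"
            rec = TripRecord(pid, tid, trip)
            if set(trip) != set(SENSORS):
                excluded.append(Exclusion(pid, tid, "missing_sensor"))
                continue
            try:
                rec = synchronize(rec)
            except ValueError:
                excluded.append(Exclusion(pid, tid, "incomplete"))
                continue
            if rec.n_rows < min_rows:
                excluded.append(Exclusion(pid, tid, "too_short"))
                continue
            kept.append(rec)
    return kept, excluded, reports


def manifest(trips: list[TripRecord]) -> pd.DataFrame:
    """Tidy cleaned-trips manifest (participant, trip, n_rows, flags)."""
    return pd.DataFrame(
        [
            {"participant_id": t.participant_id, "trip_id": t.trip_id,
             "n_rows": t.n_rows, "flags": ";".join(t.flags)}
            for t in trips
        ],
        columns=["participant_id", "trip_id", "n_rows", "flags"],
    )


def exclusion_log(excluded: list[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"participant_id": e.participant_id, "trip_id": e.trip_id, "reason": e.reason}
         for e in excluded],
        columns=["participant_id", "trip_id", "reason"],
    )
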