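"""Turning-maneuver detection and window extraction on the merged 1 Hz trip.

Turning a vehicle is cognitively demanding (divided attention, working memory,
spatial orientation), so maneuvers around detected heading-change peaks are
extracted as candidate biomarkers.  GPS latitude/longitude are projected onto a
local planar frame, heading-change magnitudes between successive path steps
are thresholded (default 10 degrees = 0.174533 rad), zero-speed candidates are
discarded, adjacent candidates are merged to their median index, and a +/-15 s
window (31 rows at 1 Hz) of the 10-channel feature matrix is cut around each
surviving peak.  Edge-truncated windows are linearly interpolated back to 31
rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import EARTH_RADIUS_KM
from .features import build_channel_set, N_CHANNELS
from .preprocess import TripRecord
from .tensorize import interpolate_to_length


@dataclass(frozen=True)
class ProjectionParams:
    """Local equirectangular projection: x = R*lon*cos(ref_lat), y = R*lat."""

    earth_radius_km: float = EARTH_RADIUS_KM
    ref_lat_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.earth_radius_km <= 0:
            raise ValueError("earth radius must be > 0")


@dataclass(frozen=True)
class TurnDetectorParams:
    """Thresholds for turn-peak detection.

    ``gradient_threshold_rad`` is the minimum heading change between successive
    path steps for a sample to count as a turn candidate (default 10 degrees).
    ``mode`` selects how the directional change is computed: ``"heading"``
    (default) uses atan2 of path increments, which is defined everywhere;
    ``"slope"`` uses the arctangent of dy/dx and discards samples with dx = 0,
    mirroring the undefined-gradient filter of slope-based detection.
    """

    gradient_threshold_rad: float = 0.174533
    half_window_s: int = 15
    adjacency_gap: int = 2
    min_speed: float = 0.0  # candidates must have speed strictly above this
    mode: str = "heading"

    def __post_init__(self) -> None:
        if self.gradient_threshold_rad <= 0:
            raise ValueError("gradient threshold must be > 0")
        if self.half_window_s < 1:
            raise ValueError("half window must be >= 1 s")
        if self.mode not in ("heading", "slope"):
            raise ValueError("mode must be 'heading' or 'slope'")

    @property
    def window_len(self) -> int:
        return 2 * self.half_window_s + 1


@dataclass
class TurnSegment:
    """A fixed-length, 10-channel window centered on a detected turn peak."""

    participant_id: str
    trip_id: str
    peak_index: int
    window: np.ndarray  # window_len x 10
    truncated: bool = False


def latlon_to_xy(
    lat_rad: np.ndarray, lon_rad: np.ndarray, params: ProjectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Project latitude/longitude (radians) to local planar km coordinates."""
    lat_rad = np.asarray(lat_rad, dtype=float)
    lon_rad = np.asarray(lon_rad, dtype=float)
    if np.any(np.abs(lat_rad) > math.pi / 2 + 1e-12):
        raise ValueError("latitude outside [-pi/2, pi/2]")
    x = params.earth_radius_km * lon_rad * math.cos(params.ref_lat_rad)
    y = params.earth_radius_km * lat_rad
    return x, y


def _wrap(angle: np.ndarray) -> np.ndarray:
    return (angle + math.pi) % (2 * math.pi) - math.pi


def heading_change(x: np.ndarray, y: np.ndarray, mode: str = "heading") -> np.ndarray:
    """Per-sample directional-change magnitude of a planar path.

    Step direction i is taken between samples i and i+1; the change at sample
    i (for i in 1..n-2) is the wrapped difference between directions i and
    i-1.  Endpoints have no defined change and are set to 0.  In ``slope``
    mode, samples adjacent to a zero-dx step are returned as NaN (undefined
    gradient) so callers can discard them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    out = np.zeros(n)
    if n < 3:
        return out
    dx = np.diff(x)
    dy = np.diff(y)
    if mode == "heading":
        ang = np.arctan2(dy, dx)
        out[1:-1] = np.abs(_wrap(ang[1:] - ang[:-1]))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.arctan(dy / dx)
        bad = dx == 0
        out[1:-1] = np.abs(_wrap(slope[1:] - slope[:-1]))
        undef = np.zeros(n, dtype=bool)
        undef[1:-1] = bad[1:] | bad[:-1]
        out[undef] = np.nan
    return out


def merge_adjacent_peaks(candidates: list[int] | np.ndarray,
                         adjacency_gap: int = 2) -> list[int]:
    """Collapse runs of nearby candidate indices to their (lower) median.

    Candidates whose successive spacing is <= ``adjacency_gap`` belong to the
    same maneuver; each run is replaced by its median index, taking the lower
    median for even-length runs.
    """
    cand = sorted(int(c) for c in candidates)
    if not cand:
        return []
    runs: list[list[int]] = [[cand[0]]]
    for c in cand[1:]:
        if c - runs[-1][-1] <= adjacency_gap:
            runs[-1].append(c)
        else:
            runs.append([c])
    return [run[(len(run) - 1) // 2] for run in runs]


def detect_turn_peaks(
    xy_path: tuple[np.ndarray, np.ndarray],
    speed: np.ndarray,
    params: TurnDetectorParams | None = None,
) -> list[int]:
    """Detect turn-peak sample indices on a planar path.

    Candidates are samples whose heading (or slope-angle) change exceeds the
    gradient threshold; undefined-gradient samples (slope mode, dx = 0) and
    samples with speed <= ``min_speed`` are discarded; adjacent candidates are
    merged to their median index.  Paths shorter than 3 samples yield no peaks.
    """
    params = params or TurnDetectorParams()
    x, y = xy_path
    if len(x) < 3:
        return []
    change = heading_change(x, y, params.mode)
    speed = np.asarray(speed, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = (change > params.gradient_threshold_rad) & (speed > params.min_speed)
    mask &= ~np.isnan(change)
    return merge_adjacent_peaks(np.flatnonzero(mask), params.adjacency_gap)


def detect_trip_turns(trip: TripRecord, params: TurnDetectorParams | None = None) -> list[int]:
    """Detect turn peaks on a synchronized trip's GPS track."""
    params = params or TurnDetectorParams()
    if trip.merged_1hz is None:
        raise ValueError("trip must be synchronized first")
    lat = np.radians(trip.merged_1hz["lat"].to_numpy())
    lon = np.radians(trip.merged_1hz["lon"].to_numpy())
    proj = ProjectionParams(ref_lat_rad=float(np.mean(lat)))
    xy = latlon_to_xy(lat, lon, proj)
    speed = trip.merged_1hz["speed"].to_numpy()
    return detect_turn_peaks(xy, speed, params)


def extract_turn_window(
    trip: TripRecord, peak: int, params: TurnDetectorParams | None = None
) -> TurnSegment:
    """Cut the +/- half-window rows of the 10-channel matrix around a peak.

    Windows truncated by the trip boundary are linearly interpolated over
    normalized time back to the standard length (endpoints preserved).
    """
    params = params or TurnDetectorParams()
    feats = build_channel_set(trip)
    n = feats.shape[0]
    if n < 2:
        raise ValueError("trip too short")
    if not 0 <= peak < n:
        raise ValueError(f"peak {peak} outside trip of {n} rows")
    a = max(0, peak - params.half_window_s)
    b = min(n, peak + params.half_window_s + 1)
    window = feats[a:b]
    truncated = window.shape[0] < params.window_len
    if truncated:
        window = interpolate_to_length(window, params.window_len)
    assert window.shape == (params.window_len, N_CHANNELS)
    return TurnSegment(trip.participant_id, trip.trip_id, int(peak), window, truncated)


def extract_trip_turns(
    trip: TripRecord, params: TurnDetectorParams | None = None
) -> list[TurnSegment]:
    """Detect and window all turning maneuvers of one synchronized trip."""
    params = params or TurnDetectorParams()
    return [extract_turn_window(trip, p, params) for p in detect_trip_turns(trip, params)]
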