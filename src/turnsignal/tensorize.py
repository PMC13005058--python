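"""Fixed-length interpolation and N x C x L tensor assembly.

Trips and turn sequences vary widely in duration, so every sequence is
resampled by per-channel linear interpolation over normalized time onto a
fixed grid: L1 = 1200 points for full trips (and for the early-fusion turn
branch), 31 points per turn window, and L2 = 310 by default for the
late-fusion concatenated-turn branch.  Four tensor modes exist: ``trip``
(N x 10 x 1200), ``turn`` (per-turn N x 10 x 31 or per-trip concatenated),
``early_fusion`` (N x 20 x 1200, trip channels stacked over turn channels),
and a late-fusion pair of aligned 10-channel tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRIP_LENGTH = 1200  # L1
TURN_WINDOW = 31
TURN_CONCAT_LENGTH = 310  # L2: ten native-resolution turn windows


def interpolate_to_length(series: np.ndarray, length: int) -> np.ndarray:
    """Resample a T x C matrix to ``length`` rows by per-channel linear
    interpolation over normalized time [0, 1].

    First and last rows are preserved exactly; when T equals ``length`` the
    input is returned unchanged (a copy is not made).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    T = series.shape[0]
    if T < 2:
        raise ValueError("need at least 2 samples to interpolate")
    if length < 2:
        raise ValueError("target length must be >= 2")
    if T == length:
        return series
    x = np.linspace(0.0, 1.0, T)
    xq = np.linspace(0.0, 1.0, length)
    return np.column_stack([np.interp(xq, x, series[:, c]) for c in range(series.shape[1])])


@dataclass
class SeriesTensor:
    """N x C x L array of interpolated sequences with aligned metadata.

    ``labels`` is binary (healthy = 0, MCI = 1); ``participant_ids`` and
    ``trip_ids`` align row-wise with ``data``.  ``mask`` (turn-derived modes)
    marks rows whose turn block is real rather than zero-padded.
    """

    data: np.ndarray
    labels: np.ndarray
    participant_ids: np.ndarray
    trip_ids: np.ndarray
    mode: str
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be N x C x L")
        n = self.data.shape[0]
        for name in ("labels", "participant_ids", "trip_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} not aligned with data rows")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def subset(self, rows: np.ndarray) -> "SeriesTensor":
        return SeriesTensor(
            self.data[rows], self.labels[rows], self.participant_ids[rows],
            self.trip_ids[rows], self.mode,
            None if self.mask is None else self.mask[rows], dict(self.meta),
        )


def _labels_for(pids: list[str], label_map: dict[str, str]) -> np.ndarray:
    return np.array([1 if label_map[p] == "mci" else 0 for p in pids], dtype=np.int64)


def build_trip_tensor(
    channel_matrices: list[np.ndarray],
    participant_ids: list[str],
    trip_ids: list[str],
    label_map: dict[str, str],
    length: int = TRIP_LENGTH,
) -> SeriesTensor:
    """Stack per-trip S x 10 channel matrices into an N x 10 x L tensor."""
    if not channel_matrices:
        data = np.zeros((0, 10, length))
    else:
        data = np.stack([interpolate_to_length(m, length).T for m in channel_matrices])
    return SeriesTensor(
        data, _labels_for(participant_ids, label_map),
        np.asarray(participant_ids, dtype=object), np.asarray(trip_ids, dtype=object),
        mode="trip",
    )


def build_turn_tensor(
    turns_by_trip: dict[tuple[str, str], list[np.ndarray]],
    label_map: dict[str, str],
    granularity: str = "per_trip_concat",
    length: int | None = None,
    zero_turn_policy: str = "zero_pad",
) -> SeriesTensor:
    """Assemble the turn-view tensor.

    ``per_turn`` emits one row per turn window (N_turns x 10 x 31);
    ``per_trip_concat`` concatenates each trip's windows in temporal order and
    interpolates to ``length`` (default L2 = 310).  Trips with zero turns are
    zero-padded with ``mask`` False (policy ``zero_pad``) or dropped
    (``exclude``).
    """
    if granularity not in ("per_turn", "per_trip_concat"):
        raise ValueError("granularity must be per_turn or per_trip_concat")
    if zero_turn_policy not in ("zero_pad", "exclude"):
        raise ValueError("zero_turn_policy must be zero_pad or exclude")

    rows, pids, tids, mask = [], [], [], []
    if granularity == "per_turn":
        length = length or TURN_WINDOW
        for (pid, tid), windows in turns_by_trip.items():
            for w in windows:
                rows.append(interpolate_to_length(w, length).T)
                pids.append(pid)
                tids.append(tid)
                mask.append(True)
    else:
        length = length or TURN_CONCAT_LENGTH
        for (pid, tid), windows in turns_by_trip.items():
            if windows:
                concat = np.vstack(windows)
                rows.append(interpolate_to_length(concat, length).T)
                mask.append(True)
            elif zero_turn_policy == "zero_pad":
                rows.append(np.zeros((10, length)))
                mask.append(False)
            else:
                continue
            pids.append(pid)
            tids.append(tid)
    data = np.stack(rows) if rows else np.zeros((0, 10, length))
    return SeriesTensor(
        data, _labels_for(pids, label_map),
        np.asarray(pids, dtype=object), np.asarray(tids, dtype=object),
        mode="turn", mask=np.asarray(mask, dtype=bool),
        meta={"granularity": granularity},
    )


def build_fused_tensor(trip_tensor: SeriesTensor, turn_tensor: SeriesTensor) -> SeriesTensor:
    """Concatenate trip and turn tensors along the channel axis (early fusion).

    Rows must align by (participant, trip) and the two tensors must share L;
    output channels 0-9 are the trip view, 10-19 the turn view.
    """
    if trip_tensor.n != turn_tensor.n:
        raise ValueError("tensor row counts differ")
    for i in range(trip_tensor.n):
        if (trip_tensor.participant_ids[i], trip_tensor.trip_ids[i]) != (
            turn_tensor.participant_ids[i], turn_tensor.trip_ids[i]
        ):
            raise ValueError(
                f"row {i} misaligned: trip view ({trip_tensor.participant_ids[i]}, "
                f"{trip_tensor.trip_ids[i]}) vs turn view "
                f"({turn_tensor.participant_ids[i]}, {turn_tensor.trip_ids[i]})"
            )
    if trip_tensor.data.shape[2] != turn_tensor.data.shape[2]:
        raise ValueError("early fusion requires equal sequence lengths")
    data = np.concatenate([trip_tensor.data, turn_tensor.data], axis=1)
    return SeriesTensor(
        data, trip_tensor.labels.copy(), trip_tensor.participant_ids.copy(),
        trip_tensor.trip_ids.copy(), mode="early_fusion", mask=turn_tensor.mask,
    )


def save_tensor(tensor: SeriesTensor, path) -> None:
    """Persist a tensor (npz container + aligned metadata arrays)."""
    np.savez_compressed(
        path, data=tensor.data, labels=tensor.labels,
        participant_ids=np.asarray(tensor.participant_ids, dtype=str),
        trip_ids=np.asarray(tensor.trip_ids, dtype=str),
        mode=np.asarray(tensor.mode),
        mask=np.zeros(0) if tensor.mask is None else tensor.mask,
    )


def load_tensor(path) -> SeriesTensor:
    z = np.load(path, allow_pickle=False)
    mask = z["mask"]
    return SeriesTensor(
        z["data"], z["labels"],
        z["participant_ids"].astype(object), z["trip_ids"].astype(object),
        str(z["mode"]), None if mask.size == 0 else mask.astype(bool),
    )
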