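"""End-to-end dataset assembly: cohort -> cleaned trips -> tensors.

Glue between the pipeline stages: runs cleaning, turn extraction and feature
construction over a cohort (in memory or a CSV tree) and assembles the tensor
views every experiment consumes — the full-trip view, the concatenated-turn
view (at the trip length for early fusion, at its own shorter length for late
fusion), the early-fusion stack, and the static 14-feature baseline table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import RawCohort, read_csv_tree
from .features import STATIC_FEATURE_NAMES, build_channel_set, static_features
from .preprocess import Exclusion, TripRecord, clean_cohort
from .tensorize import (
    SeriesTensor, TRIP_LENGTH, TURN_CONCAT_LENGTH, build_fused_tensor,
    build_trip_tensor, build_turn_tensor,
)
from .turns import TurnDetectorParams, extract_trip_turns


@dataclass
class DrivingDatasets:
    """All tensor views of one cleaned cohort, row-aligned by (participant, trip)."""

    trip: SeriesTensor
    turn_concat_l1: SeriesTensor  # turn branch interpolated to the trip length
    turn_concat_l2: SeriesTensor  # turn branch at its native shorter length
    fused: SeriesTensor  # early fusion, 20 channels
    static: pd.DataFrame  # 14-feature baseline table + participant/trip/label
    trips: list[TripRecord] = field(default_factory=list)
    exclusions: list[Exclusion] = field(default_factory=list)

    @property
    def label_map(self) -> dict[str, int]:
        return {
            str(p): int(l)
            for p, l in zip(self.trip.participant_ids, self.trip.labels)
        }


def build_datasets(
    cohort: RawCohort | str,
    detector: TurnDetectorParams | None = None,
    l1: int = TRIP_LENGTH,
    l2: int = TURN_CONCAT_LENGTH,
    zero_turn_policy: str = "zero_pad",
) -> DrivingDatasets:
    """Clean a cohort and build every tensor view the experiments use."""
    detector = detector or TurnDetectorParams()
    raw = cohort if isinstance(cohort, RawCohort) else read_csv_tree(cohort)
    label_map = raw.labels() if isinstance(raw, RawCohort) else {}
    trips, exclusions, _ = clean_cohort(raw)

    matrices, pids, tids, static_rows = [], [], [], []
    turns_by_trip: dict[tuple[str, str], list[np.ndarray]] = {}
    for t in trips:
        matrices.append(build_channel_set(t))
        pids.append(t.participant_id)
        tids.append(t.trip_id)
        turns_by_trip[(t.participant_id, t.trip_id)] = [
            seg.window for seg in extract_trip_turns(t, detector)
        ]
        static_rows.append({
            "participant_id": t.participant_id, "trip_id": t.trip_id,
            "label": 1 if label_map.get(t.participant_id) == "mci" else 0,
            **dict(zip(STATIC_FEATURE_NAMES, static_features(t))),
        })

    trip_tensor = build_trip_tensor(matrices, pids, tids, label_map, length=l1)
    turn_l1 = build_turn_tensor(turns_by_trip, label_map, "per_trip_concat",
                                length=l1, zero_turn_policy=zero_turn_policy)
    turn_l2 = build_turn_tensor(turns_by_trip, label_map, "per_trip_concat",
                                length=l2, zero_turn_policy=zero_turn_policy)
    fused = build_fused_tensor(trip_tensor, turn_l1)
    static = pd.DataFrame(
        static_rows,
        columns=["participant_id", "trip_id", "label", *STATIC_FEATURE_NAMES],
    )
    return DrivingDatasets(trip_tensor, turn_l1, turn_l2, fused, static,
                           trips, exclusions)


def dataset_for_experiment(ds: DrivingDatasets, experiment: str):
    """Map an experiment code to its model input.

    1a: full-trip single view; 1b: concatenated-turn single view; 2: early
    fusion (20 channels); 3: late-fusion pair (trip, turn at L2).
    """
    return {
        "1a": ds.trip,
        "1b": ds.turn_concat_l2,
        "2": ds.fused,
        "3": (ds.trip, ds.turn_concat_l2),
    }[experiment]


def random_forest_baseline(
    static: pd.DataFrame, folds, seed: int = 0, threshold: float = 0.5
):
    """Cross-validated random-forest benchmark on the 14 static features."""
    from sklearn.ensemble import RandomForestClassifier

    from .training import FoldResult, _mean_reports, metrics_from_probabilities

    X = static[STATIC_FEATURE_NAMES].to_numpy(float)
    y = static["label"].to_numpy(int)
    pids = static["participant_id"].to_numpy(object)
    results = []
    for i, (train_p, test_p) in enumerate(folds):
        tr = np.flatnonzero(np.isin(pids, list(train_p)))
        te = np.flatnonzero(np.isin(pids, list(test_p)))
        if len(tr) == 0 or len(te) == 0:
            continue
        rf = RandomForestClassifier(n_estimators=200, random_state=seed + i)
        rf.fit(X[tr], y[tr])
        p = rf.predict_proba(X[te])
        p_pos = p[:, 1] if p.shape[1] == 2 else np.zeros(len(te))
        report = metrics_from_probabilities(y[te], p_pos, threshold)
        results.append(FoldResult(i, report, set(test_p), p_pos, y[te],
                                  pids[te], static["trip_id"].to_numpy(object)[te]))
    return _mean_reports([r.report for r in results]), results
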