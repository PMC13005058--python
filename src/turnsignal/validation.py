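"""Validation utilities: oracle cross-checks and screening demonstrations.

These helpers quantify agreement between pipeline stages and independent
brute-force references: the turn detector versus an exhaustive
heading-difference scan over planted route corners, class exchangeability of
the generator under the null, and the sporadic-impairment screening
demonstration in which the low-threshold risk flag is compared against
majority voting on per-trip classifications.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, RawCohort, generate_cohort
from .preprocess import clean_cohort
from .risk import majority_vote, risk_score
from .turns import TurnDetectorParams, detect_trip_turns


#: scaled-down demonstration conditions for the effect-recovery studies:
#: a 19-driver cohort (12 healthy + 7 MCI) with a handful of short trips per
#: driver, and a shortened cosine-annealed training schedule whose optimizer
#: step count approximates the full-scale configuration at this cohort size.
DEMO_COHORT = dict(
    trips_per_participant=(3, 5),
    trip_duration_s=(120, 240),
    turn_count_per_trip=(4, 8),
)
DEMO_TRAIN = dict(epochs=20, batch_size=8, lr=3e-3, normalize=True)


def trip_auc_across_seeds(
    effect_size: float,
    impaired_trip_fraction: float = 1.0,
    n_seeds: int = 5,
    base_seed: int = 0,
    k: int = 7,
    model_family: str = "tiny_fcn",
) -> dict:
    """Cross-validated trip-mode AUC of the reference model over seeds.

    Generates a fresh cohort per seed under the demonstration conditions with
    the requested impairment effect, runs participant-stratified k-fold CV of
    the reference classifier, and returns per-seed AUCs plus their median.
    With ``effect_size`` well above 1 the AUC measures parameter recovery;
    with ``effect_size = 1`` it calibrates the null.
    """
    from .model import DrivingClassifier
    from .nn import ModelSpec
    from .pipeline import build_datasets
    from .training import TrainConfig

    aucs = []
    for s in range(n_seeds):
        cfg = CohortConfig(effect_size=effect_size,
                           impaired_trip_fraction=impaired_trip_fraction,
                           seed=base_seed + 10 * s + 1, **DEMO_COHORT)
        ds = build_datasets(generate_cohort(cfg))
        clf = DrivingClassifier(ds.trip, ModelSpec(model_family),
                                TrainConfig(**DEMO_TRAIN))
        res = clf.fit(k=k, seed=base_seed + 10 * s + 1)
        aucs.append(res.mean_report.auc)
    return {"aucs": aucs, "median_auc": float(np.median(aucs)), "n_seeds": n_seeds}


def brute_force_corners(x: np.ndarray, y: np.ndarray, threshold_rad: float) -> list[int]:
    """Exhaustive scan of successive-heading differences.

    Independent reference for the turn detector: computes every heading change
    directly, groups contiguous above-threshold samples, and returns each
    group's central index.
    """
    n = len(x)
    if n < 3:
        return []
    ang = np.arctan2(np.diff(y), np.diff(x))
    d = np.abs((np.diff(ang) + np.pi) % (2 * np.pi) - np.pi)
    above = np.flatnonzero(d > threshold_rad) + 1  # change at sample i+1
    groups: list[list[int]] = []
    for i in above:
        if groups and i - groups[-1][-1] <= 2:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])
    return [g[(len(g) - 1) // 2] for g in groups]


def detector_agreement(
    cohort: RawCohort,
    params: TurnDetectorParams | None = None,
    tol: int = 3,
) -> dict:
    """Precision/recall of detected turn peaks against planted route corners.

    Cleans the cohort, runs the detector per trip, and matches each detected
    peak to the nearest planted corner (from the generator's ground truth)
    within ``tol`` merged-grid samples.  Corner positions are translated from
    trip-relative GPS indices to merged-row indices via the timestamp column.
    """
    params = params or TurnDetectorParams()
    trips, _, _ = clean_cohort(cohort)
    n_det = n_true = n_matched_det = n_matched_true = 0
    for t in trips:
        info = cohort.ground_truth.get(t.participant_id)
        if info is None:
            continue
        idx = int(t.trip_id) - 1
        if idx >= len(info):
            continue
        ts = t.merged_1hz["timestamp"].to_numpy()
        t0 = ts[0]
        truth = []
        for c in info[idx]["corners"]:
            rows = np.flatnonzero(np.abs(ts - (t0 + c)) < 0.5)
            if rows.size:
                truth.append(int(rows[0]))
        peaks = detect_trip_turns(t, params)
        n_det += len(peaks)
        n_true += len(truth)
        for p in peaks:
            if truth and min(abs(p - c) for c in truth) <= tol:
                n_matched_det += 1
        for c in truth:
            if peaks and min(abs(p - c) for p in peaks) <= tol:
                n_matched_true += 1
    return {
        "n_detected": n_det,
        "n_planted": n_true,
        "precision": n_matched_det / n_det if n_det else float("nan"),
        "recall": n_matched_true / n_true if n_true else float("nan"),
    }


def noisy_oracle_trip_flags(
    cohort: RawCohort,
    sensitivity: float = 0.9,
    false_positive_rate: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trip impairment flags from a stylized trip classifier.

    Each genuinely impaired trip is flagged with probability ``sensitivity``
    and each unimpaired trip with probability ``false_positive_rate``.  This
    isolates the risk-aggregation layer from any particular model: it asks
    what participant-level screening achieves given a trip classifier of
    stated quality.  Returns (flags, participant_ids) over all generated
    trips.
    """
    rng = np.random.default_rng(seed)
    flags, pids = [], []
    for pid, info in cohort.ground_truth.items():
        for trip in info:
            p = sensitivity if trip["impaired"] else false_positive_rate
            flags.append(int(rng.random() < p))
            pids.append(pid)
    return np.asarray(flags), np.asarray(pids, dtype=object)


def sporadic_screening_comparison(
    impaired_trip_fraction: float = 0.3,
    flag_threshold: float = 0.1,
    n_seeds: int = 10,
    base_seed: int = 0,
    cohort_kwargs: dict | None = None,
) -> dict:
    """Compare risk-threshold flagging with majority voting on MCI drivers.

    For each seed, generates a sporadic cohort (each MCI trip expresses the
    impairment signature with probability ``impaired_trip_fraction``), derives
    trip flags from the stylized classifier, and counts how many true MCI
    participants each aggregation rule detects.
    """
    kw = dict(trips_per_participant=(8, 15), trip_duration_s=(60, 120),
              turn_count_per_trip=(2, 4))
    kw.update(cohort_kwargs or {})
    risk_hits = vote_hits = n_mci_total = 0
    for s in range(n_seeds):
        cfg = CohortConfig(impaired_trip_fraction=impaired_trip_fraction,
                           seed=base_seed + 1000 + s, **kw)
        cohort = generate_cohort(cfg)
        flags, pids = noisy_oracle_trip_flags(cohort, seed=base_seed + 2000 + s)
        report = risk_score(flags, pids, thresholds=(flag_threshold, 0.5))
        votes = majority_vote(report)
        mci = {p.participant_id for p in cohort.participants if p.label == "mci"}
        n_mci_total += len(mci)
        for part in report:
            if part.participant_id in mci:
                risk_hits += int(part.flags[flag_threshold])
                vote_hits += int(votes[part.participant_id])
    return {
        "n_seeds": n_seeds,
        "n_mci_total": n_mci_total,
        "risk_threshold_detected": risk_hits,
        "majority_vote_detected": vote_hits,
    }
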