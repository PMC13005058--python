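"""Participant-level risk scoring from trip-level predictions.

MCI is episodic: an affected driver may look impaired on only a minority of
trips, so collapsing trip predictions by majority vote can mask the signal.
The frequency-based risk score instead reports, per participant, the
proportion of their trips flagged impaired — a continuous value in [0, 1] that
clinicians can threshold to taste (a 10% cutoff prioritizes sensitivity for
screening; 50% prioritizes precision).  Majority vote is retained as the
comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (0.1, 0.5)


@dataclass
class ParticipantRisk:
    participant_id: str
    n_trips: int
    n_flagged: int
    risk_score: float  # n_flagged / n_trips
    trip_accuracy: float | None  # fraction of trips predicted consistently with the label
    flags: dict[float, bool]


@dataclass
class RiskReport:
    participants: list[ParticipantRisk]
    thresholds: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            row = {
                "participant_id": p.participant_id, "n_trips": p.n_trips,
                "n_flagged": p.n_flagged, "risk_score": p.risk_score,
                "trip_accuracy": p.trip_accuracy,
            }
            for t in self.thresholds:
                row[f"flag_{t:g}"] = p.flags[t]
            rows.append(row)
        return pd.DataFrame(rows)

    def __iter__(self):
        return iter(self.participants)


def risk_score(
    trip_predictions: np.ndarray,
    participant_ids: np.ndarray,
    labels: dict[str, int] | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> RiskReport:
    """Per-participant proportion of trips flagged impaired, with flags.

    ``trip_predictions`` are binary (1 = impaired); ``labels`` (participant ->
    0/1) enable the per-participant trip accuracy of the classifier.
    Participants with zero trips are omitted with a warning.
    """
    preds = np.asarray(trip_predictions, dtype=np.int64)
    pids = np.asarray(participant_ids)
    if preds.shape != pids.shape:
        raise ValueError("predictions and participant ids must align")
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError("thresholds must be in (0, 1]")
    out: list[ParticipantRisk] = []
    for pid in sorted(set(pids.tolist())):
        mask = pids == pid
        n = int(mask.sum())
        if n == 0:  # pragma: no cover - unreachable by construction
            continue
        flagged = int(preds[mask].sum())
        risk = flagged / n
        acc = None
        if labels is not None and pid in labels:
            acc = float((preds[mask] == labels[pid]).mean())
        out.append(ParticipantRisk(
            participant_id=str(pid), n_trips=n, n_flagged=flagged,
            risk_score=risk, trip_accuracy=acc,
            flags={t: risk >= t for t in thresholds},
        ))
    return RiskReport(out, tuple(thresholds))


def apply_thresholds(report: RiskReport, thresholds: tuple[float, ...]) -> RiskReport:
    """Re-flag a report at a new threshold set (risk >= threshold)."""
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError("thresholds must be in (0, 1]")
    parts = [
        ParticipantRisk(
            p.participant_id, p.n_trips, p.n_flagged, p.risk_score, p.trip_accuracy,
            {t: p.risk_score >= t for t in thresholds},
        )
        for p in report.participants
    ]
    return RiskReport(parts, tuple(thresholds))


def majority_vote(report: RiskReport) -> dict[str, int]:
    """Binary per-participant label: impaired iff risk > 0.5.

    Exact 0.5 ties break to impaired (sensitivity-first), which makes majority
    vote identical to thresholding the risk score at 0.5.
    """
    return {p.participant_id: int(p.risk_score >= 0.5) for p in report.participants}


def plot_participant_accuracy(report: RiskReport, true_labels: dict[str, int],
                              ax=None):
    """Bar chart of per-participant trip accuracy, colored by diagnosis.

    Green bars are cognitively healthy drivers, red bars MCI; requires that
    the report was built with participant labels.  Returns the axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    parts = [p for p in report.participants if p.trip_accuracy is not None]
    xs = np.arange(len(parts))
    accs = [100 * p.trip_accuracy for p in parts]
    colors = ["tab:red" if true_labels.get(p.participant_id) else "tab:green"
              for p in parts]
    ax.bar(xs, accs, color=colors)
    ax.set_xticks(xs, [p.participant_id for p in parts], rotation=90, fontsize=7)
    ax.set_ylabel("trip classification accuracy (%)")
    ax.set_ylim(0, 100)
    return ax


def threshold_curve(
    report: RiskReport,
    true_labels: dict[str, int],
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity of the risk-threshold flag over a grid.

    Requires at least one participant per class; sensitivity is monotone
    non-increasing in the threshold.
    """
    grid = np.linspace(0.0, 1.0, 101) if grid is None else np.asarray(grid, float)
    y = np.array([true_labels[p.participant_id] for p in report.participants])
    r = np.array([p.risk_score for p in report.participants])
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold curve needs both classes")
    rows = []
    for t in grid:
        flag = r >= t
        rows.append({
            "threshold": float(t),
            "sensitivity": float(flag[y == 1].mean()),
            "specificity": float((~flag[y == 0]).mean()),
        })
    return pd.DataFrame(rows)
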