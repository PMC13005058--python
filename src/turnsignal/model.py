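"""High-level modelling API: a model object fitted by cross-validation.

:class:`DrivingClassifier` binds a tensor view (or a late-fusion pair) to an
architecture spec and a training configuration; :meth:`DrivingClassifier.fit`
runs participant-stratified k-fold cross-validation and returns a
:class:`CrossValidationResults` object carrying per-fold metrics, pooled
trip-level predictions, a text ``summary()``, and the participant-level risk
report derived from the held-out predictions.

    >>> ds = build_datasets(generate_cohort(CohortConfig(seed=1)))
    >>> model = DrivingClassifier(ds.trip, ModelSpec("tiny_fcn"),
    ...                           TrainConfig(epochs=20))
    >>> res = model.fit(k=7, seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nn import ModelSpec
from .risk import DEFAULT_THRESHOLDS, RiskReport, risk_score
from .tensorize import SeriesTensor
from .training import (
    FoldResult, MetricsReport, TrainConfig, cross_validate, make_folds,
)


class DrivingClassifier:
    """Trip/turn classifier over a :class:`SeriesTensor`, fitted by CV.

    Parameters
    ----------
    tensor:
        A tensor view, or an aligned ``(trip, turn)`` pair for late-fusion
        dual-encoder models (the spec's ``dual`` flag is set automatically).
    spec:
        Architecture description; defaults to the TinyFCN reference model.
    train_config:
        Optimization settings (AdamW, cosine schedule, weighted CE).
    """

    def __init__(
        self,
        tensor: SeriesTensor | tuple[SeriesTensor, SeriesTensor],
        spec: ModelSpec | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.tensor = tensor
        pair = isinstance(tensor, tuple)
        primary = tensor[0] if pair else tensor
        spec = spec or ModelSpec()
        if pair and not spec.dual:
            spec = replace(spec, dual=True)
        if not pair:
            spec = replace(spec, in_channels=primary.data.shape[1])
        self.spec = spec
        self.train_config = train_config or TrainConfig()
        self._primary = primary

    @classmethod
    def from_datasets(cls, datasets, experiment: str = "1a",
                      spec: ModelSpec | None = None,
                      train_config: TrainConfig | None = None) -> "DrivingClassifier":
        from .pipeline import dataset_for_experiment

        return cls(dataset_for_experiment(datasets, experiment), spec, train_config)

    def fit(self, k: int = 7, seed: int = 0, threshold: float = 0.5
            ) -> "CrossValidationResults":
        """Cross-validate over participant-stratified folds."""
        primary = self._primary
        pids = sorted(set(primary.participant_ids.tolist()))
        lab = {p: int(primary.labels[primary.participant_ids == p][0]) for p in pids}
        folds = make_folds(pids, {p: "mci" if v else "healthy" for p, v in lab.items()},
                           k=k, seed=seed)
        cfg = replace(self.train_config, seed=seed)
        mean_report, fold_results = cross_validate(
            self.spec, self.tensor, cfg, folds, threshold=threshold
        )
        return CrossValidationResults(self, mean_report, fold_results, lab,
                                      k=k, seed=seed, threshold=threshold)


@dataclass
class CrossValidationResults:
    """Cross-validated estimates, diagnostics, and risk-report accessors."""

    model: DrivingClassifier
    mean_report: MetricsReport
    fold_results: list[FoldResult]
    participant_labels: dict[str, int]
    k: int
    seed: int
    threshold: float

    @property
    def metrics(self) -> pd.DataFrame:
        """Per-fold metric table (one row per fold, plus the mean)."""
        rows = [
            {"fold": r.fold, **r.report.as_dict(),
             "test_participants": ",".join(sorted(map(str, r.test_participants)))}
            for r in self.fold_results
        ]
        return pd.DataFrame(rows)

    def trip_predictions(self) -> pd.DataFrame:
        """Pooled held-out trip predictions across folds."""
        frames = [
            pd.DataFrame({
                "participant_id": r.participant_ids.astype(str),
                "trip_id": r.trip_ids.astype(str),
                "label": r.labels,
                "p_impaired": r.p_pos,
                "predicted": (r.p_pos >= self.threshold).astype(int),
                "fold": r.fold,
            })
            for r in self.fold_results
        ]
        return pd.concat(frames, ignore_index=True)

    def risk_report(self, thresholds=DEFAULT_THRESHOLDS,
                    use_probabilities: bool = False) -> RiskReport:
        """Frequency-based participant risk from the held-out predictions.

        By default each trip contributes its hard classification; with
        ``use_probabilities`` the per-trip impairment probabilities are
        averaged instead.
        """
        preds = self.trip_predictions()
        if use_probabilities:
            trip_flags = preds["p_impaired"].to_numpy()
        else:
            trip_flags = preds["predicted"].to_numpy()
        return risk_score(
            np.round(trip_flags).astype(int) if use_probabilities else trip_flags,
            preds["participant_id"].to_numpy(object),
            labels=self.participant_labels, thresholds=thresholds,
        )

    def summary(self) -> str:
        d = self.mean_report.as_dict()
        spec = self.model.spec
        cfg = self.model.train_config
        lines = [
            "Cross-validated driving-biomarker classifier",
            "=" * 52,
            f"model family:     {spec.family}"
            + (f" (dual, {spec.fusion} fusion)" if spec.dual else "")
            + (f" + {spec.attention} attention" if spec.attention != "none" else ""),
            f"input:            C={spec.in_channels}, L={spec.seq_len}"
            if not spec.dual else "input:            dual trip/turn branches",
            f"folds:            {len(self.fold_results)} (participant-stratified, k={self.k})",
            f"epochs/batch/lr:  {cfg.epochs}/{cfg.batch_size}/{cfg.lr:g}",
            f"normalize={cfg.normalize}  class_weights={cfg.class_weights}  seed={self.seed}",
            "-" * 52,
        ]
        for name in ("accuracy", "balanced_accuracy", "auc", "precision", "recall", "f1"):
            v = d[name]
            lines.append(f"{name:<18} {v:.3f}" if v is not None else f"{name:<18} n/a")
        lines.append("-" * 52)
        lines.append(
            f"confusion (pooled): TP={d['tp']} FP={d['fp']} TN={d['tn']} FN={d['fn']}"
        )
        return "\n".join(lines)
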