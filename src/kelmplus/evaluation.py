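"""Repeated stratified cross-validation, binary metrics and frequency reports.

The protocol is five-fold stratified CV repeated five times (25 fold-level
results). Inside every training fold the full pipeline is refitted: feature
selection, empirical kernel maps, KELM+ members. Metrics are accuracy,
sensitivity, specificity, Youden index, positive/negative predictive value
and F1, aggregated as mean +/- sample SD over folds; denominator-free
(undefined) metrics are excluded from aggregation rather than coerced to
zero. The positive class is the higher blood-pressure grade. Per-fold
feature selections accumulate into a Table-style frequency ledger whose
maximum attainable count is n_folds x n_repeats.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .ensemble import EnsembleConfig, EnsembleModel, _selected, _spec_for, \
    predict_ensemble, train_ensemble
from .errors import InvalidInputError
from .kelm import encode_labels, predict_kelm, train_kelm
from .selection import select_features, tally_frequency

METRIC_NAMES = ("acc", "sen", "spc", "yi", "ppv", "npv", "f1")


@dataclass(frozen=True)
class MetricSet:
    """The seven binary classification metrics, NaN where undefined."""

    acc: float
    sen: float
    spc: float
    yi: float
    ppv: float
    npv: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion_metrics(y_true, y_pred, positive_class) -> MetricSet:
    """Compute the metric set from labels, with NaN for zero denominators."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise InvalidInputError("empty label sequence")
    if len(y_true) != len(y_pred):
        raise InvalidInputError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    pos_t, pos_p = y_true == positive_class, y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    return metrics_from_counts(tp, fp, tn, fn)


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> MetricSet:
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sen = ratio(tp, tp + fn)
    spc = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    acc = ratio(tp + tn, tp + fp + tn + fn)
    yi = sen + spc - 1.0
    f1 = 2 * ppv * sen / (ppv + sen) if np.isfinite(ppv + sen) and (ppv + sen) > 0 else float("nan")
    return MetricSet(acc, sen, spc, yi, ppv, npv, f1)


@dataclass
class EvaluationReport:
    """Per-fold metrics plus aggregates and the selection-frequency ledger."""

    fold_metrics: list[MetricSet]
    baseline_metrics: list[MetricSet]
    mean: dict[str, float]
    std: dict[str, float]
    baseline_mean: dict[str, float]
    frequency: dict[str, dict[str, int]]  # feature type -> name -> count
    n_folds: int
    n_repeats: int
    seed: int
    positive_class: object
    config: EnsembleConfig | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "positive_class": str(self.positive_class),
            "n_folds": self.n_folds, "n_repeats": self.n_repeats, "seed": self.seed,
            "mean_pct": {k: 100 * v for k, v in self.mean.items()},
            "std_pct": {k: 100 * v for k, v in self.std.items()},
            "baseline_mean_pct": {k: 100 * v for k, v in self.baseline_mean.items()},
            "folds": [m.as_dict() for m in self.fold_metrics],
            "frequency": self.frequency,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def aggregate(metric_sets: list[MetricSet]) -> tuple[dict[str, float], dict[str, float]]:
    """Mean and sample SD per metric over folds, ignoring undefined values."""
    mean, std = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in metric_sets], dtype=float)
        vals = vals[np.isfinite(vals)]
        mean[name] = float(np.mean(vals)) if len(vals) else float("nan")
        std[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, std


def repeated_stratified_cv(tables: dict[str, np.ndarray], y, config: EnsembleConfig,
                           n_folds: int = 5, n_repeats: int = 5, seed: int = 0,
                           feature_names: dict[str, list[str]] | None = None,
                           baseline: bool = False) -> EvaluationReport:
    """Run the full evaluation protocol on row-aligned feature matrices.

    Everything (selection, EKM, tuning, KELM+ training) is refitted inside
    each training fold; the test fold is only ever transformed and scored.
    With ``baseline=True`` a plain KELM on the selected main feature
    (no EKM, no PI) is evaluated on the same folds for comparison.
    """
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise InvalidInputError(
            f"smallest class has {counts.min()} members; need >= n_folds ({n_folds})")
    positive_class = classes[-1]  # higher BP grade is the positive class
    fold_metrics: list[MetricSet] = []
    base_metrics: list[MetricSet] = []
    selections: dict[str, list] = {t: [] for t in tables}
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(next(iter(tables.values())), y):
            tr_tables = {t: np.asarray(M)[tr] for t, M in tables.items()}
            model = train_ensemble(tr_tables, y[tr], config)
            pred = predict_ensemble(model, np.asarray(tables[config.main])[te])
            fold_metrics.append(confusion_metrics(y[te], pred, positive_class))
            _record_selections(model, selections)
            if baseline:
                base_metrics.append(_kelm_baseline_fold(
                    tables[config.main], y, tr, te, classes, config, positive_class))
    mean, std = aggregate(fold_metrics)
    base_mean, _ = aggregate(base_metrics) if base_metrics else ({}, {})
    frequency = {}
    for t, sels in selections.items():
        if sels:
            names = feature_names.get(t) if feature_names else None
            counts_t = tally_frequency(sels, names=names)
            frequency[t] = {str(k): int(v) for k, v in counts_t.items()}
    return EvaluationReport(fold_metrics, base_metrics, mean, std, base_mean, frequency,
                            n_folds, n_repeats, seed, positive_class, config)


def _record_selections(model: EnsembleModel, selections: dict[str, list]) -> None:
    selections[model.config.main].append(model.selection_main)
    for pi, sel in model.selections_pi.items():
        selections[pi].append(sel)


def _kelm_baseline_fold(X, y, tr, te, classes, config: EnsembleConfig,
                        positive_class) -> MetricSet:
    """Plain KELM on the t-test+MI-selected main feature (no EKM, no PI).

    C is tuned by the same inner stratified CV the ensemble members use, so
    the comparison is like for like.
    """
    X = np.asarray(X)
    sel = select_features(X[tr], y[tr], config.alpha, config.k,
                          estimator=config.mi_estimator, seed=config.seed)
    X_tr, X_te = _selected(X[tr], sel), _selected(X[te], sel)
    C, gs = _tune_kelm(X_tr, y[tr], classes, config)
    model = train_kelm(X_tr, encode_labels(y[tr], classes), C,
                       _spec_for(config.kernel, X_tr, gs), classes=classes)
    _, pred = predict_kelm(model, X_te)
    return confusion_metrics(y[te], pred, positive_class)


def _tune_kelm(X_tr, y_tr, classes, config: EnsembleConfig) -> tuple[float, float]:
    grid = [(C, gs) for C in config.C_grid for gs in config.gamma_scale_grid]
    if len(grid) == 1:
        return grid[0]

    def inner_acc(cfg: tuple[float, float]) -> float:
        C, gs = cfg
        skf = StratifiedKFold(n_splits=config.tuning_folds, shuffle=True,
                              random_state=config.seed)
        accs = []
        for itr, ite in skf.split(X_tr, y_tr):
            m = train_kelm(X_tr[itr], encode_labels(y_tr[itr], classes), C,
                           _spec_for(config.kernel, X_tr[itr], gs), classes=classes)
            _, pred = predict_kelm(m, X_tr[ite])
            accs.append(float(np.mean(pred == y_tr[ite])))
        return float(np.mean(accs))

    return max(grid, key=inner_acc)


def discriminative_report(report: EvaluationReport, top_n: int = 10
                          ) -> dict[str, list[tuple[str, int]]]:
    """Top-n most frequently selected features per type, ties broken by name."""
    out = {}
    for t, counts in report.frequency.items():
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out[t] = ranked[:top_n]
    return out


def format_report(report: EvaluationReport, title: str = "") -> str:
    """Human-readable metrics table (mean +/- std, UNIT: %)."""
    lines = [title or "Evaluation report", f"positive class: {report.positive_class}",
             f"{report.n_repeats} repeats x {report.n_folds} folds  (mean +/- std, UNIT: %)"]
    for name in METRIC_NAMES:
        lines.append(f"  {name.upper():<4} {100 * report.mean[name]:6.2f} +/- "
                     f"{100 * report.std[name]:5.2f}")
    if report.baseline_mean:
        lines.append(f"  KELM baseline ACC {100 * report.baseline_mean['acc']:6.2f}")
    return "\n".join(lines)
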