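"""Supervised training and the cross-validation evaluation protocol.

Classifiers are trained with minibatch Adam on binary cross-entropy
(defaults: 500 epochs, batch size 100). Evaluation is stratified k-fold
cross-validation (default k=10): within each fold the autoencoder is
pre-trained on the fold's training portion, assembled into a classifier,
trained, and scored on the validation portion at its best epoch by F1.
Metrics follow the usual confusion-matrix definitions, reported as
percentages (accuracy, precision, recall, F1) except MCC in [-1, 1]; ROC and
precision-recall curves sweep every distinct predicted probability, with AUC
by the trapezoid rule. Zero-denominator cases (no predicted positives, a
one-class fold, ...) define the affected metric as 0 rather than erroring.

A held-out workflow splits off a stratified test fraction (default 0.33,
"one third"), cross-validates on the remainder, retrains one final model on
the whole training portion, and scores it once on the test set.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .assembly import AssemblySpec, ClassifierModel, assemble
from .autoencoders import AEConfig, AEParams, build_ae, pretrain
from .matrix import ExpressionMatrix
from .nn import Adam, bce_loss, minibatches
from .preprocessing import apply_imputer, fit_imputer

SCALAR_METRICS = ("loss", "accuracy", "mcc", "precision", "recall", "f1", "auc")


@dataclass
class TrainConfig:
    """Supervised-training and evaluation-protocol parameters."""

    epochs: int = 500
    batch_size: int = 100
    learning_rate: float = 1e-3
    folds: int = 10
    holdout_fraction: float = 0.33
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size positive")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")


@dataclass
class MetricReport:
    """One evaluation's metric suite. Rates are percentages; MCC in [-1, 1];
    ROC points run from (0,0) to (1,1)."""

    loss: float
    accuracy: float
    mcc: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)

    def scalars(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in SCALAR_METRICS}


@dataclass
class FoldResult:
    """Outcome of one cross-validation fold: the per-epoch validation
    history, the best-F1 epoch's full report, and that epoch's model."""

    fold_index: int
    history: list[dict[str, float]]
    best_epoch: int
    report: MetricReport
    model: ClassifierModel


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return tp, tn, fp, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy/precision/recall/F1 as percentages and MCC from raw counts."""
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom)
    return {"accuracy": 100.0 * (tp + tn) / n, "precision": 100.0 * precision,
            "recall": 100.0 * recall, "f1": 100.0 * f1, "mcc": float(mcc)}


def _scalar_report(y_true: np.ndarray, y_prob: np.ndarray,
                   threshold: float) -> dict[str, float]:
    loss, _ = bce_loss(y_prob.astype(float), y_true.astype(float))
    tp, tn, fp, fn = _confusion(y_true, (y_prob >= threshold).astype(int))
    out = confusion_metrics(tp, tn, fp, fn)
    out["loss"] = loss
    return out


def compute_metrics(y_true, y_prob, threshold: float = 0.5) -> MetricReport:
    """Full metric suite for one set of probabilistic predictions.

    Thresholded metrics call a sample positive when its probability is at
    least ``threshold``; curves sweep every distinct probability.
    """
    y_true = np.asarray(y_true).astype(int).ravel()
    y_prob = np.asarray(y_prob, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob lengths differ")
    if ((y_prob < 0) | (y_prob > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")

    scalars = _scalar_report(y_true, y_prob, threshold)

    if y_true.min() == y_true.max():  # one-class input: curves are undefined
        roc_pts, pr_pts, auc = [], [], 0.0
    else:
        fpr, tpr, _ = roc_curve(y_true, y_prob, drop_intermediate=False)
        auc = float(np.trapezoid(tpr, fpr))
        roc_pts = list(zip(fpr.tolist(), tpr.tolist()))
        prec, rec, _ = precision_recall_curve(y_true, y_prob)
        pr_pts = list(zip(rec.tolist(), prec.tolist()))
    return MetricReport(loss=scalars["loss"], accuracy=scalars["accuracy"],
                        mcc=scalars["mcc"], precision=scalars["precision"],
                        recall=scalars["recall"], f1=scalars["f1"], auc=auc,
                        roc_points=roc_pts, pr_points=pr_pts)


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint validation-index sets preserving class proportions; each
    fold's per-class count differs from the equal share by at most 1."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; needs >= k={k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    return [val for _, val in splitter.split(np.zeros(len(labels)), labels)]


def evaluate_model(model: ClassifierModel, X: np.ndarray, y: np.ndarray,
                   threshold: float = 0.5) -> MetricReport:
    """Score a classifier on labeled data (full metric suite)."""
    return compute_metrics(y, model.predict_proba(X), threshold)


def train_classifier(model: ClassifierModel, train_data: tuple[np.ndarray, np.ndarray],
                     val_data: tuple[np.ndarray, np.ndarray] | None,
                     config: TrainConfig, fold_index: int = 0) -> FoldResult:
    """Train with Adam on binary cross-entropy, honoring freeze flags.

    When validation data is given, every epoch is scored on it and the model
    snapshot with the highest validation F1 (earliest epoch on ties) is
    returned along with its full report. Without validation data the
    final-epoch model is returned, scored on the training data.
    """
    config.validate()
    X, y = (np.asarray(a, dtype=float) for a in train_data)
    y = y.ravel()
    if np.isnan(X).any():
        raise ValueError("training data contains missing cells; impute first")
    if np.unique(y).size < 2:
        raise ValueError("training fold contains a single class")

    rng = np.random.default_rng((config.seed + 917 * fold_index) % 2**31)
    optimizer = Adam(model.network.params(), lr=config.learning_rate)
    history: list[dict[str, float]] = []
    best_f1, best_epoch, best_net = -1.0, -1, None

    def validate_epoch(epoch: int) -> None:
        nonlocal best_f1, best_epoch, best_net
        if val_data is None:
            return
        scalars = _scalar_report(np.asarray(val_data[1]).astype(int).ravel(),
                                 model.predict_proba(val_data[0]), 0.5)
        history.append(scalars)
        if scalars["f1"] > best_f1:  # strict: ties keep the earlier epoch
            best_f1, best_epoch = scalars["f1"], epoch
            best_net = copy.deepcopy(model.network)

    if config.epochs == 0:
        validate_epoch(0)
    for epoch in range(config.epochs):
        for idx in minibatches(X.shape[0], config.batch_size, rng):
            prob = model.network.forward(X[idx], training=True).ravel()
            _, grad = bce_loss(prob, y[idx])
            model.network.backward(grad.reshape(-1, 1))
            optimizer.step()
        validate_epoch(epoch)

    if best_net is not None:
        model.network = best_net
    if val_data is not None:
        Xv, yv = val_data
        report = evaluate_model(model, np.asarray(Xv, dtype=float),
                                np.asarray(yv).astype(int).ravel())
    else:
        best_epoch = max(config.epochs - 1, 0)
        report = evaluate_model(model, X, y.astype(int))
    return FoldResult(fold_index, history, best_epoch, report, model)


def _derived_seed(base: int, salt: int) -> int:
    return int((base * 1000003 + salt) % 2**31)


def _fit_fold_model(X_tr, y_tr, X_val, y_val, ae_config: AEConfig,
                    assembly_spec: AssemblySpec, train_config: TrainConfig,
                    fold_index: int, pretrain_X=None) -> FoldResult:
    """Pre-train (when the strategy imports trained weights), assemble and
    train one classifier. ``pretrain_X`` defaults to the training portion."""
    ae_seed = _derived_seed(train_config.seed, 2 * fold_index)
    head_seed = _derived_seed(train_config.seed, 2 * fold_index + 1)
    spec = copy.deepcopy(assembly_spec)
    spec.seed = head_seed

    if assembly_spec.strategy == "none":
        model = assemble(None, spec, input_dim=X_tr.shape[1])
    else:
        cfg = copy.deepcopy(ae_config)
        cfg.input_dim = X_tr.shape[1]
        cfg.seed = ae_seed
        ae = build_ae(cfg)
        if assembly_spec.strategy != "random_ae":
            pretrain(ae, X_tr if pretrain_X is None else pretrain_X)
        model = assemble(ae, spec)
    fold_cfg = copy.deepcopy(train_config)
    val_data = None if X_val is None else (X_val, y_val)
    return train_classifier(model, (X_tr, y_tr), val_data, fold_cfg,
                            fold_index=fold_index)


def summarize(fold_results: list[FoldResult]) -> dict[str, dict[str, float]]:
    """Per-metric mean and SD over folds (sample SD when k > 1)."""
    out = {}
    for key in SCALAR_METRICS:
        vals = np.array([fr.report.scalars()[key] for fr in fold_results])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[key] = {"mean": float(vals.mean()), "sd": sd}
    return out


def format_summary(summary: dict[str, dict[str, float]]) -> str:
    """Render a summary as 'metric: mean ± SD' lines (table style)."""
    lines = []
    for key in SCALAR_METRICS:
        s = summary[key]
        lines.append(f"{key:<9} {s['mean']:7.2f} ±{s['sd']:.2f}")
    return "\n".join(lines)


def cross_validate(dataset: ExpressionMatrix, ae_config: AEConfig,
                   assembly_spec: AssemblySpec, train_config: TrainConfig,
                   pretrain_scope: str = "fold",
                   imputation: str | None = None,
                   ) -> tuple[list[FoldResult], dict[str, dict[str, float]]]:
    """Stratified k-fold cross-validation of one pipeline configuration.

    For each fold: (optionally) fit the imputer on the training rows only,
    pre-train the AE on the fold's training portion (``pretrain_scope='fold'``,
    the leakage-safe default) or on the whole matrix
    (``pretrain_scope='full'``, protocol-faithful), assemble, train, and score
    the validation portion. Labels must already be binary (0/1).
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    if pretrain_scope not in ("fold", "full"):
        raise ValueError("pretrain_scope must be 'fold' or 'full'")
    train_config.validate()
    y = dataset.labels.to_numpy().astype(int)
    folds = stratified_folds(y, train_config.folds, train_config.seed)

    results: list[FoldResult] = []
    for i, val_idx in enumerate(folds):
        tr_mask = np.ones(dataset.n_samples, dtype=bool)
        tr_mask[val_idx] = False
        m_tr = ExpressionMatrix(dataset.data.iloc[tr_mask],
                                dataset.labels.iloc[tr_mask])
        m_val = ExpressionMatrix(dataset.data.iloc[val_idx],
                                 dataset.labels.iloc[val_idx])
        if imputation is not None:  # fold-safe imputation
            imp = fit_imputer(m_tr, imputation)
            m_tr, m_val = apply_imputer(m_tr, imp), apply_imputer(m_val, imp)
        pre_X = None
        if pretrain_scope == "full":
            full = dataset if imputation is None else apply_imputer(dataset, imp)
            pre_X = full.values
        results.append(_fit_fold_model(m_tr.values, y[tr_mask], m_val.values,
                                       y[val_idx], ae_config, assembly_spec,
                                       train_config, i, pretrain_X=pre_X))
    return results, summarize(results)


def holdout_split(labels, holdout_fraction: float, seed: int):
    """Stratified train/test index split; the test share is
    ``holdout_fraction`` (ceil rounding, matching the library convention)."""
    idx = np.arange(len(labels))
    tr, te = train_test_split(idx, test_size=holdout_fraction,
                              stratify=np.asarray(labels),
                              random_state=seed % 2**32)
    return np.sort(tr), np.sort(te)


def holdout_evaluate(dataset: ExpressionMatrix, ae_config: AEConfig,
                     assembly_spec: AssemblySpec, train_config: TrainConfig,
                     pretrain_scope: str = "fold") -> dict:
    """Held-out workflow: stratified test split, CV on the training portion,
    one final model retrained on all training rows and scored once on the
    never-touched test set (final-epoch weights; no test-driven selection)."""
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    train_config.validate()
    y = dataset.labels.to_numpy().astype(int)
    tr_idx, te_idx = holdout_split(y, train_config.holdout_fraction,
                                   train_config.seed)
    if np.unique(y[tr_idx]).size < 2 or np.unique(y[te_idx]).size < 2:
        raise ValueError("degenerate split: a side holds a single class")

    m_tr = ExpressionMatrix(dataset.data.iloc[tr_idx], dataset.labels.iloc[tr_idx])
    fold_results, summary = cross_validate(m_tr, ae_config, assembly_spec,
                                           train_config, pretrain_scope)

    final = _fit_fold_model(m_tr.values, y[tr_idx], None, None, ae_config,
                            assembly_spec, train_config,
                            fold_index=train_config.folds)
    test_report = evaluate_model(final.model, dataset.data.iloc[te_idx].to_numpy(),
                                 y[te_idx])
    return {"train_summary": summary, "fold_results": fold_results,
            "test_report": test_report, "final_model": final.model,
            "n_train": int(len(tr_idx)), "n_test": int(len(te_idx))}
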