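"""Stratified k-fold training and the evaluation metric suite.

Cross-validation follows the published protocol: a stratified 10-fold
partition (every fold carries the same per-class counts up to one), train
on nine folds plus augmented copies, test on the held-out fold — the test
fold never contains augmented records. Per-class metrics are one-vs-rest
on the 0-100 scale:

    ACC = (TP+TN)/(TP+TN+FP+FN) * 100        SE = TP/(TP+FN) * 100
    SP  = TN/(TN+FP) * 100                   PR = TP/(TP+FP) * 100
    F1  = 2 * PR * SE / (PR + SE)

with macro averages taken unweighted over classes, and one-vs-rest ROC
curves summarized by the trapezoid-rule AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion, roc_curve as _sk_roc

from .augment import AugmentConfig, augment_recording, build_training_roster
from .estimator import CVTTransClassifier
from .io_dataset import CLASSES, PCGRecording
from .preprocess import PreprocConfig, preprocess
from .tfr import TFRConfig, recording_to_image


@dataclass
class FoldSplit:
    k: int
    assignments: dict[str, int]
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignments.items() if f != fold]


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 16
    epochs: int = 20
    max_steps: int = 2000
    validation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows = true, cols = predicted
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    per_class: pd.DataFrame  # index = class, columns ACC/SE/SP/PR/F1 + tp/tn/fp/fn
    macro: dict[str, float]
    zero_division_flags: list[str] = field(default_factory=list)


def stratified_kfold(labels_by_id: dict[str, str], k: int = 10, seed: int = 0) -> FoldSplit:
    """Deterministic stratified partition of record ids into ``k`` folds."""
    from sklearn.model_selection import StratifiedKFold

    ids = np.array(sorted(labels_by_id))
    y = np.array([labels_by_id[i] for i in ids])
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise ValueError(
            f"every class needs >= {k} records; too few: {small.to_dict()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(ids, y)):
        for i in test_idx:
            assignments[str(ids[i])] = fold
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def evaluate(model, X_test, y_test, labels: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    """Tally argmax predictions of a fitted classifier into a confusion matrix."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X_test)
    counts = _sk_confusion(y_test, pred, labels=list(labels))
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest ACC/SE/SP/PR/F1 (0-100) plus macro averages.

    Division by zero yields 0 for the affected metric, recorded in
    ``zero_division_flags``.
    """
    counts = cm.counts
    total = counts.sum()
    flags: list[str] = []

    def ratio(num: float, den: float, tag: str) -> float:
        if den == 0:
            flags.append(tag)
            return 0.0
        return 100.0 * num / den

    rows = []
    for ci, cls in enumerate(cm.labels):
        tp = int(counts[ci, ci])
        fn = int(counts[ci].sum() - tp)
        fp = int(counts[:, ci].sum() - tp)
        tn = int(total - tp - fn - fp)
        acc = ratio(tp + tn, total, f"{cls}:ACC")
        se = ratio(tp, tp + fn, f"{cls}:SE")
        sp = ratio(tn, tn + fp, f"{cls}:SP")
        pr = ratio(tp, tp + fp, f"{cls}:PR")
        if pr + se == 0:
            flags.append(f"{cls}:F1")
            f1 = 0.0
        else:
            f1 = 2.0 * pr * se / (pr + se)
        rows.append(
            {"class": cls, "TP": tp, "TN": tn, "FP": fp, "FN": fn,
             "ACC": acc, "SE": se, "SP": sp, "PR": pr, "F1": f1}
        )
    per_class = pd.DataFrame(rows).set_index("class")
    macro = {m: float(per_class[m].mean()) for m in ("ACC", "SE", "SP", "PR", "F1")}
    macro["overall_ACC"] = float(100.0 * np.trace(counts) / total) if total else 0.0
    return MetricsReport(per_class=per_class, macro=macro, zero_division_flags=flags)


def roc_auc(scores: np.ndarray, labels, classes: tuple[str, ...] = CLASSES):
    """One-vs-rest ROC AUC per class (trapezoid rule) and the macro mean.

    A class absent from ``labels`` (or covering all of them) has no
    defined ROC; its AUC is NaN and excluded from the macro mean.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[0] != labels.size:
        raise ValueError("scores must be (n_samples, n_classes)")
    aucs: dict[str, float] = {}
    for ci, cls in enumerate(classes):
        pos = labels == cls
        if pos.all() or not pos.any():
            aucs[cls] = float("nan")
            continue
        fpr, tpr, _ = _sk_roc(pos.astype(int), scores[:, ci])
        aucs[cls] = float(np.trapezoid(tpr, fpr))
    finite = [v for v in aucs.values() if np.isfinite(v)]
    macro = float(np.mean(finite)) if finite else float("nan")
    return aucs, macro


# ---------------------------------------------------------------------------
# end-to-end cross-validation on recordings
# ---------------------------------------------------------------------------


def _images_for(
    recs: list[PCGRecording],
    preproc: PreprocConfig,
    tfr_cfg: TFRConfig,
    kind: str,
) -> np.ndarray:
    imgs = [recording_to_image(preprocess(r, preproc), tfr_cfg, kind) for r in recs]
    return np.stack([im.pixels for im in imgs])


def run_cv(
    recordings: list[PCGRecording],
    k: int = 10,
    model_params: dict | None = None,
    train_cfg: TrainConfig | None = None,
    augment_cfg: AugmentConfig | None = None,
    preproc_cfg: PreprocConfig | None = None,
    tfr_cfg: TFRConfig | None = None,
    image_kind: str = "cwt",
    roster_mode: str = "leakage_free",
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Stratified k-fold cross-validation over labeled recordings.

    For every fold: assemble the training roster (originals + augmented
    copies, per ``roster_mode``), preprocess and image the signals, fit a
    fresh classifier, and evaluate on the untouched held-out fold. Returns
    fold metrics, the pooled confusion matrix, and mean/std summaries;
    optionally writes everything under ``out_dir``.
    """
    train_cfg = train_cfg or TrainConfig(seed=seed)
    augment_cfg = augment_cfg or AugmentConfig(seed=seed)
    preproc_cfg = preproc_cfg or PreprocConfig()
    tfr_cfg = tfr_cfg or TFRConfig(image_size=64)
    model_params = dict(model_params or {})
    model_params.setdefault("input_size", tfr_cfg.image_size)

    by_id = {r.id: r for r in recordings}
    if len(by_id) != len(recordings):
        raise ValueError("recording ids must be unique")
    labels_by_id = {r.id: r.label for r in recordings}
    if any(v is None for v in labels_by_id.values()):
        raise ValueError("all recordings must be labeled")
    split = stratified_kfold(labels_by_id, k=k, seed=seed)

    # image every original once; augmented copies are imaged per fold
    ids = sorted(by_id)
    base_images = {
        i: _images_for([by_id[i]], preproc_cfg, tfr_cfg, image_kind)[0] for i in ids
    }

    present = tuple(c for c in CLASSES if c in set(labels_by_id.values()))
    fold_reports: list[MetricsReport] = []
    fold_aucs: list[float] = []
    pooled = np.zeros((len(present), len(present)), dtype=np.int64)
    histories = []

    # roster construction needs a manifest-like object with an id column
    from .io_dataset import DatasetManifest

    manifest = DatasetManifest(
        entries=pd.DataFrame(
            {
                "id": ids,
                "path": ids,
                "label": [labels_by_id[i] for i in ids],
                "fs": [by_id[i].fs for i in ids],
                "duration_s": [by_id[i].duration_s for i in ids],
            }
        )
    )

    rng_master = np.random.SeedSequence(seed)
    fold_seeds = rng_master.spawn(k)
    for fold in range(k):
        roster = build_training_roster(
            manifest, split.assignments, fold, augment_cfg, mode=roster_mode
        )
        rng = np.random.default_rng(fold_seeds[fold])
        X_parts, y_parts = [], []
        class_pool = [by_id[i] for i in split.train_ids(fold)]
        for entry in roster:
            parent = by_id[entry["parent_id"]]
            if entry["kind"] == "original":
                X_parts.append(base_images[parent.id])
            else:
                aug, _ = augment_recording(parent, augment_cfg, rng, class_pool)
                X_parts.append(
                    _images_for([aug], preproc_cfg, tfr_cfg, image_kind)[0]
                )
            y_parts.append(parent.label)
        X_train = np.stack(X_parts)
        y_train = np.array(y_parts)

        test_ids = split.test_ids(fold)
        X_test = np.stack([base_images[i] for i in test_ids])
        y_test = np.array([labels_by_id[i] for i in test_ids])

        clf = CVTTransClassifier(
            lr=train_cfg.lr,
            momentum=train_cfg.momentum,
            batch_size=train_cfg.batch_size,
            epochs=train_cfg.epochs,
            max_steps=train_cfg.max_steps,
            validation_fraction=train_cfg.validation_fraction,
            random_state=train_cfg.seed + fold,
            **model_params,
        )
        clf.fit(X_train, y_train)
        cm = evaluate(clf, X_test, y_test, labels=present)
        pooled += cm.counts
        report = compute_metrics(cm)
        fold_reports.append(report)
        scores = clf.predict_proba(X_test)
        # column order of predict_proba follows clf.classes_ (sorted labels)
        col = {c: j for j, c in enumerate(clf.classes_)}
        aligned = np.zeros((len(y_test), len(present)))
        for j, c in enumerate(present):
            if c in col:
                aligned[:, j] = scores[:, col[c]]
        _, macro_auc = roc_auc(aligned, y_test, classes=present)
        fold_aucs.append(macro_auc)
        histories.append(clf.history_)

    accs = [r.macro["overall_ACC"] for r in fold_reports]
    summary = {
        "k": k,
        "classes": list(present),
        "mean_accuracy": float(np.mean(accs)),
        "std_accuracy": float(np.std(accs)),
        "fold_accuracies": [float(a) for a in accs],
        "mean_macro_auc": float(np.nanmean(fold_aucs)),
        "macro_means": {
            m: float(np.mean([r.macro[m] for r in fold_reports]))
            for m in ("ACC", "SE", "SP", "PR", "F1")
        },
    }
    result = {
        "summary": summary,
        "fold_reports": fold_reports,
        "pooled_confusion": ConfusionMatrix(counts=pooled, labels=present),
        "fold_split": split,
        "histories": histories,
    }
    if out_dir is not None:
        _write_run_dir(Path(out_dir), result, train_cfg, augment_cfg)
    return result


def _write_run_dir(out: Path, result: dict, train_cfg, augment_cfg) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(result["summary"], fh, indent=2)
    with open(out / "config.json", "w") as fh:
        json.dump({"train": asdict(train_cfg), "augment": asdict(augment_cfg)}, fh, indent=2)
    cm = result["pooled_confusion"]
    pd.DataFrame(cm.counts, index=cm.labels, columns=cm.labels).to_csv(out / "confusion.csv")
    folds = result["fold_split"]
    pd.DataFrame(
        {"id": list(folds.assignments), "fold": list(folds.assignments.values())}
    ).to_csv(out / "folds.csv", index=False)
    for i, rep in enumerate(result["fold_reports"]):
        rep.per_class.to_csv(out / f"fold{i}_metrics.csv")
    hist_rows = []
    for i, h in enumerate(result["histories"]):
        for j in range(len(h["epoch"])):
            hist_rows.append({"fold": i, **{k: h[k][j] for k in h}})
    pd.DataFrame(hist_rows).to_csv(out / "history.csv", index=False)
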