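"""Tenfold cross-validation harness, metrics and hyperparameter sweeps.

Each frame lands in exactly one test fold; within a fold, 20% of the
training frames are held out for validation monitoring.  Splitting is
frame-level and stratified by class by default (mirroring a 90/10
frame split); a recording-grouped mode exists because frame-level splits
can leak recording identity between train and test.

The pooled confusion matrix has true classes as rows and predicted classes
as columns; precision is the column-wise and recall the row-wise diagonal
fraction.  Fold-accuracy spread is reported as mean +/- sd (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold, train_test_split

from . import features_svm, models
from .framing import FrameDataset
from .recording import CLASSES


@dataclass
class CvPlan:
    folds: list[dict[str, np.ndarray]]   # per fold: train / val / test index arrays
    n: int
    k: int
    seed: int
    stratified: bool
    grouping: str

    def __post_init__(self):
        all_test = np.concatenate([f["test"] for f in self.folds])
        if sorted(all_test.tolist()) != list(range(self.n)):
            raise AssertionError("test folds do not partition the frames")
        for i, f in enumerate(self.folds):
            tr, va, te = set(f["train"]), set(f["val"]), set(f["test"])
            if tr & va or tr & te or va & te:
                raise AssertionError(f"fold {i}: train/val/test sets overlap")

    @property
    def fold_of(self) -> np.ndarray:
        out = np.empty(self.n, dtype=int)
        for i, f in enumerate(self.folds):
            out[f["test"]] = i + 1
        return out


def make_cv_plan(labels: np.ndarray, k: int = 10, seed: int = 0,
                 stratified: bool = True, grouping: str = "frame",
                 groups: np.ndarray | None = None,
                 val_fraction: float = 0.2) -> CvPlan:
    """Assign every frame to one of ``k`` test folds and carve out validation."""
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    if grouping == "recording":
        if groups is None:
            raise ValueError("recording-grouped plan requires group ids")
        splitter = GroupKFold(n_splits=k)
        split_iter = splitter.split(np.zeros(n), labels, groups)
    elif stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))
    folds = []
    for i, (train_full, test) in enumerate(split_iter):
        strat = labels[train_full] if stratified and grouping == "frame" else None
        train, val = train_test_split(train_full, test_size=val_fraction,
                                      random_state=seed + i, stratify=strat)
        folds.append({"train": np.sort(train), "val": np.sort(val),
                      "test": np.sort(test)})
    return CvPlan(folds, n, k, seed, stratified, grouping)


@dataclass
class CvReport:
    model_name: str
    fold_accuracies: list[float]
    confusion: np.ndarray            # rows = true, columns = predicted
    classes: tuple[str, ...] = CLASSES
    manifest: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def pooled_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def precision(self) -> np.ndarray:
        col = self.confusion.sum(axis=0)
        return np.divide(np.diag(self.confusion), col, where=col > 0,
                         out=np.zeros(len(self.classes)))

    @property
    def recall(self) -> np.ndarray:
        row = self.confusion.sum(axis=1)
        return np.divide(np.diag(self.confusion), row, where=row > 0,
                         out=np.zeros(len(self.classes)))


def _fit_predict_fold(model_name, dataset: FrameDataset, feature_table,
                      idx_train, idx_val, idx_test,
                      train_config: models.TrainConfig, fold_seed: int) -> np.ndarray:
    """Train on one fold and return predicted labels for its test frames."""
    import dataclasses as _dc
    X, y = dataset.X(), dataset.y()
    if callable(model_name):
        clf = model_name()
        clf.fit(X[idx_train], y[idx_train], X[idx_val], y[idx_val])
        return np.asarray(clf.predict(X[idx_test]))
    if model_name == "svm":
        train_tab = feature_table.iloc[idx_train].reset_index(drop=True)
        report = features_svm.tamhane_t2_select(train_tab)
        selected = report.selected or list(report.feature_p.sort_values().index[:3])
        svm = features_svm.train_svm(train_tab, selected, seed=fold_seed)
        pred = features_svm.predict_svm(svm, feature_table.iloc[idx_test])
        code = {c: i for i, c in enumerate(CLASSES)}
        return np.array([code[p] for p in pred])
    cfg = _dc.replace(train_config, rng_seed=fold_seed)
    model = models.build_model(model_name, cfg)
    models.train(model, X[idx_train], y[idx_train], X[idx_val], y[idx_val], cfg)
    return models.predict(model, X[idx_test])[1]


def evaluate_model(model_name: str | Callable, dataset: FrameDataset, plan: CvPlan,
                   train_config: models.TrainConfig | None = None) -> CvReport:
    """Run the full cross-validation and pool the confusion matrix."""
    train_config = train_config or models.TrainConfig()
    y = dataset.y()
    feature_table = None
    if model_name == "svm":
        feature_table = features_svm.extract_features(dataset)
    n_cls = len(CLASSES)
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    fold_accs = []
    for i, fold in enumerate(plan.folds):
        tr, va, te = fold["train"], fold["val"], fold["test"]
        if set(tr) & set(te) or set(va) & set(te):
            raise AssertionError(f"fold {i}: leakage between train/val and test")
        pred = _fit_predict_fold(model_name, dataset, feature_table, tr, va, te,
                                 train_config, plan.seed + 1000 * (i + 1))
        truth = y[te]
        fold_accs.append(float((pred == truth).mean()))
        np.add.at(confusion, (truth, pred), 1)
    name = model_name if isinstance(model_name, str) else getattr(
        model_name, "__name__", "custom")
    manifest = {"k": plan.k, "seed": plan.seed, "stratified": plan.stratified,
                "grouping": plan.grouping, "n_frames": plan.n,
                "train_config": vars(train_config)}
    return CvReport(name, fold_accs, confusion, CLASSES, manifest)


def sweep(model_name: str, dataset: FrameDataset,
          layer_grid=(1, 2, 3), unit_grid=(8, 16, 32, 64, 128),
          train_config: models.TrainConfig | None = None, seed: int = 0,
          k: int = 10, mode: str = "cv") -> pd.DataFrame:
    """Accuracy over the layers x units grid (full CV or a single fixed split)."""
    if not layer_grid or not unit_grid:
        raise ValueError("grids must be non-empty")
    if model_name == "svm":
        raise ValueError("the layers x units sweep applies to recurrent models only")
    base = train_config or models.TrainConfig()
    import dataclasses as _dc
    rows = []
    y = dataset.y()
    for n_layers in layer_grid:
        for units in unit_grid:
            cfg = _dc.replace(base, n_layers=n_layers, units=units)
            if mode == "cv":
                plan = make_cv_plan(y, k=k, seed=seed)
                acc = evaluate_model(model_name, dataset, plan, cfg).mean_accuracy
            else:
                plan = make_cv_plan(y, k=k, seed=seed)
                fold = plan.folds[0]
                pred = _fit_predict_fold(model_name, dataset, None, fold["train"],
                                         fold["val"], fold["test"], cfg, seed)
                acc = float((pred == y[fold["test"]]).mean())
            rows.append({"n_layers": n_layers, "units": units, "mean_accuracy": acc})
    return pd.DataFrame(rows)


@dataclass
class FrameLengthComparison:
    reports: dict[float, CvReport]
    mean_difference: float           # accuracy(length A) - accuracy(length B)


def compare_frame_lengths(datasets: dict[float, FrameDataset], model_name: str,
                          train_config: models.TrainConfig | None = None,
                          seed: int = 0, k: int = 10) -> FrameLengthComparison:
    """Paired CV (aligned fold seeds) of one model across two frame lengths."""
    if len(datasets) != 2:
        raise ValueError("exactly two frame lengths are compared")
    reports = {}
    for length, ds in sorted(datasets.items()):
        plan = make_cv_plan(ds.y(), k=k, seed=seed)
        reports[length] = evaluate_model(model_name, ds, plan, train_config)
    lengths = sorted(reports)
    diff = reports[lengths[1]].mean_accuracy - reports[lengths[0]].mean_accuracy
    return FrameLengthComparison(reports, float(diff))
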