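"""Classification tasks, patient-grouped stratified CV, metrics, and the
full experiment grid.

Six tasks are defined over the clinical-form labels: the three pairwise
form comparisons, RR vs the pooled progressive forms (PP+SP), the
three-way form classification, and MS vs healthy controls. Cross-validation
is 5-fold, grouped by patient (all scans of one patient fall in exactly
one fold — longitudinal repeats must never straddle the train/test split)
and stratified by the patient's clinical form.

The default experiment grid crosses 3 atlases x 2 distances x 4 rejection
quantiles x 3 normalization modes = 72 GCN configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .cohort import ScanRecord
from .features import Parcellation, build_feature_matrix
from .gcn import GCNClassifier, TrainingConfig, predict, train
from .graphs import build_adjacency, threshold_graph
from .normalization import (
    apply_proportional,
    apply_residual,
    fit_proportional,
    fit_residual,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TaskSpec",
    "TASKS",
    "FoldSplit",
    "make_task_dataset",
    "make_ms_vs_hc_split",
    "stratified_group_kfold",
    "compute_metrics",
    "GridConfig",
    "cross_validate_task",
    "run_experiment_grid",
]


@dataclass(frozen=True)
class TaskSpec:
    name: str
    label_map: Mapping[str, int]
    class_names: tuple

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


TASKS = {
    "RR_vs_PP": TaskSpec("RR_vs_PP", {"RR": 0, "PP": 1}, ("RR", "PP")),
    "RR_vs_SP": TaskSpec("RR_vs_SP", {"RR": 0, "SP": 1}, ("RR", "SP")),
    "PP_vs_SP": TaskSpec("PP_vs_SP", {"PP": 0, "SP": 1}, ("PP", "SP")),
    "RR_vs_PPSP": TaskSpec(
        "RR_vs_PPSP", {"RR": 0, "PP": 1, "SP": 1}, ("RR", "PPSP")
    ),
    "RR_vs_PP_vs_SP": TaskSpec(
        "RR_vs_PP_vs_SP", {"RR": 0, "PP": 1, "SP": 2}, ("RR", "PP", "SP")
    ),
    "MS_vs_HC": TaskSpec(
        "MS_vs_HC", {"RR": 0, "PP": 0, "SP": 0, "HC": 1}, ("MS", "HC")
    ),
}


def make_task_dataset(scans: Sequence[ScanRecord], task):
    """Filter scans to the task's classes and remap labels.

    Returns (subset of scans, integer label array).
    """
    if isinstance(task, str):
        try:
            task = TASKS[task]
        except KeyError:
            raise ValueError(
                f"unknown task {task!r}; choose from {sorted(TASKS)}"
            ) from None
    subset = [s for s in scans if s.label in task.label_map]
    y = np.array([task.label_map[s.label] for s in subset], dtype=int)
    return subset, y


def make_ms_vs_hc_split(
    ms_scans: Sequence[ScanRecord],
    hc_scans: Sequence[ScanRecord],
    seed: int = 0,
    test_ms_per_class: Mapping[str, int] = None,
    test_hc_ixi: int = 24,
    train_hc_ixi: int = 290,
):
    """The study's fixed MS-vs-HC train/test composition.

    Test: 42 MS scans (24 RR / 10 PP / 8 SP), all study-protocol HC scans
    (patient ids ``HCA*``) and 24 wide-age reference HC scans; train: the
    remaining MS scans plus 290 reference HC scans. Test MS scans are
    chosen patient-wise (whole patients until the class quota is filled; a
    partially used patient's remaining scans are dropped entirely) so no
    patient ever appears on both sides.

    Returns (train_scans, test_scans).
    """
    if test_ms_per_class is None:
        test_ms_per_class = {"RR": 24, "PP": 10, "SP": 8}
    rng = np.random.default_rng(seed)
    train, test = [], []
    excluded_patients = set()
    for cls, quota in test_ms_per_class.items():
        by_patient: dict = {}
        for s in ms_scans:
            if s.label == cls:
                by_patient.setdefault(s.patient_id, []).append(s)
        pids = sorted(by_patient)
        order = rng.permutation(len(pids))
        remaining = quota
        for k in order:
            if remaining <= 0:
                break
            pid = pids[k]
            scans = by_patient[pid]
            take = min(len(scans), remaining)
            test.extend(scans[:take])
            remaining -= take
            excluded_patients.add(pid)
        if remaining > 0:
            raise ValueError(
                f"not enough {cls} scans for the fixed test split"
            )
    train.extend(s for s in ms_scans if s.patient_id not in excluded_patients)

    hca = [s for s in hc_scans if s.patient_id.startswith("HCA")]
    hci = [s for s in hc_scans if not s.patient_id.startswith("HCA")]
    test.extend(hca)
    order = rng.permutation(len(hci))
    if len(hci) < test_hc_ixi + 1:
        raise ValueError("not enough reference HC scans for the fixed split")
    test.extend(hci[k] for k in order[:test_hc_ixi])
    n_train_hc = min(train_hc_ixi, len(hci) - test_hc_ixi)
    train.extend(hci[k] for k in order[test_hc_ixi:test_hc_ixi + n_train_hc])
    return train, test


@dataclass(frozen=True)
class FoldSplit:
    """k patient-disjoint folds of scan indices."""

    folds: tuple  # tuple of np.ndarray of scan indices
    patient_to_fold: Mapping[str, int]

    @property
    def k(self) -> int:
        return len(self.folds)

    def iter_splits(self):
        """Yield (train_indices, test_indices) per fold."""
        for f in range(self.k):
            test = self.folds[f]
            tr = np.concatenate([self.folds[g] for g in range(self.k) if g != f])
            yield np.sort(tr), np.sort(test)


def stratified_group_kfold(
    labels: Sequence,
    groups: Sequence,
    k: int = 5,
    seed: int = 0,
) -> FoldSplit:
    """Patient-grouped, class-stratified k folds.

    Patients (groups) are assigned whole to folds: sorted by descending
    scan count (ties shuffled by ``seed``), each patient goes to the fold
    with the fewest scans of their class, breaking ties by total fold size
    then fold index. Every patient must carry a single class label.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if k < 2:
        raise ValueError("k must be >= 2")
    patient_label: dict = {}
    patient_count: dict = {}
    for lab, g in zip(labels, groups):
        if g in patient_label and patient_label[g] != lab:
            raise ValueError(f"patient {g!r} has scans with multiple labels")
        patient_label[g] = lab
        patient_count[g] = patient_count.get(g, 0) + 1
    classes, class_n = np.unique(list(patient_label.values()), return_counts=True)
    for cls, n in zip(classes, class_n):
        if n < k:
            raise ValueError(
                f"class {cls!r} has {n} patients, fewer than k={k} folds"
            )
    rng = np.random.default_rng(seed)
    pids = sorted(patient_count)
    order = rng.permutation(len(pids))
    pids = [pids[i] for i in order]
    pids.sort(key=lambda p: -patient_count[p])  # stable: ties keep shuffle order
    fold_class_counts = [dict() for _ in range(k)]
    fold_totals = np.zeros(k, dtype=int)
    patient_to_fold = {}
    for pid in pids:
        cls, cnt = patient_label[pid], patient_count[pid]
        best = min(
            range(k),
            key=lambda f: (fold_class_counts[f].get(cls, 0), fold_totals[f], f),
        )
        patient_to_fold[pid] = best
        fold_class_counts[best][cls] = fold_class_counts[best].get(cls, 0) + cnt
        fold_totals[best] += cnt
    folds = [[] for _ in range(k)]
    for i, g in enumerate(groups):
        folds[patient_to_fold[g]].append(i)
    return FoldSplit(
        folds=tuple(np.asarray(f, dtype=int) for f in folds),
        patient_to_fold=patient_to_fold,
    )


def compute_metrics(y_true, y_pred, n_classes: int) -> dict:
    """Precision/recall/F1 (support-weighted and macro) plus per-class
    values and the confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = list(range(n_classes))
    out = {}
    for avg in ("weighted", "macro"):
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average=avg, zero_division=0
        )
        out[f"precision_{avg}"] = float(p)
        out[f"recall_{avg}"] = float(r)
        out[f"f1_{avg}"] = float(f)
    p, r, f, s = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0
    )
    out["precision_per_class"] = p.tolist()
    out["recall_per_class"] = r.tolist()
    out["f1_per_class"] = f.tolist()
    out["support_per_class"] = s.tolist()
    out["confusion_matrix"] = confusion_matrix(
        y_true, y_pred, labels=labels
    ).tolist()
    return out


def chance_level(
    y_true, y_pred, n_classes: int, n_permutations: int = 200, seed: int = 0
) -> float:
    """Chance-level weighted F1 for a given set of predictions.

    The chance level of a metric depends on the predictor's output
    marginal (a constant predictor on balanced binary data has chance
    weighted F1 of 1/3, a coin-flip predictor 1/2), so it is estimated
    the standard way: the mean metric over label permutations, which
    breaks any association between predictions and truth while keeping
    both marginals fixed.
    """
    y_true = np.asarray(y_true)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_permutations):
        perm = rng.permutation(y_true.size)
        p, r, f, _ = precision_recall_fscore_support(
            y_true[perm], y_pred, labels=list(range(n_classes)),
            average="weighted", zero_division=0,
        )
        vals.append(f)
    return float(np.mean(vals))


def cross_validate_task(
    graphs,
    labels,
    groups,
    n_classes: int,
    training: TrainingConfig,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Grouped stratified k-fold CV of the GCN on prebuilt graphs.

    Returns per-fold metrics and the mean +/- SD summary.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    split = stratified_group_kfold(labels, groups, k=k, seed=seed)
    fold_metrics = []
    for f, (tr, te) in enumerate(split.iter_splits()):
        assert not set(groups[tr]) & set(groups[te])
        model = GCNClassifier(n_classes=n_classes, seed=seed + f)
        cfg = TrainingConfig(**{**training.__dict__, "seed": seed + f})
        model, _ = train(
            model, [graphs[i] for i in tr], labels[tr], cfg, groups=groups[tr]
        )
        y_pred, _ = predict(model, [graphs[i] for i in te])
        m = compute_metrics(labels[te], y_pred, n_classes)
        m["fold"] = f
        m["y_true"] = labels[te].tolist()
        m["y_pred"] = y_pred.tolist()
        fold_metrics.append(m)
    summary = {}
    for key in ("f1_weighted", "f1_macro", "precision_weighted", "recall_weighted"):
        vals = np.array([m[key] for m in fold_metrics])
        summary[f"mean_{key}"] = float(vals.mean())
        summary[f"sd_{key}"] = float(vals.std())
    return {"folds": fold_metrics, "summary": summary, "k": k, "seed": seed}


@dataclass
class GridConfig:
    """The experiment grid: atlases x distances x thresholds x
    normalization modes (defaults give the full 72-cell grid)."""

    atlases: tuple = ("desikan-killiany", "destrieux", "glasser")
    metrics: tuple = ("mahalanobis", "taxicab")
    taus: tuple = (0.0, 0.6, 0.7, 0.8)
    normalizations: tuple = ("none", "proportional", "residual")

    def cells(self) -> list:
        return [
            {"atlas": a, "metric": m, "tau": t, "normalization": n}
            for a in self.atlases
            for m in self.metrics
            for t in self.taus
            for n in self.normalizations
        ]

    @property
    def n_cells(self) -> int:
        return (
            len(self.atlases) * len(self.metrics)
            * len(self.taus) * len(self.normalizations)
        )


def _normalized_features(scans, feats, mode, healthy_scans, healthy_feats, parc):
    if mode == "none":
        return feats
    if mode == "proportional":
        model = fit_proportional(healthy_scans)
        return [apply_proportional(X, s, model) for X, s in zip(feats, scans)]
    if mode == "residual":
        model = fit_residual(healthy_scans, parc, features=healthy_feats)
        return [apply_residual(X, s, model) for X, s in zip(feats, scans)]
    raise ValueError(f"unknown normalization mode {mode!r}")


def run_experiment_grid(
    scans: Sequence[ScanRecord],
    healthy_scans: Sequence[ScanRecord],
    grid: GridConfig,
    training: Optional[TrainingConfig] = None,
    tasks: Sequence[str] = ("RR_vs_PP",),
    k: int = 5,
    seed: int = 0,
    dry_run: bool = False,
) -> list:
    """One cross-validated metrics report per grid cell per task.

    ``dry_run=True`` only enumerates the cells (no feature extraction or
    training). Failures in one cell are recorded and the grid continues.
    Deterministic given the master seed: cell ``c`` trains with seed
    ``seed + 1000*c``.
    """
    cells = grid.cells()
    if dry_run:
        return [
            {**cell, "task": t, "status": "enumerated"}
            for cell in cells for t in tasks
        ]
    training = training or TrainingConfig()
    results = []
    feat_cache: dict = {}
    adj_cache: dict = {}
    for c, cell in enumerate(cells):
        atlas, metric, tau, mode = (
            cell["atlas"], cell["metric"], cell["tau"], cell["normalization"]
        )
        try:
            if atlas not in feat_cache:
                parc = (
                    Parcellation.from_name(atlas)
                    if atlas in ("desikan-killiany", "destrieux", "glasser")
                    else Parcellation.custom(int(atlas))
                )
                feat_cache[atlas] = (
                    parc,
                    [build_feature_matrix(s, parc) for s in scans],
                    [build_feature_matrix(s, parc) for s in healthy_scans],
                )
            parc, feats, hfeats = feat_cache[atlas]
            key = (atlas, mode, metric)
            if key not in adj_cache:
                nf = _normalized_features(
                    scans, feats, mode, healthy_scans, hfeats, parc
                )
                adj_cache[key] = (
                    nf, [build_adjacency(X, metric) for X in nf]
                )
            nf, adjs = adj_cache[key]
            graphs = [
                threshold_graph(A, tau, node_features=X)
                for A, X in zip(adjs, nf)
            ]
            for task_name in tasks:
                task = TASKS[task_name]
                idx = [i for i, s in enumerate(scans) if s.label in task.label_map]
                tgraphs = [graphs[i] for i in idx]
                ty = np.array([task.label_map[scans[i].label] for i in idx])
                tgroups = np.array([scans[i].patient_id for i in idx])
                report = cross_validate_task(
                    tgraphs, ty, tgroups, task.n_classes, training,
                    k=k, seed=seed + 1000 * c,
                )
                results.append(
                    {**cell, "task": task_name, "status": "ok", **report["summary"],
                     "folds": report["folds"]}
                )
        except Exception as exc:  # record and continue
            logger.exception("grid cell %s failed", cell)
            for task_name in tasks:
                results.append(
                    {**cell, "task": task_name, "status": "error",
                     "error": f"{type(exc).__name__}: {exc}"}
                )
    return results
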