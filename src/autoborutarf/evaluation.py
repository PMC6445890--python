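"""Binary-classification metrics, AUC and cross-validated evaluation.

The positive class throughout is "sensitive".  Metrics follow the standard
confusion-matrix formulas:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    REC = TP / (TP + FN)
    SPC = TN / (TN + FP)
    F1  = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(FP+TN)(FN+TN))

A metric whose denominator is zero is reported as 0 and flagged.  AUC uses
the rank (Mann-Whitney) formulation, with tied scores contributing 1/2.

``cross_validate`` draws a seeded stratified 10-fold partition and, per
fold, runs Boruta selection and forest/EasyEnsemble training on the nine
training folds only, so held-out cells never influence feature selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata, ranksums
from sklearn.model_selection import StratifiedKFold

from . import boruta_select, ensemble_classifier as ens
from .core_io import PipelineConfig
from .labeling import LabelVector

logger = logging.getLogger("autoborutarf")

METRIC_NAMES = ("ACC", "REC", "SPC", "F1", "MCC", "AUC")


class StratificationError(ValueError):
    pass


class UndefinedAUCError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=bool)
        p = np.asarray(y_pred, dtype=bool)
        return cls(TP=int((t & p).sum()), FP=int((~t & p).sum()),
                   FN=int((t & ~p).sum()), TN=int((~t & ~p).sum()))


@dataclass
class MetricsReport:
    drug: str
    per_fold: pd.DataFrame  # one row per fold, columns METRIC_NAMES
    fold_assignments: pd.Series  # cell id -> fold index
    seed: int
    flags: list[str] = field(default_factory=list)
    selected_per_fold: list[list[str]] = field(default_factory=list)

    @property
    def mean_metrics(self) -> pd.Series:
        return self.per_fold[list(METRIC_NAMES)].mean()

    def to_frame(self) -> pd.DataFrame:
        mean_row = self.mean_metrics.to_frame().T
        mean_row.index = ["mean"]
        return pd.concat([self.per_fold, mean_row])


def compute_metrics(counts: ConfusionCounts) -> dict:
    """ACC/REC/SPC/F1/MCC; zero-denominator metrics are 0 and flagged."""
    if counts.total <= 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = (float(counts.TP), float(counts.FP),
                      float(counts.FN), float(counts.TN))
    flags = []

    def safe(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    out = {
        "ACC": (tp + tn) / counts.total,
        "REC": safe(tp, tp + fn, "REC"),
        "SPC": safe(tn, tn + fp, "SPC"),
        "F1": safe(2 * tp, 2 * tp + fp + fn, "F1"),
        "MCC": safe(tp * tn - fp * fn,
                    np.sqrt((tp + fp) * (tp + fn) * (fp + tn) * (fn + tn)),
                    "MCC"),
    }
    out["flags"] = flags
    return out


def compute_auc(scores, y_true) -> float:
    """Area under the ROC via the Mann-Whitney rank statistic; ties count 1/2."""
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC needs both classes")
    r = rankdata(s)  # average ranks handle ties
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def stratified_folds(y, n_folds: int, seed: int) -> np.ndarray:
    """Fold index per sample from a seeded stratified partition."""
    y = np.asarray(y, dtype=bool)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold = np.empty(len(y), dtype=int)
    try:
        for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            fold[test_idx] = i
    except ValueError as exc:
        raise StratificationError(str(exc)) from exc
    return fold


def cross_validate(X: pd.DataFrame, labels: LabelVector,
                   config: PipelineConfig, seed: int = 0) -> MetricsReport:
    """Stratified k-fold evaluation with in-fold feature selection.

    When no feature is confirmed in a training fold (a null drug), the fold
    falls back to a constant score of 1/2 and the majority (non-sensitive)
    label, so its AUC is 1/2 by the tie convention.
    """
    y = labels.y
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X rows must align with labels")
    fold = stratified_folds(y, config.cv_folds, seed)
    rng = np.random.default_rng(seed)

    rows = []
    flags: list[str] = []
    selected_per_fold: list[list[str]] = []
    select_rng = np.random.default_rng(seed + 1)
    global_selected: list[str] | None = None
    if not config.select_per_fold:
        res = boruta_select.boruta_run(
            X, y, rng=select_rng, max_iter=config.boruta_max_iter,
            alpha=config.boruta_alpha, n_trees=config.boruta_n_trees,
            bootstrap_fraction=config.bootstrap_fraction,
            bootstrap_replace=config.bootstrap_replace)
        global_selected = list(res.confirmed)
        if config.keep_tentative:
            global_selected += list(res.tentative)

    for k in range(config.cv_folds):
        train = fold != k
        test = ~train
        if len(np.unique(y[train])) < 2:
            raise StratificationError(f"fold {k}: single-class training set")

        if global_selected is None:
            res = boruta_select.boruta_run(
                X.loc[train], y[train], rng=select_rng,
                max_iter=config.boruta_max_iter, alpha=config.boruta_alpha,
                n_trees=config.boruta_n_trees,
                bootstrap_fraction=config.bootstrap_fraction,
                bootstrap_replace=config.bootstrap_replace)
            selected = list(res.confirmed)
            if config.keep_tentative:
                selected += list(res.tentative)
        else:
            selected = global_selected
        selected_per_fold.append(selected)

        if selected:
            model = ens.train_easy_ensemble(
                X.loc[train, selected], y[train], n_trees=config.rf_n_trees,
                ir_threshold=config.ir_bypass_threshold,
                seed=np.random.default_rng(int(rng.integers(2**31))),
                bootstrap_fraction=config.bootstrap_fraction,
                bootstrap_replace=config.bootstrap_replace)
            pred, score = model.predict(X.loc[test, selected])
        else:
            flags.append(f"fold{k}:empty-selection")
            pred = np.zeros(int(test.sum()), dtype=bool)
            score = np.full(int(test.sum()), 0.5)

        counts = ConfusionCounts.from_predictions(y[test], pred)
        metrics = compute_metrics(counts)
        flags += [f"fold{k}:{f}" for f in metrics.pop("flags")]
        metrics["AUC"] = compute_auc(score, y[test])
        rows.append(metrics)

    per_fold = pd.DataFrame(rows, index=[f"fold{k}" for k in
                                         range(config.cv_folds)])
    report = MetricsReport(
        drug=labels.drug, per_fold=per_fold[list(METRIC_NAMES)],
        fold_assignments=pd.Series(fold, index=labels.cell_line_ids),
        seed=seed, flags=flags, selected_per_fold=selected_per_fold)
    logger.info("CV done for %s: mean AUC %.3f", labels.drug,
                report.mean_metrics["AUC"])
    return report


def biomarker_significance(selected: list[str],
                           features: dict, labels: LabelVector) -> pd.DataFrame:
    """Two-sided association tests of each selected feature with the label.

    Wilcoxon rank-sum for real-valued (expression/cna) features, Fisher's
    exact test on the 2x2 mutation-by-class table for snv.  Raw p-values,
    no multiplicity correction.  Constant features get p = 1 with a flag.
    """
    y = labels.y
    rows = []
    for feat in selected:
        kind = None
        col = None
        for k, fm in features.items():
            if feat in fm.values.columns:
                kind = k
                col = fm.values.loc[labels.cell_line_ids, feat].to_numpy()
                break
        if kind is None:
            raise KeyError(f"selected feature {feat!r} not found")
        if np.all(col == col[0]):
            rows.append({"feature": feat, "kind": kind, "p_value": 1.0,
                         "test": "constant", "flag": "constant"})
            continue
        if kind == "snv":
            table = [[int(((col == 1) & y).sum()), int(((col == 1) & ~y).sum())],
                     [int(((col == 0) & y).sum()), int(((col == 0) & ~y).sum())]]
            _, p = fisher_exact(table, alternative="two-sided")
            test = "fisher_exact"
        else:
            _, p = ranksums(col[y], col[~y])
            test = "wilcoxon_rank_sum"
        rows.append({"feature": feat, "kind": kind, "p_value": float(p),
                     "test": test, "flag": ""})
    return pd.DataFrame(rows)
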