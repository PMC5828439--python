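"""RBF-kernel SVM classification of subjects under leave-one-out CV.

The kernel scale is fixed (default 1, on standardized features); the
soft-margin box constraint is selected per training set by stratified
inner cross-validation over a documented grid, ties resolved toward the
smallest constraint. Standardization parameters are estimated on the
training rows of each fold only, so the held-out subject never leaks
into model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import feature_columns
from .metrics import ConfusionCounts, confusion_from_predictions

#: Feature subsets compared in the study design: turns-amplitude alone and
#: its extensions with permutation entropy and/or signal energy.
DEFAULT_FEATURE_SETS: tuple[tuple[str, ...], ...] = (
    ("turns_per_s", "mean_interspike_amplitude"),
    ("turns_per_s", "mean_interspike_amplitude", "permutation_entropy"),
    ("turns_per_s", "mean_interspike_amplitude", "energy"),
    ("turns_per_s", "mean_interspike_amplitude", "permutation_entropy", "energy"),
)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM training protocol.

    kernel_scale s enters the Gaussian kernel as exp(-||x-y||^2 / s^2);
    box_constraint_grid is searched by ``inner_cv_folds``-fold stratified
    inner CV on each training set.
    """

    feature_names: tuple[str, ...] = DEFAULT_FEATURE_SETS[-1]
    kernel_scale: float = 1.0
    box_constraint_grid: tuple[float, ...] = DEFAULT_C_GRID
    inner_cv_folds: int = 5
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.feature_names:
            raise ValueError("feature_names must be non-empty")
        if not self.box_constraint_grid or any(c <= 0 for c in self.box_constraint_grid):
            raise ValueError("box_constraint_grid must be positive and non-empty")
        if self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be positive")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")


@dataclass
class LOOCVResult:
    """Leave-one-out evaluation outcome.

    ``predictions`` holds one row per subject (subject_id, true_label,
    predicted_label) from the first repeat; ``counts`` are the confusion
    counts averaged over repeats (fractional when repeats > 1);
    ``chosen_constraints`` records the box constraint selected in each
    outer fold of the first repeat.
    """

    predictions: pd.DataFrame
    counts: ConfusionCounts
    chosen_constraints: list[float] = field(default_factory=list)
    repeats: int = 1


def _design_matrix(table: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks feature columns {missing}")
    X = table.loc[:, list(names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = table.loc[~np.isfinite(X).all(axis=1), "subject_id"].tolist()
        raise ValueError(
            f"subjects with undefined feature values must be excluded first: {bad}"
        )
    return X


def drop_incomplete(table: pd.DataFrame, names=None) -> pd.DataFrame:
    """Remove subjects with undefined (NaN) values among ``names``.

    Returns the filtered table; the caller is expected to log the
    excluded subject ids rather than impute.
    """
    cols = list(names) if names is not None else feature_columns(table)
    mask = table.loc[:, cols].notna().all(axis=1)
    return table.loc[mask].reset_index(drop=True)


def _make_pipeline(cfg: ClassifierConfig, C: float) -> Pipeline:
    gamma = 1.0 / (cfg.kernel_scale**2)
    steps = []
    if cfg.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel="rbf", C=C, gamma=gamma)))
    return Pipeline(steps)


def _select_constraint(
    X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig, rng_seed: int
) -> float:
    """Inner-CV accuracy over the grid; ties go to the smallest constraint."""
    n_splits = min(cfg.inner_cv_folds, int(np.min(np.bincount(y))))
    if n_splits < 2:
        return min(cfg.box_constraint_grid)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rng_seed % (2**32))
    best_c, best_acc = None, -1.0
    for c in sorted(cfg.box_constraint_grid):
        correct = 0
        for tr, te in cv.split(X, y):
            model = _make_pipeline(cfg, c)
            model.fit(X[tr], y[tr])
            correct += int(np.sum(model.predict(X[te]) == y[te]))
        acc = correct / len(y)
        if acc > best_acc:
            best_c, best_acc = c, acc
    return best_c


def train_svm(training_rows: pd.DataFrame, cfg: ClassifierConfig):
    """Fit the RBF-SVM on a cohort table; returns the fitted model.

    The returned object exposes ``predict`` on raw (unstandardized)
    feature matrices in the order of ``cfg.feature_names`` and a
    ``predict_labels(table)`` convenience wrapper.
    """
    X = _design_matrix(training_rows, cfg.feature_names)
    y = (training_rows["label"].to_numpy() == "neuropathic").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    c = _select_constraint(X, y, cfg, cfg.seed)
    model = _make_pipeline(cfg, c)
    model.fit(X, y)
    model.chosen_constraint_ = c

    def predict_labels(table: pd.DataFrame) -> np.ndarray:
        Xn = _design_matrix(table, cfg.feature_names)
        pred = model.predict(Xn)
        return np.where(pred == 1, "neuropathic", "normal")

    model.predict_labels = predict_labels
    return model


def loocv_evaluate(
    table: pd.DataFrame, cfg: ClassifierConfig, repeats: int = 1
) -> LOOCVResult:
    """Leave-one-out cross-validation over the cohort table.

    Each subject is predicted by a model trained (including inner-CV
    constraint selection and standardization) on the remaining n-1.
    With ``repeats > 1`` the whole LOOCV is rerun with fresh inner-CV
    shuffling seeds and the confusion counts are averaged, which yields
    fractional counts.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 subjects for leave-one-out CV")
    table = table.reset_index(drop=True)
    X = _design_matrix(table, cfg.feature_names)
    y = (table["label"].to_numpy() == "neuropathic").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("cohort must contain both classes")

    seed_seq = np.random.SeedSequence(cfg.seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(repeats)]

    n = len(table)
    sum_counts = np.zeros(4)  # tp, fp, tn, fn
    first_preds: list[str] = []
    chosen: list[float] = []
    for r, rseed in enumerate(repeat_seeds):
        pairs = []
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            c = _select_constraint(X[tr], y[tr], cfg, rseed + i)
            model = _make_pipeline(cfg, c)
            model.fit(X[tr], y[tr])
            pred = int(model.predict(X[i : i + 1])[0])
            true_lab = "neuropathic" if y[i] else "normal"
            pred_lab = "neuropathic" if pred else "normal"
            pairs.append((true_lab, pred_lab))
            if r == 0:
                first_preds.append(pred_lab)
                chosen.append(c)
        cc = confusion_from_predictions(pairs)
        sum_counts += np.array([cc.tp, cc.fp, cc.tn, cc.fn])
    mean_counts = sum_counts / repeats
    predictions = pd.DataFrame(
        {
            "subject_id": table["subject_id"],
            "true_label": table["label"],
            "predicted_label": first_preds,
        }
    )
    return LOOCVResult(
        predictions=predictions,
        counts=ConfusionCounts(*mean_counts),
        chosen_constraints=chosen,
        repeats=repeats,
    )


def compare_feature_sets(
    table: pd.DataFrame,
    sets=DEFAULT_FEATURE_SETS,
    cfg: ClassifierConfig = ClassifierConfig(),
    repeats: int = 1,
) -> dict[tuple[str, ...], LOOCVResult]:
    """One LOOCV evaluation per feature subset on the same subjects."""
    results = {}
    for names in sets:
        sub_cfg = ClassifierConfig(
            feature_names=tuple(names),
            kernel_scale=cfg.kernel_scale,
            box_constraint_grid=cfg.box_constraint_grid,
            inner_cv_folds=cfg.inner_cv_folds,
            standardize=cfg.standardize,
            seed=cfg.seed,
        )
        results[tuple(names)] = loocv_evaluate(table, sub_cfg, repeats=repeats)
    return results


def report_table(results: dict[tuple[str, ...], LOOCVResult]) -> pd.DataFrame:
    """Confusion counts and derived rates, one column per feature subset."""
    from .metrics import compute_metrics

    cols = {}
    for names, res in results.items():
        c = res.counts
        rep = compute_metrics(c)
        cols["+".join(names)] = {
            "TP": c.tp,
            "FN": c.fn,
            "FP": c.fp,
            "TN": c.tn,
            "Sn+": rep.sn_pos,
            "Sp+": rep.sp_pos,
            "Sn-": rep.sn_neg,
            "Sp-": rep.sp_neg,
            "Ac": rep.ac,
            "MCC": rep.mcc,
        }
    return pd.DataFrame(cols)
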