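"""Calibration/prediction split, classifier tuning, and the benchmark grid.

Three classifier families are tuned by k-fold cross-validated accuracy over
fixed hyperparameter grids:

* DT  — decision tree, minimum-leaf size ``minleaf`` in {1, 2, 4, ..., 64};
* KNN — k nearest neighbours, k in {1, 3, ..., 15};
* SVM — RBF kernel, penalty c in 2^-5..2^15 and kernel width g in 2^-15..2^3
  (one-vs-one multiclass voting).

Ties go to the simplest model (largest minleaf | smallest k | smallest c then
largest g).  Features are standardized with calibration statistics before
KNN/SVM; trees see raw features.  ``run_grid`` evaluates every combination of
pretreatment x band selector x classifier family on one shared 3:1
calibration/prediction split, reporting per-class and overall accuracies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .preprocess import make_preprocessor
from .selection import (
    NcaParams,
    RandomFrogParams,
    SelectionResult,
    nca_select,
    random_frog_select,
    spa_select,
)
from .table import SpectraTable

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "EvalReport",
    "default_spec",
    "split_calibration_prediction",
    "tune_train",
    "evaluate",
    "run_grid",
    "GridReport",
]

logger = logging.getLogger(__name__)

FAMILIES = ("DT", "KNN", "SVM")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family plus its tuning grid and CV settings."""

    family: str
    grid: Tuple[dict, ...]
    cv_folds: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if len(self.grid) == 0:
            raise ValueError("tuning grid must be nonempty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def default_spec(family: str, cv_folds: int = 5, rng_seed: int = 0) -> ModelSpec:
    """The default tuning grid for one family (tie-preferred points first)."""
    if family == "DT":
        # largest minleaf first: simplest tree wins ties
        grid = tuple({"minleaf": m} for m in (64, 32, 16, 8, 4, 2, 1))
    elif family == "KNN":
        grid = tuple({"k": k} for k in range(1, 16, 2))
    elif family == "SVM":
        grid = tuple(
            {"c": 2.0 ** pc, "g": 2.0 ** pg}
            for pc in range(-5, 16)          # smallest c first
            for pg in range(3, -16, -1)      # then largest g first
        )
    else:
        raise ValueError(f"unknown family {family!r}")
    return ModelSpec(family, grid, cv_folds=cv_folds, rng_seed=rng_seed)


@dataclass
class TrainedModel:
    """Fitted classifier with its tuning record and frozen scaling."""

    family: str
    best_params: dict
    cv_accuracy: float
    cv_record: List[Tuple[dict, float]]
    estimator: object
    classes: np.ndarray
    scaler_mean: Optional[np.ndarray] = None
    scaler_sd: Optional[np.ndarray] = None

    @property
    def parameter_label(self) -> str:
        """Tuned hyperparameters the way benchmark tables print them."""
        if self.family == "DT":
            return str(self.best_params["minleaf"])
        if self.family == "KNN":
            return str(self.best_params["k"])
        return f"({_fmt(self.best_params['c'])}, {_fmt(self.best_params['g'])})"

    def _features(self, x: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None:
            return x
        return (x - self.scaler_mean) / self.scaler_sd

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self._features(np.asarray(x, dtype=float)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "family": self.family,
            "best_params": self.best_params,
            "cv_accuracy": self.cv_accuracy,
            "classes": self.classes.tolist(),
        }, indent=2, sort_keys=True))


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def _make_estimator(family: str, params: dict, seed: int):
    if family == "DT":
        return DecisionTreeClassifier(min_samples_leaf=params["minleaf"],
                                      random_state=seed)
    if family == "KNN":
        return KNeighborsClassifier(n_neighbors=params["k"])
    return SVC(C=params["c"], gamma=params["g"], kernel="rbf",
               decision_function_shape="ovo")


def split_calibration_prediction(
    table: SpectraTable, ratio: Tuple[int, int] = (3, 1), seed: int = 0
) -> Tuple[SpectraTable, SpectraTable]:
    """Simple (non-stratified) random split into calibration and prediction.

    The calibration side gets ceil(n * cal / (cal + pred)) rows; with 400
    samples at 3:1 that is exactly 300/100.  Deterministic under ``seed``;
    realized per-class counts are logged.
    """
    cal_w, pred_w = ratio
    if cal_w < 1 or pred_w < 1:
        raise ValueError("ratio parts must be positive integers")
    n = table.n_samples
    n_cal = int(np.ceil(n * cal_w / (cal_w + pred_w)))
    if n_cal == 0 or n_cal == n:
        raise ValueError(f"split leaves an empty side (n={n}, ratio={ratio})")
    perm = np.random.default_rng(seed).permutation(n)
    cal = table.take_rows(np.sort(perm[:n_cal]))
    pred = table.take_rows(np.sort(perm[n_cal:]))
    if table.labels is not None:
        for name, part in (("calibration", cal), ("prediction", pred)):
            vals, cnts = np.unique(part.labels, return_counts=True)
            logger.info("%s set: n=%d, per-class %s", name, part.n_samples,
                        dict(zip(vals.tolist(), cnts.tolist())))
    return cal, pred


def _cv_folds(n: int, y: np.ndarray, cv_folds: int, seed: int):
    """Seeded k-fold partition whose training parts contain every class.

    Plain (unstratified) folds; if a fold's training side misses a class the
    partition is redrawn with seed+1, up to a bounded number of retries.
    """
    classes = np.unique(y)
    for attempt in range(10):
        folds = list(KFold(cv_folds, shuffle=True,
                           random_state=int((seed + attempt) % 2**31)).split(
                               np.empty(n)))
        if all(np.isin(classes, y[tr]).all() for tr, _ in folds):
            return folds
    raise ValueError(
        f"could not build {cv_folds} folds containing every class after 10 "
        "reseeds; more calibration samples per class are needed"
    )


def tune_train(cal: SpectraTable, spec: ModelSpec) -> TrainedModel:
    """Grid search by k-fold CV accuracy, then refit on all calibration rows.

    The grid is scanned in tie-preference order and the first maximum wins,
    implementing the simplest-model tie rule.
    """
    if cal.labels is None:
        raise ValueError("tuning needs labeled calibration rows")
    X, y = cal.x, cal.labels
    scaler_mean = scaler_sd = None
    if spec.family in ("KNN", "SVM"):
        scaler_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        scaler_sd = np.where(sd > 0, sd, 1.0)
        X = (X - scaler_mean) / scaler_sd
    folds = _cv_folds(X.shape[0], y, spec.cv_folds, spec.rng_seed)

    record: List[Tuple[dict, float]] = []
    best_acc, best_params = -1.0, None
    for params in spec.grid:
        correct = total = 0
        for train, test in folds:
            est = _make_estimator(spec.family, params, spec.rng_seed)
            est.fit(X[train], y[train])
            correct += int(np.sum(est.predict(X[test]) == y[test]))
            total += test.size
        acc = correct / total
        record.append((dict(params), acc))
        if acc > best_acc:
            best_acc, best_params = acc, dict(params)
    final = _make_estimator(spec.family, best_params, spec.rng_seed)
    final.fit(X, y)
    return TrainedModel(
        family=spec.family, best_params=best_params, cv_accuracy=best_acc,
        cv_record=record, estimator=final, classes=np.unique(y),
        scaler_mean=scaler_mean, scaler_sd=scaler_sd,
    )


@dataclass
class EvalReport:
    """Confusion matrix with overall and per-class accuracies (percent)."""

    confusion: np.ndarray
    classes: np.ndarray
    overall: float
    per_class: Dict[int, float]
    set_name: str

    def __str__(self) -> str:
        per = ", ".join(f"{c}: {a:.2f}%" for c, a in self.per_class.items())
        return (f"[{self.set_name}] overall {self.overall:.2f}% "
                f"(n={int(self.confusion.sum())}; per-class {per})")


def evaluate(model: TrainedModel, table: SpectraTable, set_name: str) -> EvalReport:
    """Confusion matrix and accuracies of the model on one labeled set."""
    if table.labels is None:
        raise ValueError("evaluation needs labeled rows")
    unseen = np.setdiff1d(np.unique(table.labels), model.classes)
    if unseen.size:
        raise ValueError(f"labels {unseen.tolist()} were not in training classes")
    pred = model.predict(table.x)
    cm = confusion_matrix(table.labels, pred, labels=model.classes)
    support = cm.sum(axis=1)
    overall = 100.0 * np.trace(cm) / cm.sum()
    per_class = {
        int(c): (100.0 * cm[i, i] / support[i] if support[i] else float("nan"))
        for i, c in enumerate(model.classes)
    }
    return EvalReport(cm, model.classes, float(overall), per_class, set_name)


# ---------------------------------------------------------------------------
# Benchmark grid
# ---------------------------------------------------------------------------

PREPROCESSORS = ("raw", "snv", "sg1", "msc")
SELECTORS = ("full", "spa", "frog", "nca")


@dataclass
class GridCell:
    preprocess: str
    selector: str
    family: str
    status: str = "ok"
    error: str = ""
    n_bands: int = 0
    parameter: str = ""
    cal_report: Optional[EvalReport] = None
    pred_report: Optional[EvalReport] = None


@dataclass
class GridReport:
    """Rows of the pretreatment x selector x classifier benchmark."""

    cells: List[GridCell]
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "preprocess": c.preprocess, "selector": c.selector,
                "family": c.family, "status": c.status,
                "n_bands": c.n_bands, "parameter": c.parameter,
            }
            if c.status == "ok":
                row["cal_overall"] = round(c.cal_report.overall, 2)
                for cls, acc in c.pred_report.per_class.items():
                    row[f"pred_class_{cls}"] = round(acc, 2)
                row["pred_overall"] = round(c.pred_report.overall, 2)
            else:
                row["error"] = c.error
            rows.append(row)
        return pd.DataFrame(rows)

    def cell(self, preprocess: str, selector: str, family: str) -> GridCell:
        for c in self.cells:
            if (c.preprocess, c.selector, c.family) == (preprocess, selector, family):
                return c
        raise KeyError((preprocess, selector, family))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _select_bands(
    cal_proc: SpectraTable, selector: str, seed: int,
    frog_params: Optional[RandomFrogParams],
    nca_params: Optional[NcaParams],
    spa_m_max: int,
) -> Tuple[np.ndarray, Optional[SelectionResult]]:
    if selector == "full":
        return np.arange(cal_proc.n_bands), None
    if selector == "spa":
        res = spa_select(cal_proc, m_max=spa_m_max, seed=seed)
    elif selector == "frog":
        params = frog_params or RandomFrogParams(rng_seed=seed)
        res = random_frog_select(cal_proc, params)
    elif selector == "nca":
        params = nca_params or NcaParams(rng_seed=seed)
        res = nca_select(cal_proc, params)
    else:
        raise ValueError(f"unknown selector {selector!r}")
    if res.n_selected == 0:
        raise ValueError(f"selector {selector} selected no bands: {res.warning}")
    return res.indices, res


def run_grid(
    table: SpectraTable,
    preprocessors: Sequence[str] = PREPROCESSORS,
    selectors: Sequence[str] = SELECTORS,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    ratio: Tuple[int, int] = (3, 1),
    frog_params: Optional[RandomFrogParams] = None,
    nca_params: Optional[NcaParams] = None,
    spa_m_max: int = 20,
    cv_folds: int = 5,
) -> GridReport:
    """Full benchmark: every pretreatment x selector x family combination.

    One shared calibration/prediction split; preprocessing state and band
    selection are fit on calibration rows only.  Selection depends only on
    (pretreatment, selector), so each such pair is computed once and shared
    across the classifier families.  Per-cell failures are recorded and the
    grid continues.
    """
    if not (len(preprocessors) and len(selectors) and len(families)):
        raise ValueError("factor lists must be nonempty")
    cal, pred = split_calibration_prediction(table, ratio=ratio, seed=seed)
    cells: List[GridCell] = []
    for prep_name in preprocessors:
        prep = make_preprocessor(prep_name).fit(cal)
        cal_p, pred_p = prep.apply(cal), prep.apply(pred)
        for sel_name in selectors:
            try:
                bands, _ = _select_bands(cal_p, sel_name, seed, frog_params,
                                         nca_params, spa_m_max)
            except Exception as exc:  # selector failure fails its 3 cells
                logger.warning("grid: selector %s/%s failed: %s",
                               prep_name, sel_name, exc)
                for family in families:
                    cells.append(GridCell(prep_name, sel_name, family,
                                          status="failed", error=str(exc)))
                continue
            cal_s, pred_s = cal_p.take_bands(bands), pred_p.take_bands(bands)
            for family in families:
                try:
                    model = tune_train(
                        cal_s, default_spec(family, cv_folds=cv_folds,
                                            rng_seed=seed))
                    cells.append(GridCell(
                        prep_name, sel_name, family,
                        n_bands=int(bands.size),
                        parameter=model.parameter_label,
                        cal_report=evaluate(model, cal_s, "calibration"),
                        pred_report=evaluate(model, pred_s, "prediction"),
                    ))
                except Exception as exc:
                    logger.warning("grid cell %s/%s/%s failed: %s",
                                   prep_name, sel_name, family, exc)
                    cells.append(GridCell(prep_name, sel_name, family,
                                          status="failed", error=str(exc)))
    return GridReport(cells, seed)
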