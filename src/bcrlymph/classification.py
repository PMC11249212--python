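"""Training protocol: stratified split, oversampling, CV grid search.

The protocol mirrors common practice for imbalanced multi-class
repertoire cohorts: an 80/20 stratified train/test split, random
oversampling of every non-majority class up to the majority count,
stratified 3-fold grid-search cross-validation selecting on weighted F1,
a final refit on the full (oversampled) training set and evaluation on
the held-out test set. Two model families are supported: multinomial
logistic regression with L2 penalty and a random forest. Oversampling
and feature scaling are re-fitted inside each CV training fold so that
duplicated samples and scaling statistics never leak into validation
folds.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ValidationError
from .featurization import ALLOWED_N, assemble_matrix, build_schema
from .repertoire_io import Repertoire

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("logistic", "forest")

#: Hyperparameter grids. `scaling` toggles standardization of numeric
#: features and is treated as an ordinary grid dimension.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "logistic": [
        {"C": c, "scaling": s}
        for c in (0.01, 0.1, 1.0, 10.0, 100.0)
        for s in (True, False)
    ],
    "forest": [
        {"n_estimators": t, "max_depth": d, "scaling": s}
        for t in (100, 300, 500)
        for d in (None, 10, 30)
        for s in (True, False)
    ],
}

#: The class combinations evaluated as scenarios.
SCENARIOS: dict[str, tuple[str, ...]] = {
    "HD-DLBCL-CLL": ("HD", "DLBCL", "CLL"),
    "HD-NLPBL-DLBCL": ("HD", "NLPBL", "DLBCL"),
    "HD-NLPBL-DLBCL-CLL": ("HD", "NLPBL", "DLBCL", "CLL"),
}


@dataclass
class Scenario:
    """A named class-combination plus the n values to sweep."""

    name: str
    classes: tuple[str, ...]
    n_values: tuple[int, ...] = (1, 3, 10)

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValidationError("a scenario needs at least two classes")
        bad = set(self.n_values) - ALLOWED_N
        if bad:
            raise ValidationError(f"n values {sorted(bad)} not allowed")


@dataclass
class SplitPlan:
    """Train/test sample ids per class for one stratified split."""

    train_ids: dict[str, list[str]]
    test_ids: dict[str, list[str]]
    test_fraction: float
    seed: int

    @property
    def train(self) -> list[str]:
        return [sid for ids in self.train_ids.values() for sid in ids]

    @property
    def test(self) -> list[str]:
        return [sid for ids in self.test_ids.values() for sid in ids]


@dataclass
class CVConfig:
    """Cross-validation settings: fold count, grids, seed."""

    k: int = 3
    grids: dict[str, list[dict]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRIDS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be at least 2")


@dataclass
class EvaluationReport:
    """Test-set evaluation of one fitted model."""

    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float
    weighted_f1: float
    confusion: pd.DataFrame
    model_family: str
    params: dict
    scenario: str = ""
    n_clonotypes: int | None = None
    zero_division_flagged: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "precision": self.precision[c],
                "recall": self.recall[c],
                "f1": self.f1[c],
                "support": self.support[c],
            }
            for c in self.classes
        ]
        return pd.DataFrame(rows)


def allocate_test_counts(
    class_sizes: dict[str, int], test_fraction: float
) -> dict[str, int]:
    """Per-class test-set sizes under the largest-remainder rule.

    Total test size is ``ceil(test_fraction * N)``. Each class first
    receives ``floor(test_fraction * size)`` seats; remaining seats go to
    the classes with the largest fractional remainders (ties favour the
    larger class, then class-name order).
    """
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie in (0, 1)")
    for label, size in class_sizes.items():
        if size < 1:
            raise ValidationError(f"class {label!r} has no samples")
    total = math.ceil(test_fraction * sum(class_sizes.values()))
    counts = {c: math.floor(test_fraction * s) for c, s in class_sizes.items()}
    remainders = {
        c: test_fraction * s - counts[c] for c, s in class_sizes.items()
    }
    seats = total - sum(counts.values())
    order = sorted(
        class_sizes,
        key=lambda c: (-remainders[c], -class_sizes[c], c),
    )
    for c in order[:seats]:
        counts[c] += 1
    return counts


def stratified_split(
    labels: pd.Series, test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Stratified train/test split preserving class proportions.

    ``labels`` maps sample id (index) to class. Within-class test
    membership is drawn uniformly at random from the given seed.
    """
    class_sizes = labels.value_counts().to_dict()
    counts = allocate_test_counts(class_sizes, test_fraction)
    rng = np.random.default_rng(np.random.SeedSequence(seed % 2**63))
    train_ids: dict[str, list[str]] = {}
    test_ids: dict[str, list[str]] = {}
    for label in sorted(class_sizes):
        ids = sorted(labels.index[labels == label])
        chosen = set(rng.choice(ids, size=counts[label], replace=False))
        test_ids[label] = [i for i in ids if i in chosen]
        train_ids[label] = [i for i in ids if i not in chosen]
    return SplitPlan(train_ids, test_ids, test_fraction, seed)


def random_oversample(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices resampling all classes but the majority up to its count.

    Original samples of every class are kept once; non-majority classes
    additionally receive samples drawn with replacement until all class
    counts equal the majority count.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.array([], dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    majority = counts.max()
    rng = np.random.default_rng(np.random.SeedSequence(seed % 2**63))
    out = [np.arange(labels.size)]
    for cls, count in zip(classes, counts):
        if count < majority:
            idx = np.flatnonzero(labels == cls)
            out.append(rng.choice(idx, size=majority - count, replace=True))
    return np.concatenate(out)


def make_estimator(family: str, params: dict, seed: int) -> Pipeline:
    """Build the (optionally scaling) pipeline for one grid point."""
    params = dict(params)
    scaling = params.pop("scaling", False)
    if family == "logistic":
        est = LogisticRegression(max_iter=5000, **params)
    elif family == "forest":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    else:
        raise ValidationError(
            f"unknown model family {family!r}; choose from {MODEL_FAMILIES}"
        )
    steps = []
    if scaling:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", est))
    return Pipeline(steps)


@dataclass
class GridSearchResult:
    family: str
    best_params: dict
    best_mean_f1: float
    table: pd.DataFrame


def grid_search_cv(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    family: str,
    cv: CVConfig,
) -> GridSearchResult:
    """Stratified k-fold grid search selecting on mean weighted F1.

    Folds are built on the raw training samples; oversampling (and, when
    requested, scaling) is fitted inside each fold's training part only.
    Ties between grid points break towards the earlier grid entry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grid = cv.grids.get(family)
    if not grid:
        raise ValidationError(f"no hyperparameter grid for family {family!r}")
    _, counts = np.unique(y, return_counts=True)
    if cv.k > counts.min():
        raise ValidationError(
            f"k={cv.k} exceeds the smallest class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed % 2**31)
    folds = list(skf.split(X, y))

    rows = []
    best: tuple[float, int] | None = None
    for gi, params in enumerate(grid):
        scores = []
        for fi, (tr, va) in enumerate(folds):
            os_idx = tr[random_oversample(y[tr], seed=cv.seed + 1000 * fi)]
            pipe = make_estimator(family, params, seed=cv.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # lbfgs convergence chatter
                pipe.fit(X[os_idx], y[os_idx])
            pred = pipe.predict(X[va])
            scores.append(f1_score(y[va], pred, average="weighted"))
        mean = float(np.mean(scores))
        rows.append({"family": family, **params, "mean_cv_f1": mean})
        if best is None or mean > best[0]:
            best = (mean, gi)
    assert best is not None
    return GridSearchResult(
        family=family,
        best_params=dict(grid[best[1]]),
        best_mean_f1=best[0],
        table=pd.DataFrame(rows),
    )


def fit_final_and_evaluate(
    X_train,
    y_train,
    X_test,
    y_test,
    family: str,
    params: dict,
    seed: int = 0,
) -> tuple[Pipeline, EvaluationReport]:
    """Refit on the full oversampled training set; score the test set.

    Per-class precision/recall/F1 with support, accuracy and the
    support-weighted F1. Undefined precision or recall (no predictions
    or no truth for a class) is reported as 0 and flagged.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValidationError("test set is empty")
    train_classes = set(np.unique(y_train))
    missing = set(np.unique(y_test)) - train_classes
    if missing:
        raise ValidationError(
            f"test classes absent from training: {sorted(missing)}"
        )
    os_idx = random_oversample(y_train, seed=seed)
    pipe = make_estimator(family, params, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs convergence chatter
        pipe.fit(X_train[os_idx], y_train[os_idx])
    pred = pipe.predict(X_test)

    classes = sorted(train_classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_test, pred, labels=classes, zero_division=0
    )
    flagged = bool(
        set(classes) - set(np.unique(pred)) or set(classes) - set(np.unique(y_test))
    )
    present = [c for c in classes if c in set(y_test)]
    report = EvaluationReport(
        classes=present,
        precision={c: float(p) for c, p in zip(classes, prec) if c in present},
        recall={c: float(r) for c, r in zip(classes, rec) if c in present},
        f1={c: float(v) for c, v in zip(classes, f1) if c in present},
        support={c: int(s) for c, s in zip(classes, support) if c in present},
        accuracy=float(accuracy_score(y_test, pred)),
        weighted_f1=float(f1_score(y_test, pred, average="weighted")),
        confusion=pd.DataFrame(
            confusion_matrix(y_test, pred, labels=classes),
            index=classes, columns=classes,
        ),
        model_family=family,
        params=dict(params),
        zero_division_flagged=flagged,
    )
    return pipe, report


def run_scenario(
    repertoires: list[Repertoire],
    scenario: Scenario,
    cv: CVConfig | None = None,
    families: tuple[str, ...] = MODEL_FAMILIES,
    test_fraction: float = 0.2,
) -> tuple[pd.DataFrame, dict[tuple[str, int], EvaluationReport], dict]:
    """Full split -> oversample -> CV -> final-fit sweep over n and family.

    Returns a tidy results table (scenario, model, n, mean CV F1, test
    weighted F1, chosen hyperparameters), the per-(family, n) evaluation
    reports, and the fitted model artifacts
    ``{(family, n): (schema, pipeline)}``.
    """
    cv = cv or CVConfig()
    present = {r.label for r in repertoires}
    missing = set(scenario.classes) - present
    if missing:
        raise ValidationError(
            f"scenario {scenario.name!r} requests class(es) absent from the "
            f"cohort: {sorted(missing)}"
        )
    reps = [r for r in repertoires if r.label in scenario.classes]
    labels = pd.Series(
        [r.label for r in reps], index=[r.sample_id for r in reps]
    )
    if labels.index.duplicated().any():
        raise ValidationError("duplicate sample ids in cohort")
    plan = stratified_split(labels, test_fraction, seed=cv.seed)
    by_id = {r.sample_id: r for r in reps}
    train_reps = [by_id[s] for s in plan.train]
    test_reps = [by_id[s] for s in plan.test]

    rows = []
    reports: dict[tuple[str, int], EvaluationReport] = {}
    models: dict[tuple[str, int], tuple] = {}
    for n, family in itertools.product(scenario.n_values, families):
        schema = build_schema(train_reps, n, scaling_enabled=False)
        X_tr, y_tr = assemble_matrix(train_reps, schema)
        X_te, y_te = assemble_matrix(test_reps, schema)
        search = grid_search_cv(X_tr, y_tr, family, cv)
        pipe, report = fit_final_and_evaluate(
            X_tr, y_tr, X_te, y_te, family, search.best_params, seed=cv.seed
        )
        report.scenario = scenario.name
        report.n_clonotypes = n
        reports[(family, n)] = report
        models[(family, n)] = (schema, pipe)
        rows.append({
            "scenario": scenario.name,
            "model": family,
            "n_clonotypes": n,
            "mean_cv_f1": search.best_mean_f1,
            "test_weighted_f1": report.weighted_f1,
            "test_accuracy": report.accuracy,
            "best_params": repr(search.best_params),
        })
        logger.info(
            "%s %s n=%d: cv F1 %.3f, test F1 %.3f",
            scenario.name, family, n, search.best_mean_f1, report.weighted_f1,
        )
    return pd.DataFrame(rows), reports, models
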