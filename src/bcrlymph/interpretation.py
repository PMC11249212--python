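"""Model interpretation: PCA + MANOVA group structure, predictor ranking.

Two complementary views of a fitted classification problem:

* an unsupervised one — project the feature matrix onto its first two
  principal components and test whether class mean vectors differ in
  that plane (Wilks' lambda MANOVA);
* a supervised one — rank features of a multinomial linear model by the
  mean absolute coefficient across classes, with signed per-class-pair
  contributions (the difference of the two classes' coefficients).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.pipeline import Pipeline
from statsmodels.multivariate.manova import MANOVA

from .errors import ValidationError

logger = logging.getLogger(__name__)


def pca_embed(
    X, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores with a fixed sign convention.

    The matrix is centered internally. Each component is oriented so
    that its largest-magnitude loading is positive, making the embedding
    reproducible across BLAS implementations.

    Returns ``(scores, explained_variance_ratio)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 features")
    if X.shape[0] < n_components:
        raise ValidationError(
            f"need at least {n_components} samples, got {X.shape[0]}"
        )
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    for c in range(n_components):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    return scores, pca.explained_variance_ratio_


@dataclass
class ManovaResult:
    """Wilks' lambda comparison of group mean vectors."""

    wilks_lambda: float
    f_statistic: float
    p_value: float
    df_num: float
    df_den: float
    degenerate: bool = False


def manova_groups(X, labels) -> ManovaResult:
    """MANOVA on a (typically 2-D) response matrix grouped by label.

    Each group must contain more samples than the response has
    dimensions. A singular within-group covariance yields a result
    flagged ``degenerate`` instead of an exception.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if X.shape[0] != labels.size:
        raise ValidationError("labels must match the rows of the matrix")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need at least two groups")
    p = X.shape[1]
    if counts.min() <= p:
        raise ValidationError(
            f"every group needs more than {p} samples "
            f"(smallest group has {counts.min()})"
        )
    data = pd.DataFrame(X, columns=[f"y{i}" for i in range(p)])
    data["group"] = labels
    formula = " + ".join(data.columns[:-1]) + " ~ C(group)"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MANOVA.from_formula(formula, data=data).mv_test()
        table = res.results["C(group)"]["stat"]
        row = table.loc["Wilks' lambda"]
        return ManovaResult(
            wilks_lambda=float(row["Value"]),
            f_statistic=float(row["F Value"]),
            p_value=float(row["Pr > F"]),
            df_num=float(row["Num DF"]),
            df_den=float(row["Den DF"]),
        )
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("MANOVA degenerate: %s", exc)
        return ManovaResult(
            wilks_lambda=np.nan, f_statistic=np.nan, p_value=np.nan,
            df_num=np.nan, df_den=np.nan, degenerate=True,
        )


@dataclass
class PredictorRanking:
    """Top-k features by mean absolute coefficient across classes."""

    ranking: pd.DataFrame  # columns: feature, score
    pairwise: pd.DataFrame  # columns: class_a, class_b, feature, contribution
    k: int


def _coefficients(model) -> tuple[np.ndarray, list[str]]:
    if isinstance(model, Pipeline):
        model = model.named_steps["model"]
    coef = np.asarray(model.coef_, dtype=float)
    classes = [str(c) for c in model.classes_]
    if coef.shape[0] == 1 and len(classes) == 2:
        # binary fit stores one row: w for classes_[1], -w for classes_[0]
        coef = np.vstack([-coef[0], coef[0]])
    return coef, classes


def rank_predictors(model, feature_names: list[str], k: int = 20) -> PredictorRanking:
    """Coefficient-magnitude ranking of a multinomial linear model.

    ``score(feature) = mean over classes of |coefficient|``; the top-k
    features are returned in non-increasing score order (ties by feature
    name). The pairwise table holds, for each unordered class pair, the
    signed contribution ``coef_a - coef_b`` of every ranked feature: a
    positive value pushes a sample towards class ``a``.
    """
    coef, classes = _coefficients(model)
    if coef.shape[1] != len(feature_names):
        raise ValidationError(
            f"model has {coef.shape[1]} coefficients but "
            f"{len(feature_names)} feature names were given"
        )
    if k > len(feature_names):
        warnings.warn(
            f"k={k} exceeds the {len(feature_names)} available features; "
            "clipping", stacklevel=2,
        )
        k = len(feature_names)
    scores = np.abs(coef).mean(axis=0)
    order = sorted(
        range(len(feature_names)),
        key=lambda i: (-scores[i], feature_names[i]),
    )[:k]
    ranking = pd.DataFrame({
        "feature": [feature_names[i] for i in order],
        "score": [float(scores[i]) for i in order],
    })
    rows = []
    for a, b in itertools.combinations(range(len(classes)), 2):
        for i in order:
            rows.append({
                "class_a": classes[a],
                "class_b": classes[b],
                "feature": feature_names[i],
                "contribution": float(coef[a, i] - coef[b, i]),
            })
    return PredictorRanking(
        ranking=ranking, pairwise=pd.DataFrame(rows), k=k
    )


def rank_importances(model, feature_names: list[str], k: int = 20) -> pd.DataFrame:
    """Impurity-importance ranking for tree ensembles (no pairwise view)."""
    if isinstance(model, Pipeline):
        model = model.named_steps["model"]
    imp = np.asarray(model.feature_importances_, dtype=float)
    k = min(k, len(feature_names))
    order = sorted(
        range(len(feature_names)), key=lambda i: (-imp[i], feature_names[i])
    )[:k]
    return pd.DataFrame({
        "feature": [feature_names[i] for i in order],
        "importance": [float(imp[i]) for i in order],
    })
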