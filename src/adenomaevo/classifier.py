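"""Random-forest discrimination of adenoma (CRA) versus carcinoma (CRC).

A forest is grown on the binary gene-by-patient mutation matrix; variable
importance uses minimal depth -- the depth of the first split on a variable
within a tree. Informative variables split near the root, so a small mean
minimal depth marks importance. The selection threshold comes from the
analytic null distribution of minimal depth for an uninformative variable
in trees of the observed shapes (a variable picked uniformly at random at
each internal node): either the null mean (default) or its 5th percentile
(stricter). A reduced forest restricted to the selected genes is then
evaluated by AUC (out-of-bag vote fractions on the discovery set, to avoid
optimism), AUCPR and the out-of-bag error rate.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score

from .variant_io import GeneMatrix


@dataclasses.dataclass
class ForestModel:
    estimator: RandomForestClassifier
    genes: list[str]
    seed: int
    n_trees: int
    positive_class: str
    classes: list[str]
    train_index: pd.Index
    mean_min_depth: pd.Series  # per gene
    oob_scores: np.ndarray  # P(positive class), OOB, aligned to train_index
    oob_error: float
    selected_genes: list[str] | None = None


def _extract_features(matrix: GeneMatrix, genes: list[str] | None = None) -> pd.DataFrame:
    x = matrix.values if genes is None else matrix.values[list(genes)]
    return x.astype(float)


def _tree_min_depths(tree, n_features: int) -> tuple[np.ndarray, int, np.ndarray]:
    """Per-feature minimal split depth in one tree.

    Returns (min_depth per feature with unused = max depth penalty,
    max node depth, internal-node count per depth level).
    """
    t = tree.tree_
    left, right, feature = t.children_left, t.children_right, t.feature
    depths = np.zeros(t.node_count, dtype=int)
    stack = [0]
    while stack:
        node = stack.pop()
        for child in (left[node], right[node]):
            if child != -1:
                depths[child] = depths[node] + 1
                stack.append(child)
    max_depth = int(depths.max()) if t.node_count > 1 else 0
    internal = left != -1
    counts = np.bincount(depths[internal], minlength=max_depth + 1)

    min_depth = np.full(n_features, max_depth, dtype=float)
    for node in np.flatnonzero(internal):
        f = feature[node]
        if depths[node] < min_depth[f]:
            min_depth[f] = depths[node]
    return min_depth, max_depth, counts


def _null_moments(counts: np.ndarray, max_depth: int, p: int) -> tuple[float, float]:
    """Mean and variance of minimal depth for an uninformative variable.

    Under the null the variable is chosen at each internal node with
    probability 1/p; minimal depth is capped at the tree's max depth.
    P(X >= d) = prod_{d' < d} (1 - 1/p)^{L_{d'}}.
    """
    if max_depth == 0:
        return 0.0, 0.0
    log_miss = np.log1p(-1.0 / p)
    cum = np.cumsum(counts[:max_depth]) * log_miss
    survival = np.exp(cum)  # P(X >= d) for d = 1..max_depth
    mean = float(survival.sum())
    ex2 = float(((2 * np.arange(1, max_depth + 1) - 1) * survival).sum())
    return mean, max(0.0, ex2 - mean**2)


def fit_forest(
    matrix: GeneMatrix,
    labels: pd.Series,
    seed: int,
    n_trees: int = 1000,
    positive_class: str = "CRC",
    genes: list[str] | None = None,
) -> ForestModel:
    """Grow a random forest on the binary mutation matrix.

    ``labels`` maps each patient to its class (two classes required, each
    with >= 2 patients). Deterministic given ``seed``.
    """
    x = _extract_features(matrix, genes)
    y = labels.reindex(x.index)
    if y.isna().any():
        raise ValueError("labels missing for some patients")
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if (y.value_counts() < 2).any():
        raise ValueError("need >= 2 patients per class")
    if positive_class not in classes:
        positive_class = classes[-1]

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        rf.fit(x.to_numpy(), y.to_numpy())

    n_features = x.shape[1]
    depth_sum = np.zeros(n_features)
    null_mean_sum = 0.0
    null_var_sum = 0.0
    for est in rf.estimators_:
        md, max_depth, counts = _tree_min_depths(est, n_features)
        depth_sum += md
        m, v = _null_moments(counts, max_depth, n_features)
        null_mean_sum += m
        null_var_sum += v
    mean_min_depth = pd.Series(depth_sum / n_trees, index=x.columns)

    oob = rf.oob_decision_function_
    pos_col = list(rf.classes_).index(positive_class)
    oob_scores = oob[:, pos_col]
    valid = ~np.isnan(oob_scores)
    predicted = np.asarray(rf.classes_)[np.nanargmax(np.nan_to_num(oob, nan=-1), axis=1)]
    oob_error = float(np.mean(predicted[valid] != y.to_numpy()[valid]))

    model = ForestModel(
        estimator=rf,
        genes=list(x.columns),
        seed=seed,
        n_trees=n_trees,
        positive_class=positive_class,
        classes=classes,
        train_index=x.index,
        mean_min_depth=mean_min_depth,
        oob_scores=oob_scores,
        oob_error=oob_error,
    )
    # stash null moments for the selection threshold
    model._null_mean = null_mean_sum / n_trees
    model._null_sd_of_mean = float(np.sqrt(null_var_sum) / n_trees)
    return model


def minimal_depth_select(model: ForestModel, threshold_rule: str = "mean") -> list[str]:
    """Select genes whose mean minimal depth beats the uninformative null.

    ``threshold_rule``: 'mean' selects genes below the null's expected mean
    minimal depth; 'p05' uses the null's 5th percentile of the tree-averaged
    statistic (normal approximation), a stricter cut.
    """
    if not hasattr(model, "_null_mean"):
        raise ValueError("model lacks minimal-depth records")
    if threshold_rule == "mean":
        threshold = model._null_mean
    elif threshold_rule == "p05":
        threshold = model._null_mean - 1.6449 * model._null_sd_of_mean
    else:
        raise ValueError("threshold_rule must be 'mean' or 'p05'")
    selected = [g for g in model.genes if model.mean_min_depth[g] < threshold]
    model.selected_genes = selected
    return selected


def reduced_model(
    matrix: GeneMatrix,
    labels: pd.Series,
    selected_genes: list[str],
    seed: int,
    n_trees: int = 1000,
    positive_class: str = "CRC",
) -> ForestModel:
    """Refit the forest on the selected genes only."""
    if not selected_genes:
        raise ValueError("empty gene selection")
    return fit_forest(
        matrix, labels, seed=seed, n_trees=n_trees,
        positive_class=positive_class, genes=selected_genes,
    )


def auc_rank(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic; tied scores count 0.5."""
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclasses.dataclass
class EvalReport:
    auc: float
    aucpr: float
    oob_error: float
    dataset: str


def evaluate(
    model: ForestModel,
    matrix: GeneMatrix,
    labels: pd.Series,
    dataset: str = "discovery",
) -> EvalReport:
    """Score a dataset with the fitted forest.

    When ``matrix`` is the training set itself, out-of-bag vote fractions
    are used (honest discovery-set performance); otherwise plain predicted
    vote fractions.
    """
    x = _extract_features(matrix, model.genes)
    y = labels.reindex(x.index)
    if y.isna().any():
        raise ValueError("labels missing for some patients")
    if y.nunique() < 2:
        raise ValueError("evaluation set must contain both classes")

    is_training = x.index.equals(model.train_index)
    if is_training:
        scores = model.oob_scores
        valid = ~np.isnan(scores)
        scores = scores[valid]
        y_eval = y.to_numpy()[valid]
    else:
        pos_col = list(model.estimator.classes_).index(model.positive_class)
        scores = model.estimator.predict_proba(x.to_numpy())[:, pos_col]
        y_eval = y.to_numpy()
    is_pos = y_eval == model.positive_class
    return EvalReport(
        auc=auc_rank(scores, is_pos),
        aucpr=float(average_precision_score(is_pos, scores)),
        oob_error=model.oob_error,
        dataset=dataset,
    )
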