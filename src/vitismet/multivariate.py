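"""Unsupervised structure and OPLS-DA classification with permutation significance.

PCA and Ward/Euclidean hierarchical clustering describe the sample
structure; the supervised arm is a two-class orthogonal projections to
latent structures discriminant analysis (OPLS-DA, Trygg & Wold style)
whose decision rule is the sign of the predicted encoded label.  Model
quality is assessed by stratified k-fold cross-validation (accuracy,
R2Y, Q2Y) and significance by a label-permutation test on the
cross-validated accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.model_selection import StratifiedKFold

from .peaks import FeatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    scores: np.ndarray              # samples x components
    loadings: np.ndarray            # features x components
    explained_variance_fraction: np.ndarray
    n_retained: int
    sample_ids: list[str] = field(default_factory=list)


def pca(m: FeatureMatrix, variance_threshold: float = 0.95) -> PcaResult:
    """Exact PCA of the sample x feature matrix via SVD of the centered data.

    ``n_retained`` is the smallest number of leading components whose
    cumulative explained-variance fraction reaches the threshold.
    """
    m.require_stage("pareto")
    if m.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    x = m.data.to_numpy().T  # samples x features
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("matrix has zero total variance")
    frac = var / total
    cumulative = np.cumsum(frac)
    n_retained = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    return PcaResult(
        scores=u * s,
        loadings=vt.T,
        explained_variance_fraction=frac,
        n_retained=n_retained,
        sample_ids=m.sample_ids,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering

@dataclass
class LinkageTree:
    merges: np.ndarray          # scipy linkage matrix
    labels: list[str]
    metric: str = "euclidean"
    method: str = "ward"

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with height-difference branch lengths."""
        root = to_tree(self.merges)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"

    def cut(self, n_clusters: int) -> np.ndarray:
        from scipy.cluster.hierarchy import fcluster
        return fcluster(self.merges, t=n_clusters, criterion="maxclust")


def hierarchical_cluster(m: FeatureMatrix) -> LinkageTree:
    """Agglomerative Ward clustering of samples under Euclidean distance."""
    m.require_stage("pareto")
    if m.n_samples < 2:
        raise ValueError("clustering requires at least 2 samples")
    x = m.data.to_numpy().T
    merges = linkage(x, method="ward", metric="euclidean")
    return LinkageTree(merges=merges, labels=m.sample_ids)


# ---------------------------------------------------------------------------
# OPLS-DA

@dataclass
class OplsdaModel:
    """Fitted two-class OPLS-DA model.

    The predictive component is the y-covariance direction of the
    orthogonal-filtered training data; each orthogonal component captures
    the largest remaining y-orthogonal variation.  Classes are encoded
    +1/-1 (first class in sorted order -> +1) and prediction is by the
    sign of the predicted encoded label.
    """

    w: np.ndarray                   # predictive weights, unit norm
    p: np.ndarray                   # predictive loadings
    t: np.ndarray                   # predictive training scores
    q: float                        # y loading
    w_orth: np.ndarray              # n_orth x features
    p_orth: np.ndarray
    t_orth: np.ndarray              # samples x n_orth
    x_mean: np.ndarray
    y_mean: float
    n_orthogonal: int
    classes: tuple = ("+1", "-1")   # label for +1, label for -1


def encode_labels(y) -> tuple[np.ndarray, tuple]:
    """Encode a two-class label vector as +1/-1 (sorted-first class -> +1)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.size}")
    enc = np.where(y == classes[0], 1.0, -1.0)
    return enc, (classes[0], classes[1])


def fit_oplsda(x: np.ndarray, y, n_orthogonal: int = 1) -> OplsdaModel:
    """Fit an OPLS-DA model with one predictive and ``n_orthogonal`` components.

    With ``n_orthogonal=0`` the model is exactly a one-component PLS-DA.
    """
    x = np.asarray(x, dtype=float)
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    enc, classes = encode_labels(y)
    if x.shape[0] != enc.size:
        raise ValueError("x and y have different numbers of samples")
    if n_orthogonal >= min(x.shape):
        raise ValueError("n_orthogonal must be below the rank of x")

    x_mean = x.mean(axis=0)
    y_mean = float(enc.mean())
    xc = x - x_mean
    yc = enc - y_mean

    w = xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("x has no covariance with y (zero-variance input?)")
    w = w / norm

    xd = xc.copy()
    w_orths, p_orths, t_orths = [], [], []
    for _ in range(n_orthogonal):
        t = xd @ w
        p = xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-12:
            raise ValueError("no y-orthogonal variation left to extract")
        w_o = w_o / norm_o
        t_o = xd @ w_o
        p_o = xd.T @ t_o / (t_o @ t_o)
        xd = xd - np.outer(t_o, p_o)
        w_orths.append(w_o)
        p_orths.append(p_o)
        t_orths.append(t_o)

    t = xd @ w
    tt = t @ t
    if tt == 0:
        raise ValueError("degenerate predictive scores")
    p = xd.T @ t / tt
    q = float(yc @ t / tt)

    n_feat = x.shape[1]
    return OplsdaModel(
        w=w, p=p, t=t, q=q,
        w_orth=np.array(w_orths).reshape(n_orthogonal, n_feat),
        p_orth=np.array(p_orths).reshape(n_orthogonal, n_feat),
        t_orth=(np.column_stack(t_orths) if t_orths
                else np.empty((x.shape[0], 0))),
        x_mean=x_mean, y_mean=y_mean,
        n_orthogonal=n_orthogonal, classes=classes,
    )


def predict_oplsda(model: OplsdaModel, x_new: np.ndarray):
    """Predict labels and continuous scores for new samples.

    Returns (labels, y_hat).  The decision rule is sign(y_hat); exact
    ties (y_hat == 0) are assigned the +1 class and logged.
    """
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != model.w.size:
        raise ValueError(
            f"feature count mismatch: model has {model.w.size}, got {x_new.shape[1]}"
        )
    xc = x_new - model.x_mean
    for i in range(model.n_orthogonal):
        t_o = xc @ model.w_orth[i]
        xc = xc - np.outer(t_o, model.p_orth[i])
    y_hat = (xc @ model.w) * model.q + model.y_mean
    ties = y_hat == 0
    if ties.any():
        logger.info("predict_oplsda: %d exact ties assigned to the +1 class",
                    int(ties.sum()))
    signs = np.where(y_hat > 0, 0, 1)
    signs[ties] = 0
    labels = np.asarray(model.classes, dtype=object)[signs]
    return labels, y_hat


def training_r2y(model: OplsdaModel, x: np.ndarray, y) -> float:
    enc, _ = encode_labels(y)
    _, y_hat = predict_oplsda(model, x)
    ss_res = float(np.sum((enc - y_hat) ** 2))
    ss_tot = float(np.sum((enc - enc.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# cross-validation and permutation significance

@dataclass
class CvReport:
    accuracy: float
    r2y: float
    q2y: float
    k: int
    fold_assignments: np.ndarray
    predictions: np.ndarray         # pooled held-out continuous predictions
    predicted_labels: np.ndarray


@dataclass
class PermutationResult:
    observed_accuracy: float
    permuted_accuracies: np.ndarray
    n_permutations: int
    p_value: float
    seed: int


def _scale_fold(train: np.ndarray, test: np.ndarray, scale: str):
    """Center (and optionally Pareto-scale) using training-fold statistics only."""
    if scale == "none":
        return train, test
    mean = train.mean(axis=0)
    if scale == "center":
        return train - mean, test - mean
    if scale == "pareto":
        sd = train.std(axis=0, ddof=1)
        denom = np.sqrt(sd)
        denom[denom == 0] = 1.0
        return (train - mean) / denom, (test - mean) / denom
    raise ValueError(f"unknown scale {scale!r}")


def stratified_cv(
    x: np.ndarray,
    y,
    k: int = 7,
    n_orthogonal: int = 1,
    seed: int = 0,
    scale: str = "pareto",
) -> CvReport:
    """Stratified k-fold cross-validation of the OPLS-DA classifier.

    Accuracy is pooled correct/total over held-out folds; R2Y comes from
    the full-data fit; Q2Y = 1 - PRESS/SS_tot from pooled held-out
    predictions of the encoded labels.  Centering/scaling statistics are
    computed inside each training fold only (``scale='none'`` for
    pre-scaled input).  Fold assignment depends only on (seed, y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    enc, _ = encode_labels(y)
    min_class = int(min(np.sum(enc > 0), np.sum(enc < 0)))
    if min_class < k:
        warnings.warn(f"reducing k from {k} to {min_class}: smallest class size")
        k = min_class
    if k < 2:
        raise ValueError("smallest class has fewer than 2 members")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    y_hat = np.empty(len(y))
    labels_hat = np.empty(len(y), dtype=object)
    for fold, (tr, te) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[te] = fold
        x_tr, x_te = _scale_fold(x[tr], x[te], scale)
        model = fit_oplsda(x_tr, y[tr], n_orthogonal=n_orthogonal)
        lab, pred = predict_oplsda(model, x_te)
        y_hat[te] = pred
        labels_hat[te] = lab

    accuracy = float(np.mean(labels_hat == y))
    press = float(np.sum((enc - y_hat) ** 2))
    ss_tot = float(np.sum((enc - enc.mean()) ** 2))
    q2y = 1.0 - press / ss_tot

    x_all, _ = _scale_fold(x, x[:0], scale)
    full = fit_oplsda(x_all, y, n_orthogonal=n_orthogonal)
    r2y = training_r2y(full, x_all, y)

    return CvReport(accuracy=accuracy, r2y=r2y, q2y=q2y, k=k,
                    fold_assignments=folds, predictions=y_hat,
                    predicted_labels=labels_hat)


def permutation_test(
    x: np.ndarray,
    y,
    k: int = 7,
    n_orthogonal: int = 1,
    n_permutations: int = 1000,
    seed: int = 0,
    scale: str = "pareto",
) -> PermutationResult:
    """Label-permutation significance of the cross-validated accuracy.

    Each permutation shuffles the labels, reruns the full stratified CV
    and records its accuracy.  p = (1 + #{permuted >= observed}) /
    (1 + n_permutations) — ties count against significance and p is
    never exactly zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(y)
    observed = stratified_cv(x, y, k=k, n_orthogonal=n_orthogonal,
                             seed=seed, scale=scale).accuracy
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        permuted[i] = stratified_cv(
            x, y_perm, k=k, n_orthogonal=n_orthogonal, seed=seed, scale=scale
        ).accuracy
    p = (1.0 + float(np.sum(permuted >= observed))) / (1.0 + n_permutations)
    return PermutationResult(observed_accuracy=observed,
                             permuted_accuracies=permuted,
                             n_permutations=n_permutations,
                             p_value=p, seed=seed)


def component_sweep(
    x: np.ndarray, y, k: int = 7, max_orthogonal: int = 5, seed: int = 0,
    scale: str = "pareto",
) -> pd.DataFrame:
    """Accuracy/R2Y/Q2Y as a function of the number of orthogonal components."""
    rows = []
    for n_orth in range(max_orthogonal + 1):
        rep = stratified_cv(x, y, k=k, n_orthogonal=n_orth, seed=seed, scale=scale)
        rows.append((n_orth, rep.accuracy, rep.r2y, rep.q2y))
    return pd.DataFrame(rows, columns=["n_orthogonal", "accuracy", "r2y", "q2y"])
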