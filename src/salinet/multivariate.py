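"""PerMANOVA and a multivariate regression tree (MRT) on environmental
predictors.

PerMANOVA partitions the total sum of squared dissimilarities among and
within groups and tests the pseudo-F by whole-label permutation.  On
Euclidean distances of univariate data the pseudo-F reduces exactly to the
classical one-way ANOVA F, which the test suite uses as an oracle.

The MRT recursively partitions the (Hellinger-transformed) community
matrix by environmental thresholds, minimising the within-node sum of
squared deviations about node centroids; tree size is chosen by minimum
10-fold cross-validated relative error over the cost-complexity pruning
path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .diversity import hellinger
from .io import ValidationError

__all__ = ["permanova", "PermanovaResult", "MultivariateRegressionTree", "mrt_fit"]


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    r_squared: float
    n_permutations: int
    group_sizes: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "pseudo_f": self.pseudo_f,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "n_permutations": self.n_permutations,
            "group_sizes": dict(self.group_sizes),
        }


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


def permanova(
    dist,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``dist`` may be a skbio DistanceMatrix or a square ndarray; ``groups``
    a sequence of labels aligned with its rows (or a pandas Series indexed
    by the matrix ids).
    """
    if isinstance(dist, DistanceMatrix):
        ids = list(dist.ids)
        d = dist.data
        if isinstance(groups, pd.Series):
            labels = groups.loc[ids].to_numpy()
        else:
            labels = np.asarray(list(groups))
    else:
        d = np.asarray(dist, dtype=float)
        labels = np.asarray(list(groups))
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValidationError("group labels do not align with the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs at least 2 samples")
    g = len(uniq)
    d2 = d.astype(float) ** 2
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    if ss_total == 0:
        raise ValidationError("all samples identical: PerMANOVA undefined")
    ss_w = _ss_within(d2, labels, uniq)
    if ss_w == 0:
        warnings.warn("zero within-group dispersion: pseudo-F infinite")
        return PermanovaResult(
            pseudo_f=float("inf"),
            p_value=1.0 / (n_perm + 1),
            r_squared=1.0,
            n_permutations=n_perm,
            group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
        )
    f_obs = ((ss_total - ss_w) / (g - 1)) / (ss_w / (n - g))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(n)]
        ss_wp = _ss_within(d2, perm_labels, uniq)
        if ss_wp == 0:
            hits += 1
            continue
        f_p = ((ss_total - ss_wp) / (g - 1)) / (ss_wp / (n - g))
        hits += f_p >= f_obs
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=(1 + hits) / (1 + n_perm),
        r_squared=float((ss_total - ss_w) / ss_total),
        n_permutations=n_perm,
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
    )


# ---------------------------------------------------------------------------
# multivariate regression tree


def _sstot(Y: np.ndarray) -> float:
    return float(((Y - Y.mean(axis=0)) ** 2).sum())


class MultivariateRegressionTree:
    """De'ath-style multivariate regression tree.

    An sklearn-flavoured estimator: construct with hyper-parameters, call
    :meth:`fit` with an environmental frame and a multivariate response,
    then read fitted attributes (``splits_``, ``explained_variance_``,
    ``cv_error_``, ``cv_se_``, ``leaf_assignments_``).

    The split engine is a multi-output CART regressor (squared-error
    criterion == within-node SS about centroids; thresholds are midpoints
    of consecutive observed values).  Size selection refits over the
    cost-complexity pruning path and keeps the alpha with the smallest
    cross-validated relative error (ties -> the smaller tree).
    """

    def __init__(self, max_depth: int | None = None, cv_folds: int = 10,
                 min_samples_leaf: int = 2, random_state: int = 0):
        self.max_depth = max_depth
        self.cv_folds = cv_folds
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "max_depth": self.max_depth,
            "cv_folds": self.cv_folds,
            "min_samples_leaf": self.min_samples_leaf,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _root_only(self, X: pd.DataFrame, Y: np.ndarray):
        self.splits_ = []
        self.n_leaves_ = 1
        self.explained_variance_ = 0.0
        self.alpha_ = float("inf")
        self.leaf_assignments_ = pd.Series(0, index=X.index, name="leaf")
        self.tree_ = None
        return self

    def fit(self, X: pd.DataFrame, Y):
        """Fit to environmental predictors ``X`` and response matrix ``Y``."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        X = X.loc[:, [c for c in X.columns if np.issubdtype(X[c].dtype, np.number)]]
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        if constant:
            X = X.drop(columns=constant)
        if X.shape[1] == 0:
            raise ValidationError("no usable (non-constant numeric) environmental variables")
        n = X.shape[0]
        if n < 2 * self.min_samples_leaf:
            raise ValidationError("too few samples for the requested leaf size")
        sstot = _sstot(Y)
        self.feature_names_ = list(X.columns)
        if self.max_depth == 0 or sstot == 0:
            return self._root_only(X, Y)

        def make_tree(alpha=0.0):
            return DecisionTreeRegressor(
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                ccp_alpha=alpha,
                random_state=self.random_state,
            )

        Xv = X.to_numpy(dtype=float)
        full = make_tree().fit(Xv, Y)
        path = full.cost_complexity_pruning_path(Xv, Y)
        alphas = np.unique(path.ccp_alphas)

        folds = min(self.cv_folds, n)
        kf = KFold(n_splits=folds, shuffle=True, random_state=self.random_state)
        fold_err = np.zeros((len(alphas), folds))
        fold_w = np.zeros(folds)
        for j, (tr, te) in enumerate(kf.split(Xv)):
            sst_te = ((Y[te] - Y[tr].mean(axis=0)) ** 2).sum()
            fold_w[j] = sst_te
            for i, a in enumerate(alphas):
                m = make_tree(a).fit(Xv[tr], Y[tr])
                fold_err[i, j] = ((Y[te] - m.predict(Xv[te]).reshape(len(te), -1)) ** 2).sum()
        cv_rel = fold_err.sum(axis=1) / fold_w.sum()
        # ties go to the larger alpha, i.e. the smaller tree
        best = len(alphas) - 1 - int(np.argmin(cv_rel[::-1]))
        self.alpha_ = float(alphas[best])
        self.cv_error_ = float(cv_rel[best])
        rel_by_fold = fold_err[best] / np.where(fold_w > 0, fold_w, 1.0)
        self.cv_se_ = float(rel_by_fold.std(ddof=1) / np.sqrt(folds)) if folds > 1 else 0.0
        self.cv_path_ = pd.DataFrame({"alpha": alphas, "cv_relative_error": cv_rel})

        model = make_tree(self.alpha_).fit(Xv, Y)
        self.tree_ = model
        t = model.tree_
        self.n_leaves_ = int(model.get_n_leaves())
        self.splits_ = [
            {
                "node": int(i),
                "variable": self.feature_names_[t.feature[i]],
                "threshold": float(t.threshold[i]),
            }
            for i in range(t.node_count)
            if t.children_left[i] != -1
        ]
        pred = model.predict(Xv).reshape(n, -1)
        self.explained_variance_ = float(1.0 - ((Y - pred) ** 2).sum() / sstot)
        self.leaf_assignments_ = pd.Series(model.apply(Xv), index=X.index, name="leaf")
        if self.n_leaves_ == 1:
            self.splits_ = []
            self.explained_variance_ = 0.0
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.tree_ is None:
            raise ValidationError("root-only tree: predictions are the grand mean")
        return self.tree_.predict(X[self.feature_names_].to_numpy(dtype=float))

    def to_dict(self) -> dict:
        return {
            "splits": self.splits_,
            "n_leaves": self.n_leaves_,
            "explained_variance": self.explained_variance_,
            "cv_error": getattr(self, "cv_error_", None),
            "cv_se": getattr(self, "cv_se_", None),
        }


def mrt_fit(
    table: pd.DataFrame,
    env: pd.DataFrame,
    max_depth: int | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    transform: str = "hellinger",
) -> MultivariateRegressionTree:
    """Fit an MRT of the community matrix on the numeric environmental
    variables.  ``transform`` is ``"hellinger"`` (default) or
    ``"proportion"`` for raw relative abundances."""
    if transform == "hellinger":
        Y = hellinger(table).to_numpy()
    elif transform == "proportion":
        x = table.to_numpy(dtype=float)
        Y = x / np.where(x.sum(axis=1, keepdims=True) == 0, 1, x.sum(axis=1, keepdims=True))
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    X = env.loc[table.index].drop(columns=["group"], errors="ignore")
    model = MultivariateRegressionTree(max_depth=max_depth, cv_folds=cv_folds,
                                       random_state=seed)
    return model.fit(X, Y)
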