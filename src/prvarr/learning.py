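"""Random-forest feature ranking, selection, and the three classifiers.

Feature importance is scored two ways on a bagged forest of CART trees:
*mean decrease in accuracy* (out-of-bag permutation importance: how much
each tree's OOB accuracy drops when one feature column is shuffled) and
*mean decrease in Gini* (total impurity decrease attributed to splits on
the feature, averaged over trees).  The top-``k`` features by combined
rank are kept.

Three classifiers over the 5 rhythm classes are provided: a CART decision
tree grown to purity, an extreme learning machine (random fixed input
weights, sinusoidal hidden layer, least-squares output weights via the
pseudo-inverse) and a back-propagation network (two sigmoid hidden
layers, quasi-Newton training).  All are wrapped in a
:class:`TrainedModel` that carries the feature schema, imputes missing
feature sentinels with training-set medians, and is deterministic under
its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ImportanceTable",
    "TrainedModel",
    "rf_importance",
    "select_features",
    "train_dt",
    "train_elm",
    "train_bpnn",
    "predict",
]


@dataclass
class ImportanceTable:
    """Per-feature importance scores and the selection flag ``h``."""

    table: pd.DataFrame  # columns: name, mda, gini, h

    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["h"] == 1, "name"])


def _as_matrix(X, feature_names: list[str] | None = None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return X, names


class _MedianImputer:
    """Training-median imputation of missing-value sentinels (NaN).

    Features that are entirely missing in the training split fall back to
    zero.  The number of imputed cells is recorded for logging.
    """

    def fit(self, X: np.ndarray) -> "_MedianImputer":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(X, axis=0)
        self.medians_ = np.where(np.isfinite(med), med, 0.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        mask = ~np.isfinite(X)
        self.n_imputed_ = int(mask.sum())
        out = X.copy()
        out[mask] = np.broadcast_to(self.medians_, X.shape)[mask]
        return out


def _tree_gini_decrease(tree: DecisionTreeClassifier, n_features: int) -> np.ndarray:
    """Total weighted impurity decrease per feature for one fitted tree."""
    t = tree.tree_
    out = np.zeros(n_features)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        dec = (
            t.weighted_n_node_samples[node] * t.impurity[node]
            - t.weighted_n_node_samples[left] * t.impurity[left]
            - t.weighted_n_node_samples[right] * t.impurity[right]
        )
        out[t.feature[node]] += dec
    return out


def rf_importance(
    X,
    y,
    ntree: int = 100,
    mtry: int | None = None,
    seed: int = 0,
) -> ImportanceTable:
    """Bagged-forest importance: OOB permutation accuracy and Gini decrease.

    ``mtry`` defaults to ``floor(sqrt(n_features))`` (4 for the 19-feature
    battery).  Raises on single-class labels.  Missing sentinels are
    median-imputed before fitting.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("rf_importance needs at least two classes")
    n, p = Xm.shape
    if mtry is None:
        mtry = max(1, int(np.sqrt(p)))
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must lie in [1, {p}]")
    Xm = _MedianImputer().fit(Xm).transform(Xm)

    rng = np.random.default_rng(seed)
    mda = np.zeros(p)
    gini = np.zeros(p)
    n_oob_trees = 0
    for _ in range(ntree):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(Xm[boot], y[boot])
        gini += _tree_gini_decrease(tree, p)
        if oob.size == 0:
            continue
        n_oob_trees += 1
        base = float(np.mean(tree.predict(Xm[oob]) == y[oob]))
        Xo = Xm[oob]
        for j in range(p):
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            mda[j] += base - float(np.mean(tree.predict(Xp) == y[oob]))
    mda /= max(n_oob_trees, 1)
    gini /= ntree
    table = pd.DataFrame({"name": names, "mda": mda, "gini": gini, "h": 0})
    return ImportanceTable(table=table)


def select_features(tbl: ImportanceTable, k: int) -> list[str]:
    """Keep the top-``k`` features by combined rank of the two scores.

    The combined score is the mean of the descending ranks of the
    accuracy and Gini columns, ties broken by the accuracy score; the
    table's ``h`` column is set to 1 for kept and 0 for rejected rows.
    """
    df = tbl.table
    if not 1 <= k <= len(df):
        raise ValueError(f"k must lie in [1, {len(df)}]")
    r_mda = df["mda"].rank(ascending=False, method="average")
    r_gini = df["gini"].rank(ascending=False, method="average")
    combined = (r_mda + r_gini) / 2.0
    order = np.lexsort((-df["mda"].to_numpy(), combined.to_numpy()))
    keep = set(order[:k])
    tbl.table["h"] = [1 if i in keep else 0 for i in range(len(df))]
    return [df["name"].iloc[i] for i in order[:k]]


class _ELMCore:
    """Single-hidden-layer network with fixed random weights.

    Input weights ``IW ~ U[-1, 1]`` and thresholds ``B ~ U[0, 1]`` are
    drawn once; the hidden activation is ``H = sin(X IW' + B)`` and the
    output weights solve the least-squares problem ``H LW = T`` (one-hot
    targets) through the Moore-Penrose pseudo-inverse.  Prediction takes
    the argmax over the output columns.
    """

    def fit(self, X: np.ndarray, y: np.ndarray, n_hidden: int, seed: int):
        rng = np.random.default_rng(seed)
        self.classes_ = np.unique(y)
        self.IW = rng.uniform(-1.0, 1.0, size=(n_hidden, X.shape[1]))
        self.B = rng.uniform(0.0, 1.0, size=n_hidden)
        H = self.hidden(X)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        self.LW = np.linalg.pinv(H) @ T
        return self

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return np.sin(X @ self.IW.T + self.B)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Y = self.hidden(X) @ self.LW
        return self.classes_[np.argmax(Y, axis=1)]


class _ZScore:
    def fit(self, X: np.ndarray) -> "_ZScore":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_


class _RandomInitNet:
    """Untrained two-layer network: a chance-level baseline.

    Weights are Glorot-uniform from the seed and never updated; used when
    a zero-iteration budget is requested.
    """

    def fit(self, X, y, layers: tuple[int, ...], seed: int):
        rng = np.random.default_rng(seed)
        self.classes_ = np.unique(y)
        sizes = [X.shape[1], *layers, self.classes_.size]
        self.weights = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (a + b))
            self.weights.append(rng.uniform(-bound, bound, size=(a, b)))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        h = X
        for w in self.weights[:-1]:
            h = 1.0 / (1.0 + np.exp(-np.clip(h @ w, -500, 500)))
        return self.classes_[np.argmax(h @ self.weights[-1], axis=1)]


@dataclass
class TrainedModel:
    """A fitted classifier plus its feature schema and preprocessing."""

    kind: str
    feature_names: list[str]
    seed: int
    imputer: _MedianImputer
    scaler: _ZScore | None
    core: object
    converged: bool = True
    config: dict = field(default_factory=dict)

    @property
    def classes_(self) -> np.ndarray:
        return self.core.classes_

    def _prepare(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            Xm = X[self.feature_names].to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            if Xm.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} feature columns, "
                    f"got {Xm.shape[1]}"
                )
        Xm = self.imputer.transform(Xm)
        if self.scaler is not None:
            Xm = self.scaler.transform(Xm)
        return Xm

    def predict(self, X) -> np.ndarray:
        return self.core.predict(self._prepare(X))


def _fit_common(X, y):
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    imputer = _MedianImputer().fit(Xm)
    return imputer.transform(Xm), y, names, imputer


def train_dt(X, y, seed: int = 0, **tree_kw) -> TrainedModel:
    """CART classification tree, Gini criterion, grown to purity."""
    Xm, y, names, imputer = _fit_common(X, y)
    kw = {"criterion": "gini", "min_samples_leaf": 1}
    kw.update(tree_kw)
    core = DecisionTreeClassifier(random_state=seed, **kw).fit(Xm, y)
    return TrainedModel("dt", names, seed, imputer, None, core, config=kw)


def train_elm(X, y, n_hidden: int = 300, seed: int = 0) -> TrainedModel:
    """Extreme learning machine with a 300-unit sinusoidal hidden layer.

    Features are z-scored on the training split before the random
    projection (a sinusoidal hidden layer is unusable on raw
    heterogeneous feature scales).
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    Xm, y, names, imputer = _fit_common(X, y)
    scaler = _ZScore().fit(Xm)
    core = _ELMCore().fit(scaler.transform(Xm), y, n_hidden, seed)
    return TrainedModel(
        "elm", names, seed, imputer, scaler, core, config={"n_hidden": n_hidden}
    )


def train_bpnn(
    X,
    y,
    layers: tuple[int, ...] = (15, 15),
    max_iter: int = 3000,
    lr: float = 0.1,
    tol: float = 1e-3,
    seed: int = 0,
) -> TrainedModel:
    """Feed-forward net, sigmoid hidden layers, quasi-Newton training.

    ``lr`` only applies to first-order solvers and is kept for
    configurability; the default solver is L-BFGS.  ``max_iter=0`` returns
    the untrained random-initialisation baseline.  Non-convergence yields
    a usable model flagged ``converged=False`` plus a warning.
    """
    Xm, y, names, imputer = _fit_common(X, y)
    scaler = _ZScore().fit(Xm)
    Xs = scaler.transform(Xm)
    cfg = {"layers": layers, "max_iter": max_iter, "lr": lr, "tol": tol}
    if max_iter == 0:
        core = _RandomInitNet().fit(Xs, y, layers, seed)
        return TrainedModel("bpnn", names, seed, imputer, scaler, core, config=cfg)
    core = MLPClassifier(
        hidden_layer_sizes=layers,
        activation="logistic",
        solver="lbfgs",
        max_iter=max_iter,
        tol=tol,
        learning_rate_init=lr,
        random_state=seed,
    )
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        core.fit(Xs, y)
    converged = core.n_iter_ < max_iter
    if not converged:
        warnings.warn("BPNN training did not converge", stacklevel=2)
    return TrainedModel(
        "bpnn", names, seed, imputer, scaler, core, converged=converged, config=cfg
    )


def predict(model: TrainedModel, X) -> np.ndarray:
    """Schema-checked prediction; accepts a DataFrame in any column order."""
    return model.predict(X)
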