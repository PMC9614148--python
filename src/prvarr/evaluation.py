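"""Confusion-matrix metrics and the repeated hold-out protocol.

With ``Q[t, u]`` the number of samples of true class ``t`` predicted as
``u`` and ``M`` the total evaluated count:

* ``accuracy = trace(Q) / M * 100`` — the multi-class generalisation of
  the binary (TP + TN) / total form;
* Cohen's ``kappa = (p1 - p2) / (1 - p2)`` with ``p1 = trace(Q) / M`` the
  observed agreement and ``p2 = sum_t Q_{t+} Q_{+t} / M^2`` the chance
  agreement from the row and column margins;
* the per-class variant
  ``kappa(i) = (P_tt - P_t+ P_+t) / (P_+t - P_t+ P_+t)`` with the
  proportions ``P_tt = Q_ii / M``, ``P_t+ = Q_{i+} / M``,
  ``P_+t = Q_{+i} / M`` — note the asymmetric denominator (the column
  margin appears, not the row margin); it is implemented exactly in this
  form.

Degenerate denominators (chance agreement of 1; a class never true and
never predicted) return NaN rather than raising.

The evaluation protocol mirrors common practice on segment datasets:
repeated uniform-random 80/20 hold-out over segments (subject-wise
splitting is offered as an option), each repetition retraining from
scratch, reported as mean +/- standard deviation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ConfusionMatrix

__all__ = [
    "confusion",
    "accuracy",
    "cohen_kappa",
    "per_class_kappa",
    "EvalReport",
    "repeated_holdout",
]


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Tally the class-by-class count table.

    ``labels`` fixes the class universe (rows/columns appear even for
    classes absent from both vectors); by default it is the sorted union
    of the observed labels.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    labels = list(labels)
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, u in zip(y_true, y_pred):
        counts[index[t], index[u]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of correctly classified samples, ``trace(Q) / M * 100``."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total * 100.0


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement in [-1, 1]; NaN when chance agreement is 1."""
    m = cm.total
    if m == 0:
        raise ValueError("empty confusion matrix")
    q = cm.counts.astype(float)
    p1 = np.trace(q) / m
    p2 = float(np.sum(q.sum(axis=1) * q.sum(axis=0))) / m**2
    if abs(1.0 - p2) < 1e-15:
        return float("nan")
    return float((p1 - p2) / (1.0 - p2))


def per_class_kappa(cm: ConfusionMatrix, label) -> float:
    """Single-class agreement ``(P_tt - P_t+ P_+t) / (P_+t - P_t+ P_+t)``.

    NaN when the class is never predicted and the product term equals the
    column margin (0/0).
    """
    if label not in cm.labels:
        raise ValueError(f"label {label!r} not in the matrix universe")
    m = cm.total
    if m == 0:
        raise ValueError("empty confusion matrix")
    i = cm.labels.index(label)
    q = cm.counts.astype(float)
    p_tt = q[i, i] / m
    p_row = q[i, :].sum() / m
    p_col = q[:, i].sum() / m
    denom = p_col - p_row * p_col
    if abs(denom) < 1e-15:
        return float("nan")
    return float((p_tt - p_row * p_col) / denom)


@dataclass
class EvalReport:
    """Per-repetition metrics of the repeated hold-out protocol."""

    labels: list
    accuracies: np.ndarray  # percent, one per repetition
    kappas: np.ndarray  # fraction in [-1, 1], one per repetition
    class_kappas: np.ndarray  # (n_rep, n_classes), fraction
    train_seconds: np.ndarray
    n_repetitions: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n_repetitions = int(len(self.accuracies))

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def accuracy_std(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if self.n_repetitions > 1 else 0.0

    @property
    def kappa_mean(self) -> float:
        return float(np.mean(self.kappas))

    @property
    def kappa_std(self) -> float:
        return float(np.std(self.kappas, ddof=1)) if self.n_repetitions > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Mean +/- std rows: Accuracy, Kappa, Kappa(c) per class, Time."""
        rows = {
            "Accuracy (%)": (self.accuracy_mean, self.accuracy_std),
            "Kappa (%)": (100.0 * self.kappa_mean, 100.0 * self.kappa_std),
        }
        for j, c in enumerate(self.labels):
            col = self.class_kappas[:, j]
            ok = np.isfinite(col)
            if ok.any():
                mean = 100.0 * float(np.mean(col[ok]))
                std = 100.0 * float(np.std(col[ok], ddof=1)) if ok.sum() > 1 else 0.0
            else:
                mean, std = float("nan"), float("nan")
            rows[f"Kappa ({c}) (%)"] = (mean, std)
        rows["Time (s)"] = (
            float(np.mean(self.train_seconds)),
            float(np.std(self.train_seconds, ddof=1)) if self.n_repetitions > 1 else 0.0,
        )
        return pd.DataFrame(rows, index=["mean", "std"]).T

    def format_table(self) -> str:
        df = self.to_frame()
        lines = [f"{'Metric':24s}  mean ± std"]
        for name, row in df.iterrows():
            lines.append(f"{name:24s}  {row['mean']:8.2f} ± {row['std']:.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        df = self.to_frame()
        return {
            "n_repetitions": self.n_repetitions,
            "labels": list(self.labels),
            "metrics": {
                str(name): {"mean": float(r["mean"]), "std": float(r["std"])}
                for name, r in df.iterrows()
            },
            **self.meta,
        }


def repeated_holdout(
    X,
    y,
    trainer,
    n_rep: int = 100,
    test_frac: float = 0.2,
    seed: int = 0,
    labels=None,
    groups=None,
) -> EvalReport:
    """Repeated uniform-random hold-out evaluation.

    ``trainer(X_train, y_train, seed=...)`` must return an object with a
    ``predict`` method.  Splits are random over segments; passing
    ``groups`` (e.g. record ids) switches to a group-wise split in which
    no group straddles the train/test boundary.
    """
    y = np.asarray(y)
    n = len(y)
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must lie in (0, 1)")
    if labels is None:
        labels = sorted(set(y.tolist()))
    is_frame = isinstance(X, pd.DataFrame)
    rng = np.random.default_rng(seed)
    accs, kaps, ckaps, secs = [], [], [], []
    for _ in range(n_rep):
        if groups is None:
            perm = rng.permutation(n)
            n_test = max(1, int(round(test_frac * n)))
            test_idx, train_idx = perm[:n_test], perm[n_test:]
        else:
            g = np.asarray(groups)
            uniq = rng.permutation(np.unique(g))
            n_test_g = max(1, int(round(test_frac * uniq.size)))
            test_groups = set(uniq[:n_test_g].tolist())
            mask = np.array([gi in test_groups for gi in g])
            test_idx, train_idx = np.where(mask)[0], np.where(~mask)[0]
        X_tr = X.iloc[train_idx] if is_frame else np.asarray(X)[train_idx]
        X_te = X.iloc[test_idx] if is_frame else np.asarray(X)[test_idx]
        t0 = time.perf_counter()
        model = trainer(X_tr, y[train_idx], seed=int(rng.integers(0, 2**31 - 1)))
        secs.append(time.perf_counter() - t0)
        cm = confusion(y[test_idx], model.predict(X_te), labels=labels)
        accs.append(accuracy(cm))
        kaps.append(cohen_kappa(cm))
        ckaps.append([per_class_kappa(cm, c) for c in labels])
    return EvalReport(
        labels=list(labels),
        accuracies=np.asarray(accs),
        kappas=np.asarray(kaps),
        class_kappas=np.asarray(ckaps),
        train_seconds=np.asarray(secs),
    )
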