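"""Base learners behind a uniform spec interface, plus the masked multi-task net.

``LearnerSpec`` names an algorithm (``forest``, ``boosting``, ``net``,
``multitask_net`` or a registered ``external`` learner), its hyperparameter
map and a seed.  Single-task learners delegate to scikit-learn /
XGBoost; the multi-task network is a feed-forward net trained with a
masked binary cross-entropy so that sparse label matrices can be used
directly: a compound's loss is the mean BCE over its *observed* assays
only, and compounds with no observed assay contribute zero.

All learners expose ``predict_proba``-style probabilities of the toxic
class; the binary call convention (score >= threshold -> toxic) is shared
across the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

DEFAULT_THRESHOLD = 0.5

_EXTERNAL: dict[str, Callable] = {}


class SingleClassError(ValueError):
    """Training labels contain only one class; skip or flag the assay."""


@dataclass(frozen=True)
class LearnerSpec:
    """Algorithm id + hyperparameters + seed."""

    algorithm: str
    params: tuple = ()  # stored as sorted (key, value) pairs for hashability
    seed: int = 0

    @classmethod
    def make(cls, algorithm: str, seed: int = 0, **params) -> "LearnerSpec":
        return cls(algorithm=algorithm, params=tuple(sorted(params.items())),
                   seed=seed)

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def with_seed(self, seed: int) -> "LearnerSpec":
        return replace(self, seed=seed)


def register_external(name: str, factory: Callable) -> None:
    """Attach an external learner (e.g. a matrix-factorisation tool).

    ``factory(params: dict, seed: int)`` must return an estimator with
    ``fit(X, y)`` and ``predict_proba(X)``.
    """
    _EXTERNAL[name] = factory


def make_estimator(spec: LearnerSpec):
    """Instantiate the unfitted estimator a spec describes."""
    p = spec.param_dict
    if spec.algorithm == "forest":
        p.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **p)
    if spec.algorithm == "boosting":
        p.setdefault("n_estimators", 100)
        p.setdefault("max_depth", 4)
        p.setdefault("tree_method", "hist")
        # stochastic row/column subsampling so the seed-sensitivity protocol
        # sees genuine between-seed variation (and regularises a little)
        p.setdefault("subsample", 0.8)
        p.setdefault("colsample_bytree", 0.8)
        return XGBClassifier(random_state=spec.seed, n_jobs=1,
                             eval_metric="logloss", **p)
    if spec.algorithm == "net":
        p.setdefault("hidden_layer_sizes", (128,))
        p.setdefault("activation", "relu")
        p.setdefault("solver", "adam")
        p.setdefault("max_iter", 200)
        return MLPClassifier(random_state=spec.seed, **p)
    if spec.algorithm == "multitask_net":
        return MaskedMultiTaskNet(random_state=spec.seed, **p)
    if spec.algorithm in _EXTERNAL:
        return _EXTERNAL[spec.algorithm](p, spec.seed)
    raise ValueError(f"unknown algorithm id: {spec.algorithm}")


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float32)
    return np.asarray(X, dtype=np.float32)


def fit_single_task(spec: LearnerSpec, X, y):
    """Fit one assay's classifier; raises ``SingleClassError`` on one-class y."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise SingleClassError(
            "single-class training labels; skip or flag this assay")
    model = make_estimator(spec)
    model.fit(_as_array(X), y)
    return model


def predict_proba_toxic(model, X) -> np.ndarray:
    """Probability of the toxic (label 1) class, as a 1-D array."""
    proba = model.predict_proba(_as_array(X))
    proba = np.asarray(proba)
    if proba.ndim == 1:
        return proba
    classes = getattr(model, "classes_", np.array([0, 1]))
    col = int(np.flatnonzero(np.asarray(classes) == 1)[0])
    return proba[:, col]


def grid_search_cv(grid, X, y, k: int = 5, seed: int = 0) -> LearnerSpec:
    """Fivefold stratified CV grid search maximising mean validation MCC.

    Ties go to the earliest spec in grid order.  Folds are drawn within the
    supplied (training) data only.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    if k < 2:
        raise ValueError("k must be >= 2")
    X = _as_array(X)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("grid search needs both classes")
    if min(np.bincount(y)) < k:
        raise ValueError("too few members of the minority class for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_spec, best_score = None, -np.inf
    for spec in grid:
        scores = []
        for tr, va in folds:
            model = fit_single_task(spec, X[tr], y[tr])
            preds = (predict_proba_toxic(model, X[va]) >= DEFAULT_THRESHOLD)
            scores.append(matthews_corrcoef(y[va], preds.astype(int)))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_spec, best_score = spec, mean_score
    return best_spec


def masked_bce(y_pred, y_true, mask, eps: float = 1e-7) -> float:
    """Masked binary cross-entropy (natural log).

    Per example, the BCE is averaged over observed outputs only; examples
    with nothing observed contribute zero.  The batch loss is the mean of
    the per-example losses.
    """
    p = np.clip(np.asarray(y_pred, dtype=float), eps, 1 - eps)
    y = np.nan_to_num(np.asarray(y_true, dtype=float))
    m = np.asarray(mask, dtype=float)
    cell = -(y * np.log(p) + (1 - y) * np.log(1 - p)) * m
    n_obs = m.sum(axis=-1)
    per_example = np.where(n_obs > 0, cell.sum(axis=-1) / np.maximum(n_obs, 1), 0.0)
    return float(per_example.mean())


class MaskedMultiTaskNet(BaseEstimator):
    """Feed-forward multi-task classifier with a masked BCE loss.

    One sigmoid output per assay; ReLU hidden layers; Adam updates on
    shuffled minibatches.  ``fit`` takes a 2-D target matrix with ``NaN``
    marking unobserved cells; unobserved cells are excluded from both the
    loss and its gradient, which is what makes training on sparse label
    matrices possible.

    Parameters
    ----------
    hidden_layer_sizes : widths of the hidden layers.
    lr, beta1, beta2 : Adam settings.
    n_epochs, batch_size : training schedule (fixed epoch budget).
    l2 : weight decay on the weight matrices.
    random_state : seed for init and batch shuffling.
    """

    def __init__(self, hidden_layer_sizes=(128,), lr=1e-3, beta1=0.9,
                 beta2=0.999, n_epochs=60, batch_size=64, l2=0.0,
                 random_state=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.l2 = l2
        self.random_state = random_state

    def fit(self, X, Y):
        X = _as_array(X)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2:
            raise ValueError("Y must be 2-D (compounds x assays)")
        mask = ~np.isnan(Y)
        keep = mask.any(axis=1)
        self.n_dropped_ = int((~keep).sum())  # compounds with zero observed labels
        X, Y, mask = X[keep], Y[keep], mask[keep]
        Yf = np.nan_to_num(Y)
        rng = np.random.default_rng(self.random_state)
        sizes = [X.shape[1], *self.hidden_layer_sizes, Y.shape[1]]
        self.weights_ = [rng.normal(0, np.sqrt(2.0 / sizes[i]),
                                    size=(sizes[i], sizes[i + 1]))
                         for i in range(len(sizes) - 1)]
        self.biases_ = [np.zeros(s) for s in sizes[1:]]
        m_w = [np.zeros_like(w) for w in self.weights_]
        v_w = [np.zeros_like(w) for w in self.weights_]
        m_b = [np.zeros_like(b) for b in self.biases_]
        v_b = [np.zeros_like(b) for b in self.biases_]
        t = 0
        n = X.shape[0]
        self.loss_curve_ = []
        for _epoch in range(self.n_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb, mb = X[idx], Yf[idx], mask[idx].astype(float)
                acts, pre = self._forward(xb)
                p = acts[-1]
                epoch_loss += masked_bce(p, yb, mb) * len(idx)
                # gradient of the per-example-mean masked BCE wrt the logits
                n_obs = mb.sum(axis=1, keepdims=True)
                scale = np.where(n_obs > 0, 1.0 / np.maximum(n_obs, 1), 0.0)
                delta = (p - yb) * mb * scale / len(idx)
                t += 1
                grads_w, grads_b = self._backward(acts, pre, delta)
                for i, (gw, gb) in enumerate(zip(grads_w, grads_b)):
                    if self.l2:
                        gw = gw + self.l2 * self.weights_[i]
                    m_w[i] = self.beta1 * m_w[i] + (1 - self.beta1) * gw
                    v_w[i] = self.beta2 * v_w[i] + (1 - self.beta2) * gw ** 2
                    m_b[i] = self.beta1 * m_b[i] + (1 - self.beta1) * gb
                    v_b[i] = self.beta2 * v_b[i] + (1 - self.beta2) * gb ** 2
                    mw_hat = m_w[i] / (1 - self.beta1 ** t)
                    vw_hat = v_w[i] / (1 - self.beta2 ** t)
                    mb_hat = m_b[i] / (1 - self.beta1 ** t)
                    vb_hat = v_b[i] / (1 - self.beta2 ** t)
                    self.weights_[i] -= self.lr * mw_hat / (np.sqrt(vw_hat) + 1e-8)
                    self.biases_[i] -= self.lr * mb_hat / (np.sqrt(vb_hat) + 1e-8)
            self.loss_curve_.append(epoch_loss / n)
        self.n_tasks_ = Y.shape[1]
        return self

    def _forward(self, X):
        acts, pre = [X], []
        a = X
        for i, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            z = a @ w + b
            pre.append(z)
            if i < len(self.weights_) - 1:
                a = np.maximum(z, 0.0)
            else:
                a = 1.0 / (1.0 + np.exp(-z))
            acts.append(a)
        return acts, pre

    def _backward(self, acts, pre, delta):
        grads_w = [None] * len(self.weights_)
        grads_b = [None] * len(self.weights_)
        for i in range(len(self.weights_) - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights_[i].T) * (pre[i - 1] > 0)
        return grads_w, grads_b

    def predict_proba(self, X):
        acts, _ = self._forward(_as_array(X))
        return acts[-1]

    def predict(self, X, threshold: float = DEFAULT_THRESHOLD):
        return (self.predict_proba(X) >= threshold).astype(int)


def fit_multitask_masked(spec: LearnerSpec, X, label_matrix: pd.DataFrame):
    """Fit the masked multi-task net on a (sparse) train-label matrix.

    Every assay must have at least one training label of each class.
    """
    Y = label_matrix.to_numpy(dtype=float)
    for j, assay in enumerate(label_matrix.columns):
        col = Y[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0 or len(np.unique(obs)) < 2:
            raise SingleClassError(f"assay {assay} lacks both classes in training")
    if spec.algorithm != "multitask_net":
        raise ValueError("fit_multitask_masked requires a multitask_net spec")
    model = make_estimator(spec)
    model.fit(X, Y)
    return model
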