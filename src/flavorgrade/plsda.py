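"""Partial least squares discriminant analysis, implemented from scratch.

PLS-DA regresses an autoscaled predictor matrix X (samples x variables)
against a column-centered one-hot class membership matrix Y using NIPALS
PLS2: per component, alternate

    w ∝ X'u,   t = Xw,   q ∝ Y't,   u = Yq

to convergence, then deflate X by t p' (p = X't/t't) and Y by t q'.
Reported metrics:

* R²X, R²Y — cumulative fraction of X / Y variance captured in-sample;
* Q²       — cross-validated 1 - PRESS/SS of centered Y, accumulated over
  held-out folds (stratified venetian-blind folds by default);
* VIP_j    — variable importance in projection,
  sqrt(p * Σ_a SSY_a (w_ja/||w_a||)² / Σ_a SSY_a); mean of squared VIPs
  is exactly 1;
* a label-permutation test (default 200 permutations): Y rows are
  shuffled, the model refit, and R²Y/Q² regressed on the correlation
  between permuted and original Y.  A Q² regression intercept below zero
  at correlation 0 indicates the original model is not overfit.

Sign convention: each weight vector is flipped so its largest-magnitude
entry is positive, making scores reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PlsdaError(ValueError):
    pass


def one_hot(labels) -> tuple[np.ndarray, list[str]]:
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))  # first-appearance order
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y, [str(c) for c in classes]


@dataclass
class Scaler:
    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X):
        return (X - self.mean) / self.scale


def _fit_scaler(X: np.ndarray, scaling: str) -> Scaler:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "autoscale":
        scale = np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif scaling == "center":
        scale = np.ones_like(sd)
    else:
        raise PlsdaError(f"unknown scaling {scaling!r}")
    return Scaler(mean, scale)


@dataclass
class PlsdaModel:
    n_components: int
    classes: list[str]
    variable_ids: list[str]
    x_weights: np.ndarray      # variables x A
    x_loadings: np.ndarray     # variables x A
    y_loadings: np.ndarray     # classes x A
    x_scores: np.ndarray       # samples x A
    y_scores: np.ndarray       # samples x A
    x_scaler: Scaler = None
    y_mean: np.ndarray = None
    r2x: float = 0.0
    r2y: float = 0.0
    q2: float | None = None
    r2x_per_component: np.ndarray = field(default=None)
    ssy_per_component: np.ndarray = field(default=None)

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients B with Yhat = Xscaled @ B + y_mean."""
        W, P, Q = self.x_weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict(self, X) -> np.ndarray:
        Xs = self.x_scaler.transform(np.asarray(X, dtype=float))
        return Xs @ self.coef + self.y_mean

    def predict_labels(self, X) -> list[str]:
        Yhat = self.predict(X)
        return [self.classes[j] for j in Yhat.argmax(axis=1)]

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "classes": self.classes,
            "variable_ids": list(self.variable_ids),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "r2x": self.r2x, "r2y": self.r2y, "q2": self.q2,
        }


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def plsda_fit(X, labels, n_components: int = 2,
              scaling: str = "autoscale", max_iter: int = 5000,
              tol: float = 1e-9, drop_zero_variance: bool = True
              ) -> PlsdaModel:
    """Fit a PLS-DA model by NIPALS on a one-hot class matrix."""
    Xm, var_ids = _as_matrix(X)
    labels = np.asarray(labels)
    if len(labels) != len(Xm):
        raise PlsdaError("one label per sample row required")
    classes_all, counts = np.unique(labels, return_counts=True)
    if len(classes_all) < 2:
        raise PlsdaError("need >= 2 classes")
    if counts.min() < 2:
        raise PlsdaError("need >= 2 samples per class")
    if Xm.shape[0] < n_components + 1:
        raise PlsdaError("need at least n_components + 1 samples")

    if drop_zero_variance:
        keep = Xm.std(axis=0, ddof=1) > 0
        Xm = Xm[:, keep]
        var_ids = [v for v, k in zip(var_ids, keep) if k]
        if Xm.shape[1] == 0:
            raise PlsdaError("all variables have zero variance")

    scaler = _fit_scaler(Xm, scaling)
    Xs = scaler.transform(Xm)
    Yoh, classes = one_hot(labels)
    y_mean = Yoh.mean(axis=0)
    Ys = Yoh - y_mean

    ssx_total = float((Xs ** 2).sum())
    ssy_total = float((Ys ** 2).sum())
    Xd, Yd = Xs.copy(), Ys.copy()
    n, p = Xs.shape
    A = n_components
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((Ys.shape[1], A))
    T = np.zeros((n, A))
    U = np.zeros((n, A))
    r2x_a = np.zeros(A)
    ssy_a = np.zeros(A)

    for a in range(A):
        u = Yd[:, np.argmax((Yd ** 2).sum(axis=0))].copy()
        w_old = None
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise PlsdaError(f"NIPALS degenerate at component {a + 1}")
            w /= nw
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            u = Yd @ q / (q @ q)
            if w_old is not None and np.linalg.norm(w - w_old) <= tol:
                break
            w_old = w
        else:
            raise PlsdaError(f"NIPALS failed to converge at component {a + 1}")
        # fix sign: largest-magnitude weight entry positive
        sign = np.sign(w[np.argmax(np.abs(w))]) or 1.0
        w, t, q, u = w * sign, t * sign, q * sign, u * sign
        pvec = Xd.T @ t / (t @ t)
        ssy_before = float((Yd ** 2).sum())
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a], U[:, a] = w, pvec, q, t, u
        r2x_a[a] = float((t @ t) * (pvec @ pvec)) / ssx_total
        ssy_a[a] = ssy_before - float((Yd ** 2).sum())

    r2y = 1.0 - float((Yd ** 2).sum()) / ssy_total
    return PlsdaModel(
        n_components=A, classes=classes, variable_ids=var_ids,
        x_weights=W, x_loadings=P, y_loadings=Q, x_scores=T, y_scores=U,
        x_scaler=scaler, y_mean=y_mean,
        r2x=float(r2x_a.sum()), r2y=r2y,
        r2x_per_component=r2x_a, ssy_per_component=ssy_a)


def stratified_folds(labels, n_folds: int) -> list[np.ndarray]:
    """Venetian-blind fold assignment, stratified by class.

    Samples are taken in class-blocked order and dealt round-robin to the
    folds, so every training fold retains every class whenever possible.
    Deterministic: no randomness involved.
    """
    labels = np.asarray(labels)
    order = np.concatenate([np.flatnonzero(labels == c)
                            for c in dict.fromkeys(labels)])
    assign = np.empty(len(labels), dtype=int)
    assign[order] = np.arange(len(labels)) % n_folds
    return [np.flatnonzero(assign == f) for f in range(n_folds)]


def q2_crossval(X, labels, n_components: int = 2, n_folds: int = 7,
                scaling: str = "autoscale",
                folds: list[np.ndarray] | None = None) -> float:
    """Cumulative cross-validated Q² = 1 - PRESS/SS of the centered Y.

    Folds default to class-stratified venetian blinds; ``n_folds`` larger
    than the sample count degrades to leave-one-out.  The scaler and class
    means are re-estimated inside every training fold.
    """
    Xm, _ = _as_matrix(X)
    labels = np.asarray(labels)
    n = len(labels)
    if n_folds < 2:
        raise PlsdaError("n_folds must be >= 2")
    n_folds = min(n_folds, n)
    if folds is None:
        folds = stratified_folds(labels, n_folds)
    Yoh, _ = one_hot(labels)
    Yc = Yoh - Yoh.mean(axis=0)
    press = 0.0
    for test_idx in folds:
        if len(test_idx) == 0:
            continue
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        tr_labels = labels[train_idx]
        if len(np.unique(tr_labels)) < len(np.unique(labels)):
            raise PlsdaError(
                "a training fold lost a class entirely; use stratified folds")
        # zero-variance columns are kept (they scale to all-zero and are
        # inert) so train/test column spaces always match
        model = plsda_fit(Xm[train_idx], tr_labels, n_components,
                          scaling=scaling, drop_zero_variance=False)
        Yhat = model.predict(Xm[test_idx])
        Ytrue, _ = one_hot(labels)
        # align class order of this fold's model to the global order
        global_classes = list(dict.fromkeys(labels))
        col = [model.classes.index(str(c)) for c in global_classes]
        press += float(((Ytrue[test_idx] - Yhat[:, col]) ** 2).sum())
    return 1.0 - press / float((Yc ** 2).sum())


def vip_scores(model: PlsdaModel) -> pd.Series:
    """Variable importance in projection; mean of squared VIPs equals 1."""
    ssy = model.ssy_per_component
    if ssy is None or ssy.sum() <= 0:
        raise PlsdaError("model explains no Y variance; VIP undefined")
    W = model.x_weights
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn ** 2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.variable_ids, name="vip")


@dataclass
class PermutationResult:
    n_perm: int
    correlations: np.ndarray
    r2y: np.ndarray
    q2: np.ndarray
    r2y_intercept: float
    q2_intercept: float
    original_r2y: float
    original_q2: float

    @property
    def valid(self) -> bool:
        """Model judged non-overfit: Q² intercept below zero."""
        return self.q2_intercept < 0


def permutation_test(X, labels, n_components: int = 2, n_perm: int = 200,
                     seed: int | None = None, n_folds: int = 7,
                     scaling: str = "autoscale") -> PermutationResult:
    """Label-permutation validation of a PLS-DA model.

    For each permutation the class labels are shuffled (permutations
    identical to the original ordering are re-drawn), the model refit and
    R²Y/Q² recorded together with the mean absolute Pearson correlation
    between permuted and original one-hot Y columns.  Least-squares lines
    of R²Y and Q² against that correlation — anchored by the original
    model at correlation 1 — give the reported intercepts at correlation 0.
    """
    if n_perm < 20:
        raise PlsdaError("n_perm must be >= 20")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    Xm, _ = _as_matrix(X)
    Y0, _ = one_hot(labels)
    Y0c = Y0 - Y0.mean(axis=0)

    def ycorr(perm):
        Yp = Y0[perm]
        Ypc = Yp - Yp.mean(axis=0)
        num = (Y0c * Ypc).sum(axis=0)
        den = np.sqrt((Y0c ** 2).sum(axis=0) * (Ypc ** 2).sum(axis=0))
        return float(np.abs(num / den).mean())

    model = plsda_fit(Xm, labels, n_components, scaling=scaling)
    orig_q2 = q2_crossval(Xm, labels, n_components, n_folds, scaling=scaling)

    cors, r2s, q2s = [], [], []
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        while (labels[perm] == labels).all():
            perm = rng.permutation(len(labels))
        plab = labels[perm]
        m = plsda_fit(Xm, plab, n_components, scaling=scaling)
        q2 = q2_crossval(Xm, plab, n_components, n_folds, scaling=scaling)
        cors.append(ycorr(perm))
        r2s.append(m.r2y)
        q2s.append(q2)

    cors_all = np.array(cors + [1.0])
    r2_all = np.array(r2s + [model.r2y])
    q2_all = np.array(q2s + [orig_q2])
    r2_line = np.polyfit(cors_all, r2_all, 1)
    q2_line = np.polyfit(cors_all, q2_all, 1)
    return PermutationResult(
        n_perm=n_perm, correlations=np.array(cors),
        r2y=np.array(r2s), q2=np.array(q2s),
        r2y_intercept=float(r2_line[1]), q2_intercept=float(q2_line[1]),
        original_r2y=model.r2y, original_q2=orig_q2)
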