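"""Multivariate core: PLS-DA, cross-validation, VIP, ROC, permutation tests, PCA.

The discriminant is a two-class PLS regression fitted by NIPALS with
y-deflation on autoscaled data; the class is coded 1 (positive) / 0
(negative) and the continuous prediction ("y-predicted value") is the
discriminant score. Component signs are canonicalized (largest-magnitude
weight positive) so fits are bit-reproducible across platforms.

The cross-validation is a repeated, stratified random k-fold with
re-autoscaling inside each training fold (leakage-free); the number of latent
variables is chosen by the lowest mean classification error, ties broken
toward fewer LVs, with RMSECV reported alongside. Model significance is
assessed by permutation testing with the cross-validated AUROC as target
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .io import ValidationError


# -- PLS fit ---------------------------------------------------------------


@dataclass
class PLSFit:
    """A fitted two-class PLS discriminant in coefficient and component form.

    ``weights``/``loadings`` are (n_lv, p); ``y_loadings`` has one entry per
    latent variable; ``coef`` is the p-vector such that
    ``yhat = Xc @ coef + y_mean`` with ``Xc`` in the (autoscaled) training
    feature space.
    """

    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coef: np.ndarray
    n_lv: int
    y_mean: float
    feature_names: list[str] | None = None
    class_coding: dict = field(default_factory=lambda: {"positive": 1, "negative": 0})

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        return X @ self.coef + self.y_mean

    @property
    def explained_y_variance(self) -> np.ndarray:
        """Per-LV y-variance explained, SS_a = q_a^2 * (t_a' t_a)."""
        tt = np.einsum("ia,ia->a", self.scores, self.scores)
        return self.y_loadings**2 * tt

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "coef": self.coef.tolist(),
            "n_lv": int(self.n_lv),
            "y_mean": float(self.y_mean),
            "feature_names": self.feature_names,
            "class_coding": self.class_coding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSFit":
        return cls(
            weights=np.asarray(d["weights"], float),
            loadings=np.asarray(d["loadings"], float),
            y_loadings=np.asarray(d["y_loadings"], float),
            scores=np.asarray(d["scores"], float),
            coef=np.asarray(d["coef"], float),
            n_lv=int(d["n_lv"]),
            y_mean=float(d["y_mean"]),
            feature_names=d.get("feature_names"),
            class_coding=dict(d.get("class_coding", {"positive": 1, "negative": 0})),
        )


def _as_matrix(X, feature_names=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise ValidationError(f"missing feature(s): {missing[:5]}")
            X = X[feature_names]
        return X.to_numpy(float)
    return np.asarray(X, float)


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Univariate-y NIPALS with X- and y-deflation and sign canonicalization."""
    n, p = Xc.shape
    W = np.zeros((n_lv, p))
    P = np.zeros((n_lv, p))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    X = Xc.copy()
    y = yc.copy()
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise ValidationError(
                f"X carries no y-covariance at latent variable {a + 1}; "
                f"reduce n_lv"
            )
        w /= nw
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = X @ w
        tt = t @ t
        if tt < 1e-14:
            raise ValidationError(f"degenerate score vector at LV {a + 1}")
        pvec = (X.T @ t) / tt
        qa = (y @ t) / tt
        X = X - np.outer(t, pvec)
        y = y - qa * t
        W[a], P[a], q[a], T[:, a] = w, pvec, qa, t
    return W, P, q, T


def fit_pls(X, y, n_lv: int, feature_names: list[str] | None = None) -> PLSFit:
    """Fit a two-class PLS discriminant on autoscaled X and a {0,1} class
    vector. Deterministic up to nothing: component signs are canonicalized."""
    names = feature_names
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
    X = _as_matrix(X)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y disagree on sample count")
    if len(np.unique(y)) < 2:
        raise ValidationError("constant y: both classes required")
    max_lv = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_lv <= max_lv:
        raise ValidationError(f"n_lv must be in [1, {max_lv}], got {n_lv}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values; impute or drop first")
    y_mean = float(y.mean())
    W, P, q, T = _nipals(X, y - y_mean, n_lv)
    # B = W' (P W')^{-1} q  with row-vector convention (a, p)
    R = np.linalg.solve(P @ W.T, np.eye(n_lv))
    coef = W.T @ (R @ q)
    return PLSFit(W, P, q, T, coef, n_lv, y_mean, feature_names=names)


def vip(fit: PLSFit) -> pd.DataFrame:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SS_a w_{aj}^2 / sum_a SS_a ) with SS_a the
    y-variance explained by LV a; mean(VIP^2) over features equals 1.
    """
    ss = fit.explained_y_variance
    total = ss.sum()
    if total <= 0:
        raise ValidationError("model explains no y-variance; VIP undefined")
    p = fit.weights.shape[1]
    w2 = fit.weights**2  # rows already unit-norm
    scores = np.sqrt(p * (ss @ w2) / total)
    names = fit.feature_names or [f"x{j}" for j in range(p)]
    out = pd.DataFrame({"feature": names, "vip": scores})
    out["rank"] = out["vip"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("vip", ascending=False).reset_index(drop=True)


# -- cross-validation ------------------------------------------------------


@dataclass
class CVResult:
    """Repeated stratified k-fold diagnostics per latent-variable count."""

    error_mean: np.ndarray  # per LV
    error_sd: np.ndarray
    rmsecv_mean: np.ndarray
    rmsecv_sd: np.ndarray
    n_lv: int
    k: int
    repeats: int
    seed: int
    oof_scores: np.ndarray  # (repeats, n) out-of-fold yhat at the chosen LV
    auc_per_repeat: np.ndarray

    @property
    def auc_mean(self) -> float:
        return float(self.auc_per_repeat.mean())

    @property
    def auc_sd(self) -> float:
        return float(self.auc_per_repeat.std(ddof=1)) if self.repeats > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "error_mean": self.error_mean.tolist(),
            "error_sd": self.error_sd.tolist(),
            "rmsecv_mean": self.rmsecv_mean.tolist(),
            "rmsecv_sd": self.rmsecv_sd.tolist(),
            "n_lv": int(self.n_lv),
            "k": int(self.k),
            "repeats": int(self.repeats),
            "seed": int(self.seed),
            "oof_scores": self.oof_scores.tolist(),
            "auc_per_repeat": self.auc_per_repeat.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CVResult":
        return cls(
            error_mean=np.asarray(d["error_mean"], float),
            error_sd=np.asarray(d["error_sd"], float),
            rmsecv_mean=np.asarray(d["rmsecv_mean"], float),
            rmsecv_sd=np.asarray(d["rmsecv_sd"], float),
            n_lv=int(d["n_lv"]),
            k=int(d["k"]),
            repeats=int(d["repeats"]),
            seed=int(d["seed"]),
            oof_scores=np.asarray(d["oof_scores"], float),
            auc_per_repeat=np.asarray(d["auc_per_repeat"], float),
        )


def _autoscale_fold(Xtr: np.ndarray, Xte: np.ndarray):
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant-in-fold columns contribute zeros
    return (Xtr - mean) / sd, (Xte - mean) / sd


def _coefs_per_lv(W, P, q):
    """Coefficient vectors for 1..A latent variables from one A-LV fit."""
    A = W.shape[0]
    out = []
    for a in range(1, A + 1):
        R = np.linalg.solve(P[:a] @ W[:a].T, np.eye(a))
        out.append(W[:a].T @ (R @ q[:a]))
    return out


def cross_validate(
    X, y, max_lv: int, k: int = 3, repeats: int = 10, seed: int = 0
) -> CVResult:
    """Repeated stratified random k-fold CV of the PLS discriminant.

    X is the raw (unscaled) matrix; each training fold is autoscaled and the
    held-out fold scaled with the training-fold parameters. Returns per-LV
    classification error rate (threshold 0.5 on yhat) and RMSECV, the chosen
    LV count, and out-of-fold scores at that LV for ROC construction.
    """
    X = _as_matrix(X)
    y = np.asarray(y, float).ravel()
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("need exactly two classes")
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} member(s) < k={k} folds"
        )
    max_lv = int(min(max_lv, n - int(np.ceil(n / k)) - 1, X.shape[1]))
    if max_lv < 1:
        raise ValidationError("max_lv < 1 after capping by fold size")

    errors = np.zeros((repeats, max_lv))
    rmse = np.zeros((repeats, max_lv))
    oof = np.zeros((repeats, n, max_lv))
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for tr, te in skf.split(X, y):
            Xtr, Xte = _autoscale_fold(X[tr], X[te])
            ytr = y[tr]
            a_fit = min(max_lv, len(tr) - 1)
            W, P, q, _ = _nipals(Xtr, ytr - ytr.mean(), a_fit)
            for a, coef in enumerate(_coefs_per_lv(W, P, q)):
                oof[rep, te, a] = Xte @ coef + ytr.mean()
            for a in range(a_fit, max_lv):  # fold smaller than max_lv: reuse last
                oof[rep, te, a] = oof[rep, te, a_fit - 1]
        pred = oof[rep]
        errors[rep] = ((pred >= 0.5).astype(float) != y[:, None]).mean(axis=0)
        rmse[rep] = np.sqrt(((pred - y[:, None]) ** 2).mean(axis=0))

    err_mean = errors.mean(axis=0)
    chosen = int(np.argmin(err_mean)) + 1  # argmin takes the first (fewest LVs)
    auc_rep = np.array([auc_mann_whitney(oof[r, :, chosen - 1], y)
                        for r in range(repeats)])
    return CVResult(
        error_mean=err_mean,
        error_sd=errors.std(axis=0, ddof=1) if repeats > 1 else np.zeros(max_lv),
        rmsecv_mean=rmse.mean(axis=0),
        rmsecv_sd=rmse.std(axis=0, ddof=1) if repeats > 1 else np.zeros(max_lv),
        n_lv=chosen,
        k=k,
        repeats=repeats,
        seed=seed,
        oof_scores=oof[:, :, chosen - 1].copy(),
        auc_per_repeat=auc_rep,
    )


# -- ROC -------------------------------------------------------------------


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_sd: float = 0.0

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "auc": float(self.auc),
            "auc_sd": float(self.auc_sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROCResult":
        return cls(
            thresholds=np.asarray(d["thresholds"], float),
            sensitivity=np.asarray(d["sensitivity"], float),
            specificity=np.asarray(d["specificity"], float),
            auc=float(d["auc"]),
            auc_sd=float(d.get("auc_sd", 0.0)),
        )


def auc_mann_whitney(scores, labels) -> float:
    """AUROC as the Mann-Whitney concordance probability (ties counted 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUROC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc(scores, labels) -> ROCResult:
    """ROC over a threshold grid of the observed scores (plus guard points);
    a sample is called positive when its score >= threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == 1
    if pos.all() or (~pos).all():
        raise ValidationError("ROC needs both classes present")
    uniq = np.unique(scores)
    span = max(uniq[-1] - uniq[0], 1.0)
    grid = np.concatenate([[uniq[0] - 0.05 * span], uniq, [uniq[-1] + 0.05 * span]])
    sens = np.array([(scores[pos] >= t).mean() for t in grid])
    spec = np.array([(scores[~pos] < t).mean() for t in grid])
    return ROCResult(grid, sens, spec, auc_mann_whitney(scores, labels))


def roc_from_cv(cv: CVResult, labels) -> ROCResult:
    """ROC of the pooled out-of-fold scores with the AUC mean +/- sd over
    repeats (the shaded-ROC summary)."""
    pooled_scores = cv.oof_scores.ravel()
    pooled_labels = np.tile(np.asarray(labels), cv.repeats)
    r = roc(pooled_scores, pooled_labels)
    r.auc = cv.auc_mean
    r.auc_sd = cv.auc_sd
    return r


def select_threshold(r: ROCResult) -> float:
    """Decision threshold at the intersection of the sensitivity and
    specificity curves: the threshold minimizing |sens - spec|, with linear
    interpolation where the curves cross between grid points and ties broken
    toward the lower threshold."""
    if len(r.thresholds) < 2:
        raise ValidationError("degenerate single-point threshold grid")
    d = r.sensitivity - r.specificity
    for i in range(len(d)):
        if d[i] == 0:
            return float(r.thresholds[i])
        if i + 1 < len(d) and d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            return float(r.thresholds[i] + frac * (r.thresholds[i + 1] - r.thresholds[i]))
    return float(r.thresholds[int(np.argmin(np.abs(d)))])


# -- permutation testing ---------------------------------------------------


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float

    def to_dict(self) -> dict:
        return {
            "observed": float(self.observed),
            "permuted": self.permuted.tolist(),
            "p_value": float(self.p_value),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PermutationResult":
        return cls(float(d["observed"]), np.asarray(d["permuted"], float),
                   float(d["p_value"]))


def permutation_test(
    X,
    y,
    n_lv: int,
    B: int = 200,
    k: int = 3,
    repeats: int = 1,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of the cross-validated AUROC.

    The CV-AUROC is recomputed from scratch for each of B permutations of the
    class labels; p = (#{AUC_perm >= AUC_obs} + 1) / (B + 1), never zero.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    X = _as_matrix(X)
    y = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)

    def cv_auc(yv: np.ndarray, cv_seed: int) -> float:
        cv = cross_validate(X, yv, max_lv=n_lv, k=k, repeats=repeats, seed=cv_seed)
        scores = cv.oof_scores  # at chosen LV <= n_lv
        return float(np.mean([auc_mann_whitney(scores[r], yv)
                              for r in range(cv.repeats)]))

    observed = cv_auc(y, seed)
    permuted = np.empty(B)
    for b in range(B):
        yp = rng.permutation(y)
        try:
            permuted[b] = cv_auc(yp, seed + b + 1)
        except ValidationError:
            permuted[b] = 0.5  # degenerate permutation: no information
    p = (np.count_nonzero(permuted >= observed) + 1) / (B + 1)
    return PermutationResult(observed, permuted, float(p))


# -- PCA -------------------------------------------------------------------


def pca(X, n_pc: int):
    """PCA of an autoscaled matrix via SVD.

    Returns (scores, loadings, explained variance fractions), components
    ordered by explained variance; raises when n_pc exceeds the matrix rank.
    """
    X = _as_matrix(X)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(Xc.shape) * np.finfo(float).eps)) if s.size else 0
    if n_pc > rank:
        raise ValidationError(f"n_pc={n_pc} exceeds rank {rank}")
    scores = U[:, :n_pc] * s[:n_pc]
    loadings = Vt[:n_pc].T
    explained = (s**2) / (s**2).sum()
    return scores, loadings, explained[:n_pc]
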