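"""Radial-SVM training and evaluation: ROC/AUC, accuracy, calibration,
exact kernel SHAP, decision-curve analysis, and per-phenotype sub-models."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
@dataclass
class SvmModel:
    """Radial-kernel SVM with frozen standardization and a Platt-style
    sigmoid mapping from decision values to probabilities.  All parameters
    are plain arrays so the model serializes to JSON and round-trips
    bit-exactly."""

    feature_names: list
    means: np.ndarray
    sds: np.ndarray
    gamma: float
    C: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.means) / self.sds

    def decision_function(self, x) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            x = x[self.feature_names].to_numpy(dtype=float)
        z = self._standardize(np.atleast_2d(x))
        d2 = (np.sum(z ** 2, axis=1)[:, None]
              + np.sum(self.support_vectors ** 2, axis=1)[None, :]
              - 2.0 * z @ self.support_vectors.T)
        kernel = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return kernel @ self.dual_coef + self.intercept

    def predict_proba(self, x) -> np.ndarray:
        p = expit(self.platt_a * self.decision_function(x) + self.platt_b)
        return np.clip(p, 1e-12, 1 - 1e-12)

    def predict(self, x, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(x) >= threshold).astype(int)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "gamma": self.gamma,
            "C": self.C,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "SvmModel":
        return cls(
            feature_names=list(d["feature_names"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            gamma=float(d["gamma"]),
            C=float(d["C"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
        )

    @classmethod
    def load(cls, path) -> "SvmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_sigmoid(decision: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-10):
    """Logistic fit of y on decision values (Platt scaling)."""
    X = np.column_stack([decision, np.ones_like(decision)])
    beta = np.zeros(2)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None]) + 1e-10 * np.eye(2)
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[0]), float(beta[1])


def train_radial_svm(x: pd.DataFrame, y, C: float = 1.0, gamma: float | None = None,
                     calibration_folds: int = 5, seed: int = 0) -> SvmModel:
    """Soft-margin RBF SVM on standardized features; probabilities come from
    a sigmoid fit on cross-validated decision values."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    values = x.to_numpy(dtype=float)
    p = values.shape[1]
    if gamma is None:
        gamma = 1.0 / p
    means = values.mean(axis=0)
    sds = values.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    z = (values - means) / sds

    clf = SVC(C=C, kernel="rbf", gamma=gamma)
    clf.fit(z, y)

    # cross-validated decision values for calibration
    n_folds = min(calibration_folds, int(np.min(np.bincount(y))))
    dec_cv = np.empty(y.size)
    if n_folds >= 2:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(z, y):
            fold_clf = SVC(C=C, kernel="rbf", gamma=gamma)
            fold_clf.fit(z[tr], y[tr])
            dec_cv[te] = fold_clf.decision_function(z[te])
    else:
        dec_cv = clf.decision_function(z)
    a, b = _fit_sigmoid(dec_cv, y.astype(float))
    if a < 0:  # guard: decision values should increase with class 1
        a, b = _fit_sigmoid(clf.decision_function(z), y.astype(float))

    return SvmModel(
        feature_names=list(x.columns),
        means=means, sds=sds, gamma=float(gamma), C=float(C),
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        platt_a=a, platt_b=b,
    )


# ---------------------------------------------------------------------------
def roc_auc(scores, y):
    """ROC points over the unique-score threshold sweep and trapezoidal AUC
    (equals the Mann-Whitney U statistic with half credit for ties)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s, lab = scores[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(lab)[distinct]
    fps = np.cumsum(1 - lab)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return points, auc


def accuracy(probs, y, threshold: float = 0.5) -> float:
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    return float(np.mean((probs >= threshold).astype(int) == y))


def calibration_curve(probs, y, bins: int = 10) -> pd.DataFrame:
    """Equal-width bins on [0, 1]; per-bin mean predicted probability and
    observed event rate; empty bins omitted."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = which == b
        if not sel.any():
            continue
        rows.append((b, float(edges[b]), float(edges[b + 1]), int(sel.sum()),
                     float(probs[sel].mean()), float(y[sel].mean())))
    return pd.DataFrame(rows, columns=["bin", "lo", "hi", "n",
                                       "mean_predicted", "observed_rate"])


# ---------------------------------------------------------------------------
def kernel_shap(model, background, explain, batch_rows: int = 200_000):
    """Exact Shapley attributions by full coalition enumeration.

    ``model`` is an :class:`SvmModel` (its calibrated probability is
    explained) or any callable mapping a 2-D array to outputs.  Absent
    features are marginalized by substituting background rows and averaging.
    Returns (shap matrix [n_explain x p], base value).
    """
    f = model.predict_proba if isinstance(model, SvmModel) else model
    if isinstance(background, pd.DataFrame):
        background = background.to_numpy(dtype=float)
    if isinstance(explain, pd.DataFrame):
        explain = explain.to_numpy(dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    explain = np.atleast_2d(np.asarray(explain, dtype=float))
    p = explain.shape[1]
    if p > 20:
        raise ValueError("exact enumeration limited to p <= 20 features; "
                         "a sampling mode is not implemented")
    ne, nb = explain.shape[0], background.shape[0]

    # v[S] for every coalition bitmask
    v = np.empty((2 ** p, ne))
    rows_per_subset = ne * nb
    for mask_bits in range(2 ** p):
        member = np.array([(mask_bits >> j) & 1 for j in range(p)], dtype=bool)
        # explained values on member features, background elsewhere
        z = np.where(member[None, None, :], explain[:, None, :], background[None, :, :])
        out = np.asarray(f(z.reshape(rows_per_subset, p)), dtype=float)
        v[mask_bits] = out.reshape(ne, nb).mean(axis=1)

    base = float(v[0].mean())  # identical for every explained row
    weights = np.array([1.0 / (p * comb(p - 1, s)) for s in range(p)])
    phi = np.zeros((ne, p))
    size_of = np.array([bin(m).count("1") for m in range(2 ** p)])
    for mask_bits in range(2 ** p):
        s = size_of[mask_bits]
        for j in range(p):
            if (mask_bits >> j) & 1:
                continue
            phi[:, j] += weights[s] * (v[mask_bits | (1 << j)] - v[mask_bits])
    return phi, base


# ---------------------------------------------------------------------------
def decision_curve(prob_sets: dict, y, thresholds=None) -> pd.DataFrame:
    """Net benefit NB(p_t) = TP/n - (FP/n) * p_t/(1-p_t) per model across a
    threshold grid, plus treat-all and treat-none reference curves."""
    y = np.asarray(y, dtype=int)
    n = y.size
    prevalence = y.mean()
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.801, 0.01), 10)
    thresholds = np.asarray([t for t in thresholds if t < 1.0], dtype=float)
    rows = []
    curves = dict(prob_sets)
    for name, probs in curves.items():
        probs = np.asarray(probs, dtype=float)
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError(f"probabilities for {name!r} must lie in [0, 1]")
        for t in thresholds:
            predicted = probs >= t
            tp = np.sum(predicted & (y == 1)) / n
            fp = np.sum(predicted & (y == 0)) / n
            rows.append((name, t, tp - fp * t / (1 - t)))
    for t in thresholds:
        rows.append(("treat_all", t, prevalence - (1 - prevalence) * t / (1 - t)))
        rows.append(("treat_none", t, 0.0))
    return pd.DataFrame(rows, columns=["model", "threshold", "net_benefit"])


# ---------------------------------------------------------------------------
def univariate_clinical_roc(traits: pd.DataFrame, y, variables=None) -> pd.DataFrame:
    """Per-variable univariate-logistic AUC and the Youden-J best threshold
    reported on the original variable scale."""
    from .selection import _logistic_irls

    y = np.asarray(y, dtype=int)
    variables = variables or list(traits.columns)
    rows = []
    for var in variables:
        x = traits[var].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        xv, yv = x[ok], y[ok]
        sd = xv.std()
        xs = (xv - xv.mean()) / (sd if sd > 0 else 1.0)
        slope, *_ = _logistic_irls(xs, yv.astype(float))
        score = slope * xs
        points, auc = roc_auc(score, yv)
        j = points["tpr"] - points["fpr"]
        best = int(np.argmax(j.to_numpy()))
        thr_score = points["threshold"].iloc[best]
        # "score >= t" keeps the same confusion matrix for any t down to the
        # next lower score; report the midpoint of that interval
        if best + 1 < len(points):
            thr_score = 0.5 * (thr_score + points["threshold"].iloc[best + 1])
        if np.isfinite(thr_score) and slope != 0:
            thr = thr_score / slope * (sd if sd > 0 else 1.0) + xv.mean()
        else:
            thr = np.nan
        rows.append((var, float(auc), float(thr), float(slope)))
    return pd.DataFrame(rows, columns=["variable", "auc", "best_threshold", "slope"])


# ---------------------------------------------------------------------------
@dataclass
class EvaluationReport:
    auc: float
    accuracy: float
    roc_points: pd.DataFrame
    calibration: pd.DataFrame
    probs: np.ndarray
    shap_values: np.ndarray | None = None
    shap_base: float | None = None

    def to_dict(self) -> dict:
        return {"auc": self.auc, "accuracy": self.accuracy}


def evaluate_model(model: SvmModel, x: pd.DataFrame, y, bins: int = 10,
                   with_shap: bool = False, background: pd.DataFrame | None = None
                   ) -> EvaluationReport:
    probs = model.predict_proba(x)
    points, auc = roc_auc(probs, y)
    rep = EvaluationReport(
        auc=auc, accuracy=accuracy(probs, y),
        roc_points=points, calibration=calibration_curve(probs, y, bins=bins),
        probs=probs,
    )
    if with_shap:
        bg = background if background is not None else x
        rep.shap_values, rep.shap_base = kernel_shap(model, bg[model.feature_names], x[model.feature_names])
    return rep


def _logistic_probs(x_train: pd.DataFrame, y_train, x_eval: pd.DataFrame) -> np.ndarray:
    """Multivariate logistic probabilities (for the DCA comparison models)."""
    from sklearn.linear_model import LogisticRegression

    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0).replace(0, 1.0)
    clf = LogisticRegression(max_iter=2000, C=1e6)
    clf.fit((x_train - mu) / sd, np.asarray(y_train, dtype=int))
    return clf.predict_proba((x_eval - mu) / sd)[:, 1]


def evaluate_submodels(panel_train: pd.DataFrame, y_train,
                       panel_valid: pd.DataFrame | None, y_valid,
                       types: dict, C: float = 1.0, seed: int = 0,
                       dca_thresholds=None) -> dict:
    """Train one radial SVM per phenotype type plus the full model, evaluate
    on train and (when given) validation, and run DCA on logistic-model
    probabilities per type."""
    groups: dict[str, list] = {"full": list(panel_train.columns)}
    for feat in panel_train.columns:
        groups.setdefault(types.get(feat, "molecular"), []).append(feat)

    report: dict[str, dict] = {}
    dca_probs_train: dict[str, np.ndarray] = {}
    dca_probs_valid: dict[str, np.ndarray] = {}
    for name, feats in groups.items():
        if not feats:
            log.warning("phenotype type %s has no features; skipped", name)
            continue
        model = train_radial_svm(panel_train[feats], y_train, C=C, seed=seed)
        entry = {"features": feats,
                 "train": evaluate_model(model, panel_train[feats], y_train).to_dict()}
        if panel_valid is not None:
            entry["valid"] = evaluate_model(model, panel_valid[feats], y_valid).to_dict()
        report[name] = entry
        dca_probs_train[name] = _logistic_probs(panel_train[feats], y_train,
                                                panel_train[feats])
        if panel_valid is not None:
            dca_probs_valid[name] = _logistic_probs(panel_train[feats], y_train,
                                                    panel_valid[feats])
    dca = {"train": decision_curve(dca_probs_train, y_train, thresholds=dca_thresholds)}
    if panel_valid is not None:
        dca["valid"] = decision_curve(dca_probs_valid, y_valid, thresholds=dca_thresholds)
    return {"models": report, "dca": dca}
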