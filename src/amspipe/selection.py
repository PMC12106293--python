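"""Clinical screening and MI-driven recursive feature elimination.

The molecular route ranks features by a nearest-neighbor mutual-information
estimate against the binary label, averaged over stratified CV folds; the
surviving set is halved each round while it exceeds ``halve_above`` and then
shrunk one feature at a time.  A radial-kernel SVM estimates the
generalization error of the top-1..k_max feature subsets, and the candidate
panel is filtered by univariate logistic regression with a Bonferroni
family-wise correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, expit
from scipy.stats import chi2, fisher_exact, mannwhitneyu, norm, rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .matrix import CLINICAL_VARIABLES

log = logging.getLogger(__name__)

CATEGORICAL_CLINICAL = {"Smoke"}


# ---------------------------------------------------------------------------
def screen_clinical(traits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable two-group tests against the binary AMS label: Fisher's
    exact test for categorical variables, two-sided Mann-Whitney otherwise.
    Selection is at raw p < alpha (no multiplicity correction)."""
    if "AMS" not in traits.columns:
        raise ValueError("traits table must contain the AMS label")
    y = traits["AMS"].to_numpy(dtype=float)
    rows = []
    for var in [c for c in CLINICAL_VARIABLES if c in traits.columns]:
        x = traits[var].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        x0, x1 = x[ok & (y == 0)], x[ok & (y == 1)]
        if min(x0.size, x1.size) < 2:
            log.warning("variable %s skipped: fewer than 2 observations per group", var)
            continue
        if var in CATEGORICAL_CLINICAL:
            table = [[np.sum(x1 == 1), np.sum(x1 == 0)],
                     [np.sum(x0 == 1), np.sum(x0 == 0)]]
            stat, p = fisher_exact(table, alternative="two-sided")
            test = "fisher"
        else:
            stat, p = mannwhitneyu(x1, x0, alternative="two-sided", method="auto")
            test = "mannwhitney"
        rows.append((var, test, float(stat), float(p), p < alpha))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p", "selected"])


# ---------------------------------------------------------------------------
def mutual_information(x, y, k: int = 3) -> float:
    """Nearest-neighbor MI (nats) between a continuous vector and a discrete
    label; negative estimates are clipped at zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = x.size
    if n < 10:
        raise ValueError("mutual_information needs length >= 10")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if np.ptp(x) == 0:
        return 0.0

    radius = np.empty(n)
    k_used = np.empty(n)
    label_count = np.empty(n)
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        kc = min(k, cnt - 1)
        label_count[idx] = cnt
        if kc < 1:
            # singleton class: point carries no within-class neighborhood
            radius[idx] = 0.0
            k_used[idx] = 1
            continue
        order = np.argsort(x[idx], kind="mergesort")
        xs = x[idx][order]
        # kth-NN distance via the sliding window of kc+1 consecutive points
        r_sorted = np.empty(idx.size)
        for t in range(idx.size):
            best = np.inf
            for s in range(max(0, t - kc), min(t, idx.size - 1 - kc) + 1):
                width = max(xs[t] - xs[s], xs[s + kc] - xs[t])
                best = min(best, width)
            r_sorted[t] = best
        r = np.empty(idx.size)
        r[order] = r_sorted
        radius[idx] = r
        k_used[idx] = kc

    # count points strictly inside the kth-neighbor distance (self included);
    # exact distances, chunked to bound memory at large n
    m_all = np.empty(n)
    chunk = max(1, 2_000_000 // n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        dist = np.abs(x[None, :] - x[start:stop, None])
        m_all[start:stop] = np.sum(dist < radius[start:stop, None], axis=1)
    m_all = np.maximum(m_all, 1)
    mi = (digamma(n) + np.mean(digamma(k_used)) - np.mean(digamma(label_count))
          - np.mean(digamma(m_all)))
    return float(max(mi, 0.0))


# ---------------------------------------------------------------------------
@dataclass
class FeatureRanking:
    elimination_order: list            # first eliminated ... last eliminated
    rank: dict                         # feature -> 1..p (1 = best)
    rounds: list = field(default_factory=list)
    seed: int = 0

    def top(self, k: int) -> list:
        ordered = sorted(self.rank, key=self.rank.get)
        return ordered[:k]


@dataclass
class CvErrorCurve:
    k: list
    mean_error: list
    sd_error: list
    chosen_k: int


def _stratified_folds(y: np.ndarray, k_folds: int, rng: np.random.Generator,
                      max_attempts: int = 100):
    for _ in range(max_attempts):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31 - 1)))
        folds = list(skf.split(np.zeros_like(y), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise RuntimeError("could not draw a stratified partition with both classes")


def mi_svm_rfe(x: pd.DataFrame, y, k_folds: int = 3, halve_above: int = 100,
               seed: int = 0, mi_neighbors: int = 3) -> FeatureRanking:
    """Recursive elimination by fold-averaged MI rank.

    Each round draws a fresh stratified k-fold partition, ranks every
    surviving feature by MI against the label within each fold's training
    portion (rank 1 = most informative), averages the ranks, and eliminates
    the worst floor(p/2) features while more than ``halve_above`` survive,
    else the single worst.  Final rank is the reverse elimination order.
    """
    y = np.asarray(y, dtype=int)
    features = list(x.columns)
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    values = x.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    surviving = list(range(len(features)))
    eliminated: list[str] = []
    rounds = []

    while len(surviving) > 1:
        folds = _stratified_folds(y, k_folds, rng)
        ranks = np.zeros(len(surviving))
        for tr, _ in folds:
            mis = np.array([mutual_information(values[tr, j], y[tr], k=mi_neighbors)
                            for j in surviving])
            # descending MI -> ascending rank; ties share the average rank so
            # that column order never influences the outcome
            ranks += rankdata(-mis, method="average")
        ranks /= k_folds
        p = len(surviving)
        n_drop = p // 2 if p > halve_above else 1
        # worst averaged rank out; remaining ties broken by feature name
        order = sorted(range(p),
                       key=lambda j: (-ranks[j], features[surviving[j]]))
        dropped = sorted(order[:n_drop])
        dropped_feats = [features[surviving[j]] for j in dropped]
        rounds.append({"surviving": p, "eliminated": dropped_feats})
        eliminated.extend(dropped_feats)
        surviving = [s for i, s in enumerate(surviving) if i not in set(dropped)]
    eliminated.append(features[surviving[0]])

    rank = {f: len(features) - i for i, f in enumerate(eliminated)}
    return FeatureRanking(elimination_order=eliminated, rank=rank,
                          rounds=rounds, seed=seed)


def estimate_error_curve(x: pd.DataFrame, y, ranking: FeatureRanking,
                         k_max: int = 30, k_folds: int = 3, n_repeats: int = 20,
                         seed: int = 0, C: float = 1.0) -> CvErrorCurve:
    """Repeated stratified CV misclassification error of a radial SVM on the
    top-k ranked features, for k = 1..k_max; chosen k = argmin mean error
    with the smallest-k tie-break."""
    y = np.asarray(y, dtype=int)
    p = x.shape[1]
    if k_max > p:
        log.warning("k_max %d > %d features; truncated", k_max, p)
        k_max = p
    rng = np.random.default_rng(seed)
    ordered = ranking.top(p)
    values = x[ordered].to_numpy(dtype=float)

    means, sds = [], []
    for k in range(1, k_max + 1):
        xk = values[:, :k]
        errs = []
        for _ in range(n_repeats):
            folds = _stratified_folds(y, k_folds, rng)
            wrong = 0
            for tr, te in folds:
                mu, sd = xk[tr].mean(axis=0), xk[tr].std(axis=0)
                sd = np.where(sd == 0, 1.0, sd)
                clf = SVC(C=C, kernel="rbf", gamma=1.0 / k)
                clf.fit((xk[tr] - mu) / sd, y[tr])
                wrong += int(np.sum(clf.predict((xk[te] - mu) / sd) != y[te]))
            errs.append(wrong / y.size)
        means.append(float(np.mean(errs)))
        sds.append(float(np.std(errs)))
    chosen = int(np.argmin(means)) + 1
    return CvErrorCurve(k=list(range(1, k_max + 1)), mean_error=means,
                        sd_error=sds, chosen_k=chosen)


# ---------------------------------------------------------------------------
@dataclass
class BiomarkerPanel:
    table: pd.DataFrame       # feature, type, slope, p, p_bonferroni, selected
    family_size: int

    @property
    def selected(self) -> list:
        return self.table.loc[self.table["selected"], "feature"].tolist()


def _logistic_irls(x: np.ndarray, y: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-8):
    """Univariate logistic fit (intercept + slope) by IRLS.

    Returns (slope, wald_p, converged, loglik, loglik_null).
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    loglik_null = float(np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar)))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    se = np.sqrt(max(cov[1, 1], 1e-300))
    zstat = beta[1] / se
    wald_p = 2 * norm.sf(abs(zstat))
    return float(beta[1]), float(wald_p), converged, loglik, loglik_null


def univariate_logistic_filter(candidates: pd.DataFrame, y, alpha: float = 0.05,
                               types: dict | None = None) -> BiomarkerPanel:
    """Per-candidate univariate logistic regression (on standardized values)
    with a Bonferroni-corrected Wald test; complete separation falls back to
    a likelihood-ratio p-value."""
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    m = candidates.shape[1]
    rows = []
    for feat in candidates.columns:
        x = candidates[feat].to_numpy(dtype=float)
        sd = x.std()
        xs = (x - x.mean()) / (sd if sd > 0 else 1.0)
        slope, p, converged, ll, ll0 = _logistic_irls(xs, y)
        if not converged or abs(slope) > 15:
            lrt = 2 * (ll - ll0)
            p = float(chi2.sf(max(lrt, 0.0), df=1))
            log.info("separation detected for %s; LRT p=%.3g used", feat, p)
        p_bonf = min(p * m, 1.0)
        ftype = (types or {}).get(feat, "molecular")
        rows.append((feat, ftype, slope, p, p_bonf, p_bonf < alpha))
    table = pd.DataFrame(rows, columns=["feature", "type", "slope", "p",
                                        "p_bonferroni", "selected"])
    return BiomarkerPanel(table=table, family_size=m)
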