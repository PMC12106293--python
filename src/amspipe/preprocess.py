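"""Abundance-matrix quality control, imputation, and normalization.

Order of operations for a raw matrix (the protein branch; the metabolite
branch skips the sample-missingness filter):

1. mask within-sample outlier cells (> 5 SD from the sample mean)
2. drop samples with missing fraction > 20% (proteins only)
3. drop samples whose KS distance to the pooled distribution exceeds
   Q3 + 1.5*IQR of per-sample KS distances
4. drop features with missing fraction above the per-omic threshold
5. log2 transform
6. predictive-mean-matching imputation (chained equations, single imputation)
7. cyclic loess normalization over all sample pairs
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import AbundanceMatrix
from .stats import ks_distance

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    outlier_sd: float = 5.0
    max_sample_missing_frac: float = 0.20
    max_feature_missing_frac_protein: float = 0.50
    max_feature_missing_frac_metabolite: float = 0.10
    ks_fence_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.outlier_sd <= 0 or self.ks_fence_multiplier <= 0:
            raise ValueError("thresholds must be positive")
        for frac in (self.max_sample_missing_frac,
                     self.max_feature_missing_frac_protein,
                     self.max_feature_missing_frac_metabolite):
            if not (0.0 < frac <= 1.0):
                raise ValueError("missingness fractions must lie in (0, 1]")

    def feature_threshold(self, omic: str) -> float:
        return (self.max_feature_missing_frac_protein if omic == "protein"
                else self.max_feature_missing_frac_metabolite)


@dataclass
class QCReport:
    omic: str = ""
    sample_missing_fraction: dict = field(default_factory=dict)
    sample_ks_distance: dict = field(default_factory=dict)
    ks_fence: float | None = None
    excluded_samples: dict = field(default_factory=dict)   # id -> reason
    excluded_features: dict = field(default_factory=dict)  # id -> missing fraction
    stage_counts: list = field(default_factory=list)       # (stage, n_samples, n_features)
    n_outlier_cells_masked: int = 0
    n_imputed_cells: int = 0

    def record(self, stage: str, m: AbundanceMatrix) -> None:
        self.stage_counts.append((stage, m.n_samples, m.n_features))

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
def mask_within_sample_outliers(m: AbundanceMatrix, n_sd: float = 5.0) -> AbundanceMatrix:
    """Set cells deviating more than ``n_sd`` sample SDs from the sample mean
    to missing.  Mean and SD are over the sample's non-missing cells and
    include any candidate outlier."""
    out = m.copy()
    for i in range(out.n_samples):
        obs = ~out.mask[i]
        vals = out.values[i, obs]
        if vals.size < 3:
            log.warning("sample %s has < 3 observed cells; outlier masking skipped",
                        out.samples[i])
            continue
        sd = vals.std()
        if sd == 0:
            continue
        dev = np.abs(out.values[i] - vals.mean()) > n_sd * sd
        newly = dev & obs
        out.mask[i, newly] = True
    out.values = np.where(out.mask, np.nan, out.values)
    return out


def filter_samples_by_missingness(m: AbundanceMatrix, max_frac: float = 0.20):
    frac = m.sample_missing_fraction()
    keep = frac <= max_frac
    excluded = [m.samples[i] for i in np.flatnonzero(~keep)]
    if not keep.any():
        raise RuntimeError("all samples excluded by the missingness filter")
    return m.subset_samples(keep), excluded


def filter_samples_by_ks(m: AbundanceMatrix, fence_multiplier: float = 1.5):
    """Exclude samples whose KS distance to the pooled value distribution
    exceeds Q3 + multiplier*IQR of the per-sample KS distances."""
    pooled = m.values[~m.mask]
    distances = np.array([
        ks_distance(m.values[i, ~m.mask[i]], pooled) for i in range(m.n_samples)
    ])
    if m.n_samples < 4:
        log.warning("KS fence needs >= 4 samples; no exclusion performed")
        return m, [], None, dict(zip(m.samples, distances))
    q1, q3 = np.percentile(distances, [25, 75])
    fence = float(q3 + fence_multiplier * (q3 - q1))
    keep = distances <= fence
    excluded = [m.samples[i] for i in np.flatnonzero(~keep)]
    return m.subset_samples(keep), excluded, fence, dict(zip(m.samples, distances))


def filter_features_by_missingness(m: AbundanceMatrix, max_frac: float,
                                   protect=()):
    """``protect`` lists features exempt from removal (e.g. the biomarker
    panel when re-processing a validation cohort)."""
    frac = m.feature_missing_fraction()
    keep = frac <= max_frac
    if len(protect):
        keep |= np.isin(m.features, list(protect))
    excluded = {m.features[i]: float(frac[i]) for i in np.flatnonzero(~keep)}
    return m.subset_features(keep), excluded


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    if m.scale != "raw":
        raise ValueError("matrix is not on the raw scale")
    bad = (m.values <= 0) & ~m.mask
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive abundance at sample {m.samples[i]!r}, feature {m.features[j]!r}"
        )
    out = m.copy()
    out.values = np.where(out.mask, np.nan, np.log2(np.where(out.mask, 1.0, out.values)))
    out.scale = "log2"
    return out


# ---------------------------------------------------------------------------
def pmm_impute(m: AbundanceMatrix, n_donors: int = 5, n_cycles: int = 10,
               seed: int = 0, n_predictors: int = 20,
               ridge: float = 1e-6) -> AbundanceMatrix:
    """Chained-equations predictive mean matching (single imputation).

    Missing cells are initialised with random observed draws of their own
    feature; then for ``n_cycles`` passes, features with missing cells are
    revisited in order of ascending missingness.  Each target feature is
    regressed (OLS, ridge fallback) on its ``n_predictors`` most-correlated
    features; for each missing row the observed row with one of the
    ``n_donors`` nearest predictions donates its observed value.
    Observed cells are never modified.
    """
    if not m.mask.any():
        return m.copy()
    if m.scale != "log2":
        raise ValueError("pmm_impute expects a log2-scale matrix")
    n, p = m.values.shape
    obs = ~m.mask
    n_obs = obs.sum(axis=0)
    if (n_obs < n_donors).any():
        j = int(np.argmin(n_obs))
        raise ValueError(
            f"feature {m.features[j]!r} has only {int(n_obs[j])} observed values "
            f"(need >= {n_donors})"
        )
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("every sample needs at least one observed value")

    rng = np.random.default_rng(seed)
    filled = m.values.copy()
    for j in np.flatnonzero(m.mask.any(axis=0)):
        miss_rows = np.flatnonzero(m.mask[:, j])
        donors = filled[obs[:, j], j]
        filled[miss_rows, j] = rng.choice(donors, size=miss_rows.size, replace=True)

    # predictor sets fixed after initialization: the most-correlated features
    corr = np.corrcoef(filled, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)

    targets = np.flatnonzero(m.mask.any(axis=0))
    targets = targets[np.argsort(m.mask[:, targets].sum(axis=0), kind="mergesort")]
    pred_of = {
        j: np.argsort(-np.abs(corr[:, j]), kind="mergesort")[: min(n_predictors, p - 1)]
        for j in targets
    }

    for _ in range(n_cycles):
        for j in targets:
            preds = pred_of[j]
            rows_obs = np.flatnonzero(obs[:, j])
            rows_mis = np.flatnonzero(m.mask[:, j])
            X = np.column_stack([np.ones(n), filled[:, preds]])
            Xo, yo = X[rows_obs], filled[rows_obs, j]
            try:
                beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
                if not np.all(np.isfinite(beta)):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                log.warning("singular regression for feature %s; ridge fallback",
                            m.features[j])
                A = Xo.T @ Xo + ridge * np.eye(Xo.shape[1])
                beta = np.linalg.solve(A, Xo.T @ yo)
            yhat = X @ beta
            # nearest-prediction donors
            for i in rows_mis:
                d = np.abs(yhat[rows_obs] - yhat[i])
                nearest = rows_obs[np.argsort(d, kind="mergesort")[:n_donors]]
                donor = nearest[rng.integers(nearest.size)]
                filled[i, j] = m.values[donor, j]

    out = m.copy()
    out.values = filled
    out.mask = np.zeros_like(m.mask)
    return out


# ---------------------------------------------------------------------------
def cyclic_loess_normalize(m: AbundanceMatrix, span: float = 0.7,
                           iterations: int = 3) -> AbundanceMatrix:
    """Pairwise MA-trend removal: for every unordered sample pair, fit a
    loess of M = x_i - x_j on A = (x_i + x_j)/2 and split the fitted trend
    between the two samples; repeated for ``iterations`` passes."""
    if m.mask.any():
        raise ValueError("cyclic loess requires a complete matrix (impute first)")
    out = m.copy()
    x = out.values
    n = out.n_samples
    for _ in range(iterations):
        for i in range(n):
            for j in range(i + 1, n):
                mm = x[i] - x[j]
                aa = (x[i] + x[j]) / 2.0
                span_aa = np.ptp(aa)
                delta = 0.01 * span_aa if span_aa > 0 else 0.0
                fitted = lowess(mm, aa, frac=span, it=0, delta=delta,
                                return_sorted=False)
                x[i] -= fitted / 2.0
                x[j] += fitted / 2.0
    out.values = x
    return out


# ---------------------------------------------------------------------------
def run_qc(m: AbundanceMatrix, thresholds: QCThresholds | None = None,
           seed: int = 0, n_donors: int = 5, n_cycles: int = 10,
           loess_span: float = 0.7, loess_iterations: int = 3,
           protect_features=()):
    """Full per-omic QC chain; returns (processed matrix, QCReport).

    A matrix already on the log2 scale skips the raw-scale steps (outlier
    masking and the log2 transform), which makes the chain idempotent.
    """
    t = thresholds or QCThresholds()
    report = QCReport(omic=m.omic)
    report.record("input", m)

    raw = m.scale == "raw"
    if raw:
        masked = mask_within_sample_outliers(m, t.outlier_sd)
        report.n_outlier_cells_masked = int(masked.mask.sum() - m.mask.sum())
        report.record("outlier_mask", masked)
    else:
        masked = m.copy()

    if m.omic == "protein":
        frac = {s: float(v) for s, v in zip(masked.samples,
                                            masked.sample_missing_fraction())}
        report.sample_missing_fraction = frac
        masked, excl = filter_samples_by_missingness(masked, t.max_sample_missing_frac)
        for s in excl:
            report.excluded_samples[s] = "missingness"
            log.info("sample %s excluded: missing fraction %.3f > %.2f",
                     s, frac[s], t.max_sample_missing_frac)
        report.record("sample_missingness", masked)
    else:
        report.sample_missing_fraction = {
            s: float(v) for s, v in zip(masked.samples, masked.sample_missing_fraction())
        }

    masked, excl_ks, fence, distances = filter_samples_by_ks(masked, t.ks_fence_multiplier)
    report.sample_ks_distance = {k: float(v) for k, v in distances.items()}
    report.ks_fence = fence
    for s in excl_ks:
        report.excluded_samples[s] = "ks_outlier"
        log.info("sample %s excluded: KS %.4f > fence %.4f", s, distances[s], fence)
    report.record("ks_filter", masked)

    masked, excl_feat = filter_features_by_missingness(
        masked, t.feature_threshold(m.omic), protect=protect_features)
    report.excluded_features = excl_feat
    report.record("feature_missingness", masked)

    if raw:
        masked = log2_transform(masked)
    n_missing = int(masked.mask.sum())
    imputed = pmm_impute(masked, n_donors=n_donors, n_cycles=n_cycles, seed=seed)
    report.n_imputed_cells = n_missing
    report.record("pmm_impute", imputed)

    normalized = cyclic_loess_normalize(imputed, span=loess_span,
                                        iterations=loess_iterations)
    report.record("cyclic_loess", normalized)
    return normalized, report
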