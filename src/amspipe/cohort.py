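"""Synthetic two-cohort generator.

Produces protein and metabolite abundance matrices with block co-expression
structure (latent module factors), a clinical table, an ordinal illness
degree, and a ground-truth manifest, so that every downstream stage can be
tested without external data.  Raw abundances are strictly positive
(exponentiated log2 signal) and optionally corrupted with MCAR missingness,
within-sample outliers, and globally shifted samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix, CLINICAL_VARIABLES

# Overall cohort medians and quartiles (median, Q1, Q3) used to parameterise
# the clinical variables; Smoke is a Bernoulli rate.
CLINICAL_BASELINE: dict[str, tuple[float, float, float]] = {
    "Age": (23.0, 21.0, 24.0),
    "BMI": (22.0, 21.0, 24.0),
    "SBP": (120.0, 112.0, 125.0),
    "DBP": (76.0, 70.0, 83.5),
    "HR": (76.0, 67.0, 85.0),
    "SpO2": (99.0, 98.0, 99.0),
    "FVC": (3.46, 2.71, 4.31),
    "FEV1": (3.10, 2.13, 3.79),
    "PEF": (472.0, 320.0, 530.0),
    "FEV1_FVC": (1.00, 0.83, 1.00),
    "WBC": (5.97, 5.19, 6.43),
    "NE": (2.80, 2.33, 3.42),
    "LY": (2.32, 1.99, 2.75),
    "RBC": (5.30, 5.08, 5.47),
    "HGB": (157.0, 150.0, 162.0),
    "PLT": (228.0, 200.0, 251.0),
    "ALT": (0.27, 0.23, 0.36),
    "AST": (0.33, 0.27, 0.39),
    "TBIL": (15.5, 12.7, 22.7),
    "UA": (374.0, 344.0, 413.0),
    "UREA": (5.57, 4.68, 6.35),
    "CREA": (76.5, 68.0, 82.1),
    "CKMB": (0.27, 0.22, 0.33),
    "LDH": (2.96, 2.66, 3.27),
    "GLU": (4.51, 4.16, 4.88),
}
SMOKE_RATE = 0.45

# Group-shifted clinical variables: variable -> (median non-ill, median ill,
# normal-scale dispersion sigma).
DEFAULT_CLINICAL_EFFECTS: dict[str, tuple[float, float, float]] = {
    "SBP": (116.0, 120.0, 9.5),
    "FEV1": (3.29, 2.34, 1.0),
    "PEF": (509.0, 366.0, 130.0),
    "FEV1_FVC": (1.00, 0.93, 0.12),
}

_IQR_TO_SD = 1.349  # normal IQR -> SD


def _default_clinical_effects() -> dict[str, tuple[float, float, float]]:
    return dict(DEFAULT_CLINICAL_EFFECTS)


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_train: int = 66
    n_valid: int = 24
    n_proteins: int = 429
    n_metabolites: int = 984
    n_modules: int = 17
    min_module_size: int = 45
    n_ams_modules: int = 6
    n_informative_features: int = 10
    effect_size_d: float = 1.2
    module_effect: float = 1.2
    clinical_effects: dict = field(default_factory=_default_clinical_effects)
    missing_rate_mcar: float = 0.02
    outlier_cell_rate: float = 0.002
    n_shifted_samples: int = 0
    sample_scale_sd: float = 0.3
    loading_range: tuple = (0.6, 0.95)
    noise_sd: float = 0.8
    degree_probs: tuple = (41 / 83, 37 / 83, 5 / 83)

    def validate(self) -> None:
        if self.n_modules * self.min_module_size > self.n_proteins + self.n_metabolites:
            raise ValueError(
                "module_capacity: n_modules * min_module_size exceeds total feature count"
            )
        for name in ("missing_rate_mcar", "outlier_cell_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}: must lie in [0, 1), got {v}")
        if self.effect_size_d < 0:
            raise ValueError(f"effect_size_d: must be >= 0, got {self.effect_size_d}")
        if self.n_ams_modules > self.n_modules:
            raise ValueError("n_ams_modules: exceeds n_modules")
        if self.n_ams_modules == 0 and self.n_informative_features > 0:
            raise ValueError(
                "n_informative_features: informative features require at least one AMS module"
            )
        if self.n_train < 4 or self.n_valid < 0:
            raise ValueError("cohort_size: n_train must be >= 4 and n_valid >= 0")
        if self.n_shifted_samples < 0 or self.n_shifted_samples > self.n_train + self.n_valid:
            raise ValueError("n_shifted_samples: out of range")
        if self.sample_scale_sd < 0:
            raise ValueError("sample_scale_sd: must be >= 0")


@dataclass
class GroundTruthManifest:
    module_of_feature: dict
    informative_features: dict          # feature -> signed effect size (log2 SD units)
    ams_modules: list
    shifted_samples: list
    clinical_effects: dict
    latent_factors: dict                # module -> per-sample factor list
    train_samples: list
    valid_samples: list
    ams_degree: dict
    outlier_cells: list = field(default_factory=list)  # (sample, feature) pairs
    n_injected_missing: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _draw_degrees(rng: np.random.Generator, n: int, probs) -> np.ndarray:
    """Ordinal illness degree 0/1/2 with both binary classes guaranteed."""
    for _ in range(100):
        deg = rng.choice(len(probs), size=n, p=np.asarray(probs) / np.sum(probs))
        y = (deg > 0).astype(int)
        if 0 < y.sum() < n:
            return deg
    raise RuntimeError("could not draw labels with both classes present")


def _module_sizes(rng: np.random.Generator, n_features: int, n_modules: int,
                  min_size: int) -> np.ndarray:
    sizes = np.full(n_modules, min_size, dtype=int)
    extra = n_features - sizes.sum()
    if extra > 0:
        sizes += rng.multinomial(extra, np.full(n_modules, 1.0 / n_modules))
    return sizes


def generate_cohort(config: GeneratorConfig):
    """Generate (protein matrix, metabolite matrix, clinical table, manifest).

    Matrices contain the full train+validation sample set; the split is
    recorded in the manifest.  Values are raw positive abundances with no
    missingness (see :func:`inject_missing_and_outliers`).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_train + config.n_valid
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    train_ids = sample_ids[: config.n_train]
    valid_ids = sample_ids[config.n_train:]

    degree = _draw_degrees(rng, n, config.degree_probs)
    if config.n_valid:
        # both classes in each cohort
        for _ in range(100):
            y_tr = degree[: config.n_train] > 0
            y_va = degree[config.n_train:] > 0
            if 0 < y_tr.sum() < y_tr.size and 0 < y_va.sum() < y_va.size:
                break
            degree = _draw_degrees(rng, n, config.degree_probs)
    y = (degree > 0).astype(int)

    # --- feature -> module assignment over both omics jointly -------------
    feature_ids = [f"P{i + 1:04d}" for i in range(config.n_proteins)] + [
        f"X{i + 1:04d}" for i in range(config.n_metabolites)
    ]
    p_total = len(feature_ids)
    sizes = _module_sizes(rng, p_total, config.n_modules, config.min_module_size)
    perm = rng.permutation(p_total)
    module_of = np.empty(p_total, dtype=int)
    start = 0
    for m, sz in enumerate(sizes):
        module_of[perm[start:start + sz]] = m
        start += sz
    module_names = [f"M{m + 1}" for m in range(config.n_modules)]

    ams_modules = sorted(rng.choice(config.n_modules, size=config.n_ams_modules,
                                    replace=False).tolist())
    module_sign = np.where(rng.random(config.n_modules) < 0.5, -1.0, 1.0)

    # --- latent module factors -------------------------------------------
    factors = rng.standard_normal((config.n_modules, n))
    for m in ams_modules:
        factors[m] += config.module_effect * module_sign[m] * degree

    # --- informative features --------------------------------------------
    ams_feature_pool = np.flatnonzero(np.isin(module_of, ams_modules))
    informative_idx = rng.choice(ams_feature_pool, size=config.n_informative_features,
                                 replace=False) if config.n_informative_features else np.array([], dtype=int)
    # the direct effect reinforces the module's own shift direction so the two
    # planted signals cannot cancel
    informative_sign = np.array([module_sign[module_of[j]] for j in informative_idx])

    # --- molecular signal on the log2 scale ------------------------------
    loadings = rng.uniform(*config.loading_range, size=p_total)
    noise = rng.standard_normal((n, p_total)) * config.noise_sd
    signal = loadings[None, :] * factors[module_of].T + noise
    sd_feature = np.sqrt(loadings ** 2 + config.noise_sd ** 2)
    informative_effects: dict[str, float] = {}
    for j, sgn in zip(informative_idx, informative_sign):
        shift = sgn * config.effect_size_d * sd_feature[j]
        signal[:, j] += shift * y
        informative_effects[feature_ids[j]] = float(sgn * config.effect_size_d)

    baseline = rng.uniform(3.0, 10.0, size=p_total)
    offsets_p = rng.normal(0.0, config.sample_scale_sd, size=n) if config.sample_scale_sd else np.zeros(n)
    offsets_m = rng.normal(0.0, config.sample_scale_sd, size=n) if config.sample_scale_sd else np.zeros(n)

    log2_all = signal + baseline[None, :]
    raw_prot = 2.0 ** (log2_all[:, : config.n_proteins] + offsets_p[:, None])
    raw_met = 2.0 ** (log2_all[:, config.n_proteins:] + offsets_m[:, None])

    proteins = AbundanceMatrix(samples=sample_ids,
                               features=feature_ids[: config.n_proteins],
                               values=raw_prot, omic="protein", scale="raw")
    metabolites = AbundanceMatrix(samples=sample_ids,
                                  features=feature_ids[config.n_proteins:],
                                  values=raw_met, omic="metabolite", scale="raw")

    clinical = _generate_clinical(rng, sample_ids, y, degree, config.clinical_effects)

    manifest = GroundTruthManifest(
        module_of_feature={f: module_names[m] for f, m in zip(feature_ids, module_of)},
        informative_features=informative_effects,
        ams_modules=[module_names[m] for m in ams_modules],
        shifted_samples=[],
        clinical_effects={k: list(v) for k, v in config.clinical_effects.items()},
        latent_factors={module_names[m]: factors[m].tolist() for m in range(config.n_modules)},
        train_samples=train_ids,
        valid_samples=valid_ids,
        ams_degree={s: int(d) for s, d in zip(sample_ids, degree)},
    )
    return proteins, metabolites, clinical, manifest


def _generate_clinical(rng, sample_ids, y, degree, clinical_effects) -> pd.DataFrame:
    n = len(sample_ids)
    data: dict[str, np.ndarray] = {}
    for var in CLINICAL_VARIABLES:
        if var == "Smoke":
            data[var] = rng.binomial(1, SMOKE_RATE, size=n).astype(float)
            continue
        if var in clinical_effects:
            med0, med1, sigma = clinical_effects[var]
            mean = np.where(y == 1, med1, med0).astype(float)
        else:
            med, q1, q3 = CLINICAL_BASELINE[var]
            mean = np.full(n, med)
            sigma = (q3 - q1) / _IQR_TO_SD
            sigma = max(sigma, 1e-6)
        vals = rng.normal(mean, sigma)
        if var == "SpO2":
            vals = np.clip(vals, 85.0, 100.0)
        elif var == "FEV1_FVC":
            vals = np.clip(vals, 0.2, 1.0)
        else:
            vals = np.maximum(vals, 0.01)
        data[var] = vals
    df = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample"))
    df["AMS"] = y
    df["AMS_degree"] = degree
    return df


def inject_missing_and_outliers(matrix: AbundanceMatrix, config: GeneratorConfig,
                                manifest: GroundTruthManifest | None = None) -> AbundanceMatrix:
    """Corrupt a complete raw matrix with MCAR missingness, >5-SD outlier
    cells, and globally shifted samples; records what was planted in the
    manifest when one is supplied."""
    config.validate()
    if matrix.mask.any():
        raise ValueError("input matrix must be complete")
    omic_key = {"protein": 1, "metabolite": 2}[matrix.omic]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE, omic_key]))
    out = matrix.copy()
    n, p = out.values.shape

    # global distributional shift on the log2 scale (location + scale)
    shifted: list[str] = []
    if config.n_shifted_samples:
        idx = rng.choice(n, size=config.n_shifted_samples, replace=False)
        for i in idx:
            lv = np.log2(out.values[i])
            med = np.median(lv)
            out.values[i] = 2.0 ** (1.5 * (lv - med) + med + 3.0)
            shifted.append(out.samples[i])

    # within-sample outlier cells displaced > 5 post-displacement SDs
    outlier_cells: list[tuple[str, str]] = []
    if config.outlier_cell_rate > 0:
        cells = rng.random((n, p)) < config.outlier_cell_rate
        for i in range(n):
            cols = np.flatnonzero(cells[i])
            if cols.size == 0:
                continue
            row = out.values[i]
            m0, s0 = row.mean(), row.std()
            mult = 12.0
            for _ in range(12):
                trial = row.copy()
                trial[cols] = m0 + mult * max(s0, 1e-9)
                m1, s1 = trial.mean(), trial.std()
                if np.all(np.abs(trial[cols] - m1) > 5.0 * s1):
                    out.values[i] = trial
                    outlier_cells.extend((out.samples[i], out.features[j]) for j in cols)
                    break
                mult *= 2.0

    # MCAR missingness
    n_missing = 0
    if config.missing_rate_mcar > 0:
        miss = rng.random((n, p)) < config.missing_rate_mcar
        out.mask |= miss
        out.values = np.where(out.mask, np.nan, out.values)
        n_missing = int(miss.sum())

    if manifest is not None:
        manifest.shifted_samples = sorted(set(manifest.shifted_samples) | set(shifted))
        manifest.outlier_cells.extend([list(c) for c in outlier_cells])
        manifest.n_injected_missing += n_missing
    return out
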