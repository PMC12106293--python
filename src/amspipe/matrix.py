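"""Sample x feature abundance matrices with an explicit missingness mask.

The on-disk format is plain TSV: one row per sample, first column ``sample``,
remaining columns are feature ids; missing cells are written as ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_OMIC = ("protein", "metabolite")
VALID_SCALE = ("raw", "log2")


@dataclass
class AbundanceMatrix:
    """Samples x features abundance table.

    ``values`` holds NaN in masked cells; ``mask`` (True = missing) is the
    authoritative record of missingness.
    """

    samples: list[str]
    features: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    omic: str = "protein"
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical shape")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature ids")
        if self.omic not in VALID_OMIC:
            raise ValueError(f"omic must be one of {VALID_OMIC}, got {self.omic!r}")
        if self.scale not in VALID_SCALE:
            raise ValueError(f"scale must be one of {VALID_SCALE}, got {self.scale!r}")
        # keep the two representations congruent
        self.values = np.where(self.mask, np.nan, self.values)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def copy(self) -> "AbundanceMatrix":
        return replace(self, values=self.values.copy(), mask=self.mask.copy(),
                       samples=list(self.samples), features=list(self.features))

    def sample_missing_fraction(self) -> np.ndarray:
        return self.mask.mean(axis=1)

    def feature_missing_fraction(self) -> np.ndarray:
        return self.mask.mean(axis=0)

    def subset_samples(self, keep: np.ndarray) -> "AbundanceMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            features=list(self.features),
            values=self.values[idx].copy(),
            mask=self.mask[idx].copy(),
        )

    def subset_features(self, keep: np.ndarray) -> "AbundanceMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            samples=list(self.samples),
            features=[self.features[i] for i in idx],
            values=self.values[:, idx].copy(),
            mask=self.mask[:, idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.samples, name="sample"),
                            columns=self.features)

    # ------------------------------------------------------------------
    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, omic: str, scale: str = "raw") -> "AbundanceMatrix":
        return cls(
            samples=[str(s) for s in df.index],
            features=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            omic=omic,
            scale=scale,
        )

    @classmethod
    def read_tsv(cls, path, omic: str, scale: str = "raw") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        return cls.from_frame(df, omic=omic, scale=scale)


#: column order of the clinical table; the last two are the outcome columns
CLINICAL_VARIABLES = [
    "Age", "BMI", "Smoke", "SBP", "DBP", "HR", "SpO2", "FVC", "FEV1", "PEF",
    "FEV1_FVC", "WBC", "NE", "LY", "RBC", "HGB", "PLT", "ALT", "AST", "TBIL",
    "UA", "UREA", "CREA", "CKMB", "LDH", "GLU",
]
CLINICAL_OUTCOMES = ["AMS", "AMS_degree"]


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    missing = [c for c in CLINICAL_VARIABLES + CLINICAL_OUTCOMES if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def write_clinical_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="sample")
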