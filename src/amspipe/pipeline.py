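"""End-to-end orchestration: simulate -> QC -> modules -> selection ->
model -> evaluation, with per-stage seeds, artifacts, and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import GeneratorConfig, generate_cohort, inject_missing_and_outliers
from .matrix import AbundanceMatrix, read_clinical_tsv, write_clinical_tsv, CLINICAL_VARIABLES
from .model import (evaluate_model, evaluate_submodels, kernel_shap,
                    train_radial_svm, univariate_clinical_roc)
from .modules import (ams_modules, concatenate_omics, dynamic_tree_cut,
                      merge_close_modules, module_trait_association,
                      spearman_dissimilarity, ward_cluster)
from .preprocess import QCThresholds, run_qc
from .selection import (estimate_error_curve, mi_svm_rfe, screen_clinical,
                        univariate_logistic_filter)

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "amspipe_run"
    # inputs: either paths or simulation
    proteins_tsv: str | None = None
    metabolites_tsv: str | None = None
    clinical_tsv: str | None = None
    simulate: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # QC
    qc: QCThresholds = field(default_factory=QCThresholds)
    pmm_donors: int = 5
    pmm_cycles: int = 10
    loess_span: float = 0.7
    loess_iterations: int = 3
    # modules
    min_module_size: int = 45
    merge_cut_height: float = 0.4
    fdr_family: str = "grid"
    # selection
    k_folds: int = 3
    halve_above: int = 100
    k_max: int = 30
    error_curve_repeats: int = 20
    alpha: float = 0.05
    # model
    svm_C: float = 1.0
    svm_gamma: float | None = None
    calibration_folds: int = 5
    with_shap: bool = True
    with_plots: bool = True

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds: cross-validation requires >= 2 folds")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not self.simulate:
            for path in (self.proteins_tsv, self.metabolites_tsv, self.clinical_tsv):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"input table not found: {path}")
        self.generator.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            gen = dict(d["generator"])
            if "clinical_effects" in gen:
                gen["clinical_effects"] = {k: tuple(v) for k, v in gen["clinical_effects"].items()}
            d["generator"] = GeneratorConfig(**gen)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)

    def config_hash(self) -> str:
        # paths identify a run location, not the analysis: exclude them so
        # identical analyses hash identically wherever they are written
        d = self.to_dict()
        for key in ("output_dir", "proteins_tsv", "metabolites_tsv", "clinical_tsv"):
            d.pop(key, None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunManifest:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed,
                           version=__version__, started=time.time())
    config.to_yaml(out / "config.yaml")

    def checkpoint(stage: str, **dims) -> None:
        manifest.stages.append({"stage": stage, **dims, "t": time.time()})
        log.info("stage %s done: %s", stage, dims)

    try:
        # ------------------------------------------------------------ inputs
        if config.simulate:
            gen = config.generator
            proteins, metabolites, clinical, truth = generate_cohort(gen)
            proteins = inject_missing_and_outliers(proteins, gen, truth)
            metabolites = inject_missing_and_outliers(metabolites, gen, truth)
            proteins.write_tsv(out / "proteins.tsv")
            metabolites.write_tsv(out / "metabolites.tsv")
            write_clinical_tsv(clinical, out / "clinical.tsv")
            truth.to_json(out / "truth.json")
            train_ids, valid_ids = truth.train_samples, truth.valid_samples
        else:
            proteins = AbundanceMatrix.read_tsv(config.proteins_tsv, omic="protein")
            metabolites = AbundanceMatrix.read_tsv(config.metabolites_tsv, omic="metabolite")
            clinical = read_clinical_tsv(config.clinical_tsv)
            train_ids, valid_ids = list(clinical.index), []
        checkpoint("inputs", n_samples=proteins.n_samples,
                   n_proteins=proteins.n_features, n_metabolites=metabolites.n_features)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("inputs", exc) from exc

    # ---------------------------------------------------------------- QC ---
    def qc_cohort(sample_ids, tag, protect_protein=(), protect_metabolite=()):
        pm = proteins.subset_samples(np.isin(proteins.samples, sample_ids))
        mm = metabolites.subset_samples(np.isin(metabolites.samples, sample_ids))
        pq, prep = run_qc(pm, config.qc, seed=stage_seed(config.seed, f"qc-protein-{tag}"),
                          n_donors=config.pmm_donors, n_cycles=config.pmm_cycles,
                          loess_span=config.loess_span,
                          loess_iterations=config.loess_iterations,
                          protect_features=protect_protein)
        mq, mrep = run_qc(mm, config.qc, seed=stage_seed(config.seed, f"qc-metabolite-{tag}"),
                          n_donors=config.pmm_donors, n_cycles=config.pmm_cycles,
                          loess_span=config.loess_span,
                          loess_iterations=config.loess_iterations,
                          protect_features=protect_metabolite)
        with open(out / f"qc_report_{tag}.json", "w") as fh:
            json.dump({"protein": prep.to_dict(), "metabolite": mrep.to_dict()}, fh, indent=1)
        return pq, mq

    try:
        prot_train, met_train = qc_cohort(train_ids, "train")
        checkpoint("qc_train", proteins=prot_train.values.shape, metabolites=met_train.values.shape)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("qc", exc) from exc

    # ------------------------------------------------------------- modules -
    try:
        integrated = concatenate_omics(prot_train, met_train)
        diss = spearman_dissimilarity(integrated)
        dendrogram = ward_cluster(diss)
        assignment = dynamic_tree_cut(dendrogram, diss,
                                      min_cluster_size=config.min_module_size)
        module_set = merge_close_modules(integrated, assignment,
                                         cut_height=config.merge_cut_height)
        traits = clinical.loc[integrated.samples,
                              CLINICAL_VARIABLES + ["AMS_degree"]]
        association = module_trait_association(module_set.eigengenes, traits,
                                               alpha=config.alpha,
                                               fdr_family=config.fdr_family)
        ams_mods = ams_modules(association)
        pd.DataFrame({
            "feature": module_set.features,
            "omic": integrated.omic_of_feature,
            "module": [f"M{a}" if a else "unassigned" for a in module_set.assignment],
        }).to_csv(out / "modules.tsv", sep="\t", index=False)
        module_set.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        association.to_csv(out / "module_trait.tsv", sep="\t", index=False)
        checkpoint("modules", n_modules=len(module_set.module_sizes),
                   n_ams_modules=len(ams_mods))
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("modules", exc) from exc

    # ----------------------------------------------------------- selection -
    try:
        y_train = clinical.loc[integrated.samples, "AMS"].to_numpy(dtype=int)
        screened = screen_clinical(clinical.loc[integrated.samples], alpha=config.alpha)
        screened.to_csv(out / "clinical_screen.tsv", sep="\t", index=False)
        clin_vars = screened.loc[screened["selected"], "variable"].tolist()

        pool = [f for f, a in zip(module_set.features, module_set.assignment)
                if a and f"M{a}" in ams_mods]
        if not pool:
            raise RuntimeError("no AMS-associated module features to select from")
        xpool = integrated.to_frame()[pool]
        ranking = mi_svm_rfe(xpool, y_train, k_folds=config.k_folds,
                             halve_above=config.halve_above,
                             seed=stage_seed(config.seed, "rfe"))
        curve = estimate_error_curve(xpool, y_train, ranking, k_max=config.k_max,
                                     k_folds=config.k_folds,
                                     n_repeats=config.error_curve_repeats,
                                     seed=stage_seed(config.seed, "error-curve"),
                                     C=config.svm_C)
        pd.DataFrame({
            "feature": ranking.elimination_order,
            "final_rank": [ranking.rank[f] for f in ranking.elimination_order],
        }).to_csv(out / "ranking.tsv", sep="\t", index=False)
        pd.DataFrame({"k": curve.k, "mean_error": curve.mean_error,
                      "sd_error": curve.sd_error}).to_csv(
            out / "error_curve.tsv", sep="\t", index=False)

        top_mol = ranking.top(curve.chosen_k)
        types = {f: integrated.omic_of_feature[integrated.features.index(f)]
                 for f in top_mol}
        types.update({v: "clinical" for v in clin_vars})
        candidates = pd.concat(
            [integrated.to_frame()[top_mol],
             clinical.loc[integrated.samples, clin_vars]], axis=1)
        # clinical variables may carry missing entries: mean-fill for the fit
        candidates = candidates.fillna(candidates.mean())
        panel = univariate_logistic_filter(candidates, y_train, alpha=config.alpha,
                                           types=types)
        panel.table.to_csv(out / "panel.tsv", sep="\t", index=False)
        checkpoint("selection", chosen_k=curve.chosen_k,
                   n_candidates=panel.family_size, panel_size=len(panel.selected))
        if not panel.selected:
            raise RuntimeError("empty biomarker panel after the Bonferroni filter")
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("selection", exc) from exc

    # --------------------------------------------------------------- model -
    try:
        feats = panel.selected
        panel_train = candidates[feats]
        model = train_radial_svm(panel_train, y_train, C=config.svm_C,
                                 gamma=config.svm_gamma,
                                 calibration_folds=config.calibration_folds,
                                 seed=stage_seed(config.seed, "svm") % (2 ** 31))
        model.save(out / "model.json")

        train_eval = evaluate_model(model, panel_train, y_train)
        evaluation = {"train": train_eval.to_dict()}
        train_eval.roc_points.to_csv(out / "roc_train.tsv", sep="\t", index=False)
        train_eval.calibration.to_csv(out / "calibration_train.tsv", sep="\t", index=False)

        panel_valid = None
        y_valid = None
        if valid_ids:
            # validation QC runs with the panel features protected from the
            # feature-missingness filter: a deployed model's biomarkers are
            # never dropped, their missing cells are imputed instead
            protect_p = [f.split(":", 1)[1] for f in feats if f.startswith("protein:")]
            protect_m = [f.split(":", 1)[1] for f in feats if f.startswith("metabolite:")]
            prot_valid, met_valid = qc_cohort(valid_ids, "valid",
                                              protect_protein=protect_p,
                                              protect_metabolite=protect_m)
            checkpoint("qc_valid", proteins=prot_valid.values.shape,
                       metabolites=met_valid.values.shape)
            integrated_valid = concatenate_omics(prot_valid, met_valid)
            valid_frame = pd.concat(
                [integrated_valid.to_frame(),
                 clinical.loc[integrated_valid.samples, clin_vars]], axis=1)
            missing_feats = [f for f in feats if f not in valid_frame.columns]
            if missing_feats:
                raise RuntimeError(
                    f"panel features absent after validation QC: {missing_feats}")
            panel_valid = valid_frame[feats].fillna(candidates.mean()[feats])
            y_valid = clinical.loc[integrated_valid.samples, "AMS"].to_numpy(dtype=int)
            valid_eval = evaluate_model(model, panel_valid, y_valid)
            evaluation["valid"] = valid_eval.to_dict()
            valid_eval.roc_points.to_csv(out / "roc_valid.tsv", sep="\t", index=False)

        sub = evaluate_submodels(panel_train, y_train, panel_valid, y_valid,
                                 types=types, C=config.svm_C,
                                 seed=stage_seed(config.seed, "submodels") % (2 ** 31))
        evaluation["submodels"] = {k: {kk: vv for kk, vv in v.items() if kk != "features"}
                                   for k, v in sub["models"].items()}
        for tag, dca in sub["dca"].items():
            dca.to_csv(out / f"dca_{tag}.tsv", sep="\t", index=False)

        clin_roc = univariate_clinical_roc(clinical.loc[integrated.samples, clin_vars],
                                           y_train, variables=clin_vars) if clin_vars else None
        if clin_roc is not None:
            clin_roc.to_csv(out / "clinical_roc.tsv", sep="\t", index=False)

        shap_matrix = shap_base = None
        if config.with_shap:
            shap_matrix, shap_base = kernel_shap(model, panel_train, panel_train)
            pd.DataFrame(shap_matrix, index=integrated.samples,
                         columns=feats).to_csv(out / "shap.tsv", sep="\t")
            evaluation["shap_base"] = shap_base

        evaluation["config_hash"] = config.config_hash()
        with open(out / "evaluation.json", "w") as fh:
            json.dump(evaluation, fh, indent=1)
        checkpoint("model", **{k: v for k, v in evaluation["train"].items()})

        if config.with_plots:
            from .viz import plot_all
            plot_all(out, train_eval, sub["dca"].get("train"), shap_matrix,
                     feats, panel_train)
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("model", exc) from exc

    for path in sorted(out.glob("*")):
        if path.is_file():
            manifest.checksums[path.name] = _sha256(path)
    manifest.finished = time.time()
    manifest.to_json(out / "run_manifest.json")
    return manifest
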