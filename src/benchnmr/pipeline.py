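"""End-to-end pipeline: simulate → quantify → statistics (→ comparison).

A :class:`RunConfig` fixes the seed, acquisition settings and analysis
options; :func:`run_pipeline` executes the stages, writes every artifact
under the output directory and records a manifest (parameters, seed,
SHA-256 of every output) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chemometrics as chem
from . import cohort as coh
from . import compare as cmp_mod
from . import io as bio
from . import quantify as quant
from .spin import AcquisitionConfig

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, artifacts, cause):
        super().__init__(f"stage {stage!r} failed: {cause}; "
                         f"artifacts so far: {[str(a) for a in artifacts]}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    cohort_spec: coh.CohortSpec = None
    bucket_table: quant.BucketTable = None
    n_orthogonal: int = 1
    k_folds: int = 10
    n_permutations: int = 200
    mccv_features: tuple = (10,)
    mccv_splits: int = 100
    method_comparison: coh.MethodComparisonSpec = None
    write_spectra: bool = False

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if self.cohort_spec is None:
            self.cohort_spec = coh.default_cohort_spec()
        if self.bucket_table is None:
            self.bucket_table = quant.default_bucket_table()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list = []
    manifest = {"seed": config.seed,
                "acquisition": {k: getattr(config.acquisition, k) for k in
                                ("field_MHz", "n_scans", "acq_time_s",
                                 "repetition_time_s", "pulse_angle_deg",
                                 "presat_ppm", "presat_power_dB",
                                 "noise_sigma", "linewidth_Hz")},
                "stages": {}, "outputs": {}}

    def record(path: Path):
        artifacts.append(path)
        manifest["outputs"][path.name] = _sha256(path)

    # --- simulate -----------------------------------------------------
    stage = "simulate"
    t0 = time.time()
    try:
        spectra, truth = coh.generate_cohort(
            config.cohort_spec, config.acquisition, seed=config.seed)
        p = out / "cohort_truth.csv"
        truth.to_csv(p, index=False)
        record(p)
        if config.write_spectra:
            for s in spectra:
                p = out / f"spectrum_{s.meta['sample']}.jdx"
                bio.write_spectrum(s, p)
                record(p)
    except Exception as exc:
        raise PipelineError(stage, artifacts, exc) from exc
    manifest["stages"][stage] = round(time.time() - t0, 3)

    # --- quantify -----------------------------------------------------
    stage = "quantify"
    t0 = time.time()
    try:
        from .preprocess import baseline_correct
        spectra = [baseline_correct(s) for s in spectra]
        table = config.bucket_table
        fm = quant.bucket_feature_matrix(spectra, table)
        tsp_areas = [quant.integrate_bucket(s, *quant.TSP_BUCKET)
                     for s in spectra]
        fm_tsp = quant.tsp_normalize_matrix(fm, tsp_areas)
        p = bio.write_feature_matrix(fm_tsp, out / "features_tsp.csv")
        record(p)
    except Exception as exc:
        raise PipelineError(stage, artifacts, exc) from exc
    manifest["stages"][stage] = round(time.time() - t0, 3)

    # --- statistics ---------------------------------------------------
    stage = "stats"
    t0 = time.time()
    try:
        groups = np.asarray(fm_tsp.attrs["groups"])
        filtered, dropped = chem.exclusion_filter(
            fm_tsp, quant.EXCLUSION_REGIONS, table)
        transformed = chem.pareto_scale(chem.glog_transform(filtered))
        uni = chem.ttest_fdr(transformed, groups)
        p = out / "univariate.csv"
        uni.to_csv(p)
        record(p)
        opls = chem.oplsda_fit(transformed, groups,
                               n_orthogonal=config.n_orthogonal)
        q2 = chem.cv_q2(transformed, groups, k_folds=config.k_folds,
                        n_orthogonal=config.n_orthogonal, seed=config.seed)
        perm = chem.permutation_test(
            transformed, groups, B=config.n_permutations,
            n_orthogonal=config.n_orthogonal, k_folds=config.k_folds,
            seed=config.seed)
        mccv = chem.mccv_svm_roc(transformed, groups,
                                 n_features_grid=config.mccv_features,
                                 n_splits=config.mccv_splits,
                                 seed=config.seed)
        rf = chem.random_forest_classify(fm_tsp, groups, seed=config.seed)
        for k, (fpr, tpr) in mccv.roc_points.items():
            p = out / f"roc_{k}features.csv"
            np.savetxt(p, np.column_stack((fpr, tpr)), delimiter=",",
                       header="fpr,tpr", comments="")
            record(p)
        summary = {
            "dropped_buckets": dropped,
            "R2X": opls.R2X, "R2Y": opls.R2Y, "Q2": q2,
            "p_Q2": perm["p_Q2"], "p_R2Y": perm["p_R2Y"],
            "auroc": {str(k): v for k, v in mccv.auroc.items()},
            "rf_oob_accuracy": rf["oob_accuracy"],
        }
        p = out / "stats_summary.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True))
        record(p)
    except Exception as exc:
        raise PipelineError(stage, artifacts, exc) from exc
    manifest["stages"][stage] = round(time.time() - t0, 3)

    # --- method comparison (optional) ---------------------------------
    if config.method_comparison is not None:
        stage = "compare"
        t0 = time.time()
        try:
            tbl = coh.generate_method_comparison(config.method_comparison,
                                                 seed=config.seed)
            anova = cmp_mod.variance_components_anova(tbl)
            hsd = cmp_mod.tukey_hsd(tbl)
            p = out / "method_comparison.csv"
            tbl.to_csv(p, index=False)
            record(p)
            p = out / "tukey_hsd.csv"
            hsd.to_csv(p, index=False)
            record(p)
            comp = {"p_method": anova.p_method,
                    "p_participant": anova.p_participant,
                    "var_participant": anova.var_participant,
                    "var_error": anova.var_error,
                    "method_means": anova.table.mean(axis=0).to_dict()}
            p = out / "compare_summary.json"
            p.write_text(json.dumps(comp, indent=2, sort_keys=True))
            record(p)
        except Exception as exc:
            raise PipelineError(stage, artifacts, exc) from exc
        manifest["stages"][stage] = round(time.time() - t0, 3)

    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
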