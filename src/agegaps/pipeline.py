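"""End-to-end analysis pipeline.

Composes the stages: cohort ingestion or simulation -> eligibility
screening -> per-block preprocessing -> cognitive age gap (19 predictors,
3 PLS components) -> brain age gap (9 predictors, 2 components) ->
lifestyle PCA gated by Horn's parallel analysis -> association regressions
(gap ~ PCs + sex) -> causal mediation of the active-life profile on the
cognitive gap via the brain gap -> APOE e4 t-tests.

Every artifact is stamped with the config snapshot and stage seeds; a rerun
with an identical config reproduces the manifest checksums byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import age_gap as ag
from . import inference as inf
from . import preprocess as pp
from . import profiles as pr
from . import synthetic as syn
from .cohort import CohortTable, load_cohort_csv

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Settings for :func:`run_pipeline`; YAML-serializable."""

    input: str = "synthetic"                 # path to a cohort CSV or "synthetic"
    output_dir: str = "agegaps_run"
    seed: int = 0
    # synthetic cohort
    n: int = 350
    loadings: str = "default"                # "default" | "block"
    inject_missingness: bool = True
    # cognitive model
    cognitive_components: int = 3
    n_folds: int = 10
    max_cognitive_missing: int = 3
    # brain model
    brain_components: int = 2
    ticv_method: str = "residual"
    # bias correction
    bias_variant: str = "offset"
    # lifestyle PCA
    pca_iterations: int = 5000
    pca_criterion: str = "mean"
    residualize_alpha: float = 0.05
    # mediation
    mediation_draws: int = 10000
    treatment_pc: int = 2
    # screening
    screen: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    """In-memory view of a pipeline run (artifacts also land on disk)."""

    config: PipelineConfig
    cohort: CohortTable
    truth: syn.GenerativeTruth | None
    cag: pd.DataFrame
    bag: pd.DataFrame
    cag_metrics: dict
    bag_metrics: dict
    pca: pr.PCAResult
    parallel: pr.ParallelAnalysisResult
    pc_scores: pd.DataFrame
    association_cag: inf.OLSResult
    association_bag: inf.OLSResult
    mediation: inf.MediationResult
    apoe_tests: dict
    stage_log: dict
    manifest: dict
    output_dir: Path


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _screen_stage(table: CohortTable, log: dict) -> pd.Index:
    df = table.data.set_index("subject_id")
    screening = table.screening_columns
    keep = []
    excluded = []
    if not screening or "mmse_raw" not in table.data.columns:
        log["screening"] = {"n_in": len(df), "n_out": len(df), "note": "no screening columns; all retained"}
        return df.index
    for sid, row in df.iterrows():
        z = {t: row[t] for t in screening}
        decision = pp.screen_eligibility(z, row["mmse_raw"], syn.SCREENING_DOMAIN_MAP)
        if decision.include:
            keep.append(sid)
        else:
            excluded.append({"subject": sid, "reasons": decision.reasons})
    log["screening"] = {"n_in": len(df), "n_out": len(keep), "excluded": excluded}
    return pd.Index(keep)


_COGNITIVE_INVERT = ("tmt_ba_ratio", "gonogo_median_rt")


def _cognitive_stage(
    table: CohortTable, eligible: pd.Index, cfg: PipelineConfig,
    report: pp.PreprocessReport, log: dict,
) -> tuple[pd.DataFrame, pd.Series]:
    df = table.data.set_index("subject_id").loc[eligible]
    cols = table.cognitive_columns
    skewed = {v.name for v in syn.COGNITIVE_VARS if v.skewed}
    work = {}
    for col in cols:
        vals = df[col].to_numpy(float)
        if col in _COGNITIVE_INVERT:
            vals = pp.invert_direction(col, vals)
            report.log_transform(col, pp.TransformSpec(col, "invert"))
        if col in skewed:
            spec = pp.fit_transform_spec(col, vals, "boxcox")
            vals = pp.apply_transform(spec, vals)
            report.log_transform(col, spec)
        zspec = pp.fit_zscore(col, vals)
        vals = pp.apply_transform(zspec, vals)
        report.log_transform(col, zspec)
        work[col] = vals
    Z = pd.DataFrame(work, index=df.index)
    filled, included = pp.impute_cognitive_scores(
        Z.to_numpy(), max_missing=cfg.max_cognitive_missing
    )
    n_imputed = int(np.isnan(Z.to_numpy()[included]).sum())
    if n_imputed:
        report.imputation_log.append(
            {"stage": "cognitive", "cells": n_imputed, "method": "subject_mean_z"}
        )
    for sid in Z.index[~included]:
        report.excluded_subjects.append((sid, "more_than_max_missing_cognitive"))
    X = pd.DataFrame(filled, index=Z.index, columns=Z.columns).loc[included]
    age = df.loc[X.index, "age"]
    log["cognitive_preprocess"] = {"n_in": len(Z), "n_out": len(X), "imputed_cells": n_imputed}
    return X, age


def _brain_stage(
    table: CohortTable, eligible: pd.Index, cfg: PipelineConfig,
    report: pp.PreprocessReport, log: dict,
) -> tuple[pd.DataFrame, pd.Series]:
    df = table.data.set_index("subject_id").loc[eligible]
    cols = table.brain_columns
    have = df[cols + ["ticv"]].notna().all(axis=1)
    df = df.loc[have]
    volumes = [c for c in cols if "volume" in c]
    inverted = [c for c in cols if c in ("hippocampus_left_volume", "hippocampus_right_volume", "gm_thickness")]
    boxcoxed = [c for c in cols if c in ("csf_volume", "pvs_bg_count", "pvs_cso_count", "abeta_ratio", "ptau217")]
    logged = [c for c in cols if c == "wmh_volume"]
    work = {}
    for col in cols:
        vals = df[col].to_numpy(float)
        if col in volumes:
            vals = pp.adjust_for_ticv(vals, df["ticv"].to_numpy(float), method=cfg.ticv_method)
            report.log_transform(col, pp.TransformSpec(col, "identity", shift=0.0))
        if col in boxcoxed:
            spec = pp.fit_transform_spec(col, vals, "boxcox")
            vals = pp.apply_transform(spec, vals)
            report.log_transform(col, spec)
        elif col in logged:
            spec = pp.fit_transform_spec(col, vals, "log_shift")
            vals = pp.apply_transform(spec, vals)
            report.log_transform(col, spec)
        if col in inverted:
            vals = pp.invert_direction(col, vals)
            report.log_transform(col, pp.TransformSpec(col, "invert"))
        zspec = pp.fit_zscore(col, vals)
        vals = pp.apply_transform(zspec, vals)
        report.log_transform(col, zspec)
        work[col] = vals
    X = pd.DataFrame(work, index=df.index)
    log["brain_preprocess"] = {"n_in": int(len(eligible)), "n_out": len(X)}
    return X, df["age"]


def _lifestyle_stage(
    table: CohortTable, eligible: pd.Index, cfg: PipelineConfig,
    report: pp.PreprocessReport, log: dict, seed: int,
) -> pd.DataFrame:
    df = table.data.set_index("subject_id").loc[eligible]
    cols = table.lifestyle_columns
    have = df[cols].notna().any(axis=1)
    df = df.loc[have]
    from scipy import stats as sps

    work = {}
    for col in cols:
        vals = df[col].to_numpy(float)
        obs = vals[~np.isnan(vals)]
        normal_p = sps.shapiro(obs if obs.size <= 5000 else obs[:5000]).pvalue
        if normal_p < 0.05:
            spec, vals = pp.select_normalizing_transform(col, vals)
            report.log_transform(col, spec)
        work[col] = vals
    T = pd.DataFrame(work, index=df.index)
    # extreme-outlier fencing, then listwise deletion
    drop: set = set()
    for col in cols:
        idx = pp.flag_extreme_outliers(T[col].to_numpy())
        for i in idx:
            sid = T.index[i]
            report.outlier_subjects.append((sid, col))
            drop.add(sid)
    T = T.drop(index=sorted(drop))
    for sid in sorted(drop):
        report.excluded_subjects.append((sid, "extreme_outlier"))
    age = df.loc[T.index, "age"].to_numpy(float)
    sex = df.loc[T.index, "sex"].to_numpy(float)
    for col in cols:
        vals, used, pvals = pp.residualize_age_sex(
            T[col].to_numpy(), age, sex, alpha=cfg.residualize_alpha
        )
        T[col] = vals
        report.residualized_vars[col] = {"used_residuals": used, "p_values": pvals}
    n_missing = int(T.isna().to_numpy().sum())
    T = pp.iterative_impute(T, seed=seed)
    if n_missing:
        report.imputation_log.append(
            {"stage": "lifestyle", "cells": n_missing, "method": "iterative_chained"}
        )
    Z = (T - T.mean()) / T.std(ddof=1)
    log["lifestyle_preprocess"] = {
        "n_in": int(len(eligible)), "n_with_block": int(have.sum()),
        "n_out": len(Z), "outliers_removed": len(drop), "imputed_cells": n_missing,
    }
    return Z


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    cfg = config or PipelineConfig()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {}
    report = pp.PreprocessReport()

    # stage seeds, all derived from the master seed
    seed_gen = cfg.seed
    seed_missing = cfg.seed + 1
    seed_folds = cfg.seed + 2
    seed_horn = cfg.seed + 3
    seed_mediation = cfg.seed + 4
    seed_impute = cfg.seed + 5

    truth = None
    if cfg.input == "synthetic":
        gen_cfg = syn.GeneratorConfig(
            n=cfg.n,
            factor_loadings=syn.block_loadings() if cfg.loadings == "block" else None,
        )
        cohort, truth = syn.generate_cohort(gen_cfg, seed=seed_gen)
        if cfg.inject_missingness:
            cohort = syn.inject_missingness(cohort, syn.default_missingness_plan(seed_missing))
        log["cohort"] = {"source": "synthetic", "n": cohort.n_subjects, "seed": seed_gen}
    else:
        cohort = load_cohort_csv(cfg.input)
        log["cohort"] = {"source": cfg.input, "n": cohort.n_subjects}

    df_all = cohort.data.set_index("subject_id")
    eligible = _screen_stage(cohort, log) if cfg.screen else df_all.index

    # cognitive age gap
    Xc, age_c = _cognitive_stage(cohort, eligible, cfg, report, log)
    cag_res, cag_info = ag.estimate_age_gap(
        Xc.to_numpy(), age_c.to_numpy(), cfg.cognitive_components,
        n_folds=cfg.n_folds, seed=seed_folds, variant=cfg.bias_variant,
    )
    cag = pd.DataFrame(
        {
            "fold": cag_res.fold,
            "raw_predicted_age": cag_res.raw_predicted_age,
            "corrected_predicted_age": cag_res.corrected_predicted_age,
            "gap": cag_res.gap,
        },
        index=Xc.index,
    )
    m = ag.prediction_metrics(cag_res.corrected_predicted_age, age_c.to_numpy())
    m_raw = ag.prediction_metrics(cag_res.raw_predicted_age, age_c.to_numpy())
    cag_metrics = {
        "n": len(cag), "pearson_r": m.pearson_r, "r_squared": m.r_squared,
        "r_squared_raw": m_raw.r_squared, "mae": m.mae, "mae_sd": m.mae_sd,
        "mse": m.mse, "bias_alpha": cag_res.bias.alpha, "bias_beta": cag_res.bias.beta,
        **cag_info,
    }
    log["cognitive_age_gap"] = {"n": len(cag)}

    # brain age gap
    Xb, age_b = _brain_stage(cohort, eligible, cfg, report, log)
    bag_res, bag_info = ag.estimate_age_gap(
        Xb.to_numpy(), age_b.to_numpy(), cfg.brain_components,
        n_folds=cfg.n_folds, seed=seed_folds + 100, variant=cfg.bias_variant,
    )
    bag = pd.DataFrame(
        {
            "fold": bag_res.fold,
            "raw_predicted_age": bag_res.raw_predicted_age,
            "corrected_predicted_age": bag_res.corrected_predicted_age,
            "gap": bag_res.gap,
        },
        index=Xb.index,
    )
    mb = ag.prediction_metrics(bag_res.corrected_predicted_age, age_b.to_numpy())
    mb_raw = ag.prediction_metrics(bag_res.raw_predicted_age, age_b.to_numpy())
    bag_metrics = {
        "n": len(bag), "pearson_r": mb.pearson_r, "r_squared": mb.r_squared,
        "r_squared_raw": mb_raw.r_squared, "mae": mb.mae, "mae_sd": mb.mae_sd,
        "mse": mb.mse, "bias_alpha": bag_res.bias.alpha, "bias_beta": bag_res.bias.beta,
        **bag_info,
    }
    log["brain_age_gap"] = {"n": len(bag)}

    # lifestyle profiles
    Z = _lifestyle_stage(cohort, eligible, cfg, report, log, seed=seed_impute)
    pca = pr.run_pca(Z)
    parallel = pr.horn_parallel(
        n=Z.shape[0], p=Z.shape[1], observed_eigenvalues=pca.eigenvalues,
        n_iterations=cfg.pca_iterations, criterion=cfg.pca_criterion, seed=seed_horn,
    )
    k = max(parallel.retained, 1)
    pc_cols = [f"PC{j + 1}" for j in range(k)]
    pc_scores = pd.DataFrame(pca.scores[:, :k], index=Z.index, columns=pc_cols)
    log["lifestyle_profiles"] = {
        "n": len(Z), "retained": parallel.retained,
        "cum_pct_var_retained": pr.cumulative_variance(pca, k),
    }

    # association regressions on subjects surviving all upstream filters
    sex_all = df_all["sex"]
    assoc_results = {}
    for name, gaps in (("cag", cag), ("bag", bag)):
        common = gaps.index.intersection(pc_scores.index)
        design = pc_scores.loc[common].copy()
        design["sex_male"] = sex_all.loc[common].to_numpy()
        assoc_results[name] = inf.fit_ols(gaps.loc[common, "gap"].to_numpy(), design)
        log[f"association_{name}"] = {"n": len(common)}

    # mediation: treatment PC -> CAG via BAG, sex as covariate
    treat_col = f"PC{cfg.treatment_pc}"
    if treat_col not in pc_scores.columns:
        treat_col = pc_scores.columns[min(cfg.treatment_pc, k) - 1]
    med_idx = cag.index.intersection(bag.index).intersection(pc_scores.index)
    mediation = inf.mediate_quasibayes(
        treatment=pc_scores.loc[med_idx, treat_col].to_numpy(),
        mediator=bag.loc[med_idx, "gap"].to_numpy(),
        outcome=cag.loc[med_idx, "gap"].to_numpy(),
        covariates=sex_all.loc[med_idx].to_numpy(),
        n_draws=cfg.mediation_draws,
        seed=seed_mediation,
    )
    log["mediation"] = {"n": len(med_idx), "treatment": treat_col}

    # APOE t-tests (carriers > non-carriers)
    apoe = df_all["apoe4_carrier"]
    apoe_tests = {}
    for name, gaps in (("cag", cag), ("bag", bag)):
        a = gaps.loc[apoe.reindex(gaps.index) == 1, "gap"].to_numpy()
        b = gaps.loc[apoe.reindex(gaps.index) == 0, "gap"].to_numpy()
        t = inf.ttest_onesided_pooled(a, b)
        apoe_tests[name] = {
            "t": t.t, "df": t.df, "p_one_sided": t.p_one_sided,
            "cohens_d": t.cohens_d,
            "mean_carrier": t.group_means[0], "mean_noncarrier": t.group_means[1],
        }
    log["apoe_tests"] = {k_: v["p_one_sided"] for k_, v in apoe_tests.items()}

    manifest = _write_artifacts(
        out_dir, cfg, cohort, truth, cag, bag, cag_metrics, bag_metrics,
        pca, parallel, pc_scores, assoc_results, mediation, apoe_tests,
        report, log,
    )
    return PipelineResult(
        config=cfg, cohort=cohort, truth=truth, cag=cag, bag=bag,
        cag_metrics=cag_metrics, bag_metrics=bag_metrics, pca=pca,
        parallel=parallel, pc_scores=pc_scores,
        association_cag=assoc_results["cag"], association_bag=assoc_results["bag"],
        mediation=mediation, apoe_tests=apoe_tests, stage_log=log,
        manifest=manifest, output_dir=out_dir,
    )


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def _json_dump(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def _write_artifacts(
    out_dir, cfg, cohort, truth, cag, bag, cag_metrics, bag_metrics,
    pca, parallel, pc_scores, assoc, mediation, apoe_tests, report, log,
) -> dict:
    sidecar = {"truth": truth.to_jsonable()} if truth is not None else None
    cohort.write_csv(out_dir / "cohort.csv", sidecar=sidecar)
    cag.to_csv(out_dir / "cag_results.csv", index_label="subject_id")
    bag.to_csv(out_dir / "bag_results.csv", index_label="subject_id")
    _json_dump(out_dir / "cag_metrics.json", cag_metrics)
    _json_dump(out_dir / "bag_metrics.json", bag_metrics)
    loadings = pd.DataFrame(
        pca.loadings, index=pca.variable_names,
        columns=[f"PC{j + 1}" for j in range(pca.loadings.shape[1])],
    )
    loadings.to_csv(out_dir / "lifestyle_loadings.csv", index_label="variable")
    pc_scores.to_csv(out_dir / "lifestyle_scores.csv", index_label="subject_id")
    _json_dump(
        out_dir / "parallel_analysis.json",
        {
            "observed_eigenvalues": pca.eigenvalues,
            "reference_mean": parallel.reference_mean,
            "n_iterations": parallel.n_iterations,
            "criterion": parallel.criterion,
            "retained": parallel.retained,
            "seed": parallel.seed,
            "pct_var": pca.pct_var,
        },
    )
    for name, res in assoc.items():
        res.to_frame().to_csv(out_dir / f"association_{name}.csv", index_label="term")
    _json_dump(
        out_dir / "mediation.json",
        {
            "acme": mediation.acme, "ade": mediation.ade,
            "total_effect": mediation.total_effect,
            "prop_mediated": mediation.prop_mediated,
            "ci": mediation.ci, "mc_p": mediation.mc_p,
            "n_draws": mediation.n_draws, "seed": mediation.seed,
        },
    )
    _json_dump(out_dir / "apoe_ttests.json", apoe_tests)
    _json_dump(out_dir / "preprocess_report.json", report.to_jsonable())
    _json_dump(out_dir / "stage_log.json", log)

    files = sorted(
        p.name for p in out_dir.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": cfg.to_dict(),
        "files": {
            name: hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
            for name in files
        },
        "stage_counts": {
            stage: {k: v for k, v in info.items() if isinstance(v, (int, float, str))}
            for stage, info in log.items()
        },
    }
    _json_dump(out_dir / "manifest.json", manifest)
    return manifest
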