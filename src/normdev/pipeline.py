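"""End-to-end orchestration: simulate/load -> QC -> match -> fit norms ->
score -> atypicality -> inference, with provenance logging.

Every stage writes plain files under the output directory so a run can be
inspected or resumed stage by stage; the resolved configuration and a
manifest (input hashes, seed, stage timings, package versions) make the
run reproducible from its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atypicality import (flag_outliers, global_w_ratios, outlier_age_summary,
                          prevalence_chisq, region_prevalence)
from .inference import (case_control_map, remove_region_outliers_and_refit,
                        spearman_phenotype_map, wscore_one_sample)
from .io_core import (CohortTable, MorphMatrix, load_cohort, load_morphometry,
                      match_groups_by_age, qc_exclude_euler)
from .normative import build_normative_model, compute_wscores
from .synthetic_data import SimConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Config for a full pipeline run; either simulate or give input paths."""

    output_dir: str = "normdev_run"
    simulate: bool = True
    sim: dict = field(default_factory=dict)      # SimConfig overrides
    cohort_path: str | None = None
    morph_path: str | None = None
    phenotype_path: str | None = None
    sex: str | None = "male"
    outlier_threshold: float = 2.0
    expected_prevalence: float = 0.05
    fdr_q: float = 0.05
    min_bin_count: int = 5
    span: float | str = "auto"
    span_bounds: tuple[float, float] = (0.05, 1.0)
    sse_mode: str = "cv"
    euler_top_fraction: float = 0.10
    match_groups: bool = True
    covariates: tuple[str, ...] = ("age", "sex", "motion_fd", "euler")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["span_bounds"] = list(self.span_bounds)
        data["covariates"] = list(self.covariates)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    Any stage failure aborts with the stage name; outputs written by
    earlier stages are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "inputs": {}}
    t_all = time.time()
    stage = "init"

    def record(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}

    try:
        # ---- inputs ---------------------------------------------------------
        stage = "inputs"
        t0 = time.time()
        phenotypes = None
        if config.simulate:
            sim = SimConfig(**{"seed": config.seed, **config.sim})
            cohort, morph, truth = generate_cohort(sim)
            cohort.to_csv(out / "cohort.csv")
            morph.to_csv(out / "morphometry.csv")
            (out / "sim_config.yaml").write_text(
                yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in asdict(sim).items()}), encoding="utf-8")
            record(stage, t0, n_subjects=len(cohort), n_regions=len(morph.regions))
        else:
            if not config.cohort_path or not config.morph_path:
                raise FileNotFoundError("cohort_path and morph_path required when "
                                        "simulate is false")
            for p in (config.cohort_path, config.morph_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")
            cohort, cohort_rej = load_cohort(config.cohort_path)
            morph, morph_rej = load_morphometry(config.morph_path)
            cohort_rej.to_csv(out / "cohort_rejections.csv")
            morph_rej.to_csv(out / "morph_rejections.csv")
            manifest["inputs"]["cohort_sha256"] = _sha256(Path(config.cohort_path))
            manifest["inputs"]["morph_sha256"] = _sha256(Path(config.morph_path))
            if config.phenotype_path:
                phenotypes = pd.read_csv(config.phenotype_path, index_col="subject_id")
            record(stage, t0, n_subjects=len(cohort),
                   n_rejected=len(cohort_rej) + len(morph_rej))

        # ---- stratum + QC ---------------------------------------------------
        stage = "qc"
        t0 = time.time()
        if config.sex is not None:
            cohort = cohort.filter_sex(config.sex)
        qc = qc_exclude_euler(cohort, config.euler_top_fraction)
        cohort = qc.kept
        pd.Series(qc.excluded_ids, name="subject_id").to_csv(
            out / "euler_excluded.csv", index=False)
        record(stage, t0, n_excluded=len(qc.excluded_ids),
               euler_threshold=qc.threshold)

        # ---- matching -------------------------------------------------------
        stage = "match"
        t0 = time.time()
        cases = cohort.filter_group("case")
        controls = cohort.filter_group("control")
        if config.match_groups and len(cases) and len(controls):
            match = match_groups_by_age(cases, controls)
            cases, controls = match.cases, match.controls
            match.pairs.to_csv(out / "matched_pairs.csv", index=False)
            record(stage, t0, n_pairs=len(match.pairs),
                   mean_abs_age_diff=match.mean_abs_age_diff)
        else:
            record(stage, t0, skipped=True)
        analysis_ids = pd.Index(list(cases.subject_ids) + list(controls.subject_ids))
        combined = cohort.subset(cohort.df["subject_id"].isin(analysis_ids))

        # ---- norms + scoring ------------------------------------------------
        stage = "fit_norms"
        t0 = time.time()
        model = build_normative_model(controls, morph.subset(controls.subject_ids),
                                      span=config.span,
                                      min_bin_count=config.min_bin_count,
                                      span_bounds=config.span_bounds,
                                      sse_mode=config.sse_mode, sex=None,
                                      seed=config.seed)
        model.save(out / "normative_model")
        record(stage, t0, n_regions=len(model.regions),
               n_dropped_bins=int((~model.bins["retained"]).sum()))

        stage = "score"
        t0 = time.time()
        scored = morph.subset(analysis_ids.intersection(morph.subject_ids))
        w = compute_wscores(scored, model, combined)
        w_out = w.copy()
        w_out.insert(0, "subject_id", w_out.index)
        w_out.to_csv(out / "wscores.csv", index=False)
        record(stage, t0, n_missing_cells=int(w.isna().sum().sum()))

        # ---- atypicality ----------------------------------------------------
        stage = "atypicality"
        t0 = time.time()
        case_w = w.loc[w.index.intersection(cases.subject_ids)]
        flags = flag_outliers(case_w, config.outlier_threshold)
        prev = region_prevalence(flags)
        x2, pval = prevalence_chisq(prev.median, config.expected_prevalence,
                                    len(flags.columns), yates=True)
        x2_raw, pval_raw = prevalence_chisq(prev.median, config.expected_prevalence,
                                            len(flags.columns), yates=False)
        ratios = global_w_ratios(case_w, config.outlier_threshold)
        ages = outlier_age_summary(flags, combined)
        prev.per_region.rename("prevalence").rename_axis("region").to_csv(
            out / "region_prevalence.csv")
        ratios.to_csv(out / "global_ratios.csv")
        summary = dict(median_prevalence=prev.median,
                       chisq_yates=dict(x2=x2, p=pval),
                       chisq=dict(x2=x2_raw, p=pval_raw),
                       n_global_thin=int(ratios["global_thin"].sum()),
                       outlier_age_range=list(ages.range))
        (out / "atypicality_summary.json").write_text(json.dumps(summary, indent=2),
                                                      encoding="utf-8")
        record(stage, t0, median_prevalence=prev.median)

        # ---- inference ------------------------------------------------------
        stage = "inference"
        t0 = time.time()
        morph_df = scored.df
        removal = remove_region_outliers_and_refit(
            morph_df, w, combined, threshold=config.outlier_threshold,
            covariates=config.covariates, fdr_q=config.fdr_q)
        one_sample = wscore_one_sample(w, combined, fdr_q=config.fdr_q)
        tables = [removal.before, removal.after, one_sample]
        if phenotypes is not None:
            tables.append(spearman_phenotype_map(case_w, phenotypes,
                                                 fdr_q=config.fdr_q))
        results = pd.concat(tables, ignore_index=True)
        results.to_csv(out / "region_stats.csv", index=False)
        inf_summary = dict(
            n_significant_case_control=removal.n_significant_before,
            n_significant_after_outlier_removal=removal.n_significant_after,
            fold_change=removal.ratio if np.isfinite(removal.ratio) else None,
            n_significant_wscore=int(one_sample["significant"].sum()))
        (out / "inference_summary.json").write_text(json.dumps(inf_summary, indent=2),
                                                    encoding="utf-8")
        record(stage, t0, **inf_summary)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                           encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    logger.info("pipeline complete in %.1fs -> %s", manifest["total_seconds"], out)
    return manifest
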