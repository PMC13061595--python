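"""End-to-end orchestration: project -> associate -> link -> score -> validate.

Each stage writes its artifact as CSV under the output directory, and a
JSON manifest records the seed, per-stage row counts and warnings so that
identical config + seed yields an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .association import association_scan, significant_associations
from .cohort import CohortSpec, simulate_study
from .errors import EpifitError
from .io import (PipelineConfig, read_covariates, read_cvd_weights, read_fitness,
                 read_hazard, read_methylation, read_name_mapping, read_reference_means,
                 read_weights, write_matrix, write_series, write_table)
from .linkage import assess_direction_consistency, link_fitness_disease, link_granularities
from .projection import harmonize_names, project_episcores, standardize_columns
from .risk import (categorize_fitness, compute_direct_risk, compute_indirect_risk,
                   compute_risk_scores, rank_high_risk_patients)
from .validation import compute_cvd_score, validate_against_benchmark

logger = logging.getLogger(__name__)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_simulation(spec: CohortSpec, out_dir: Path | str) -> dict:
    """Generate a synthetic study and write every input table the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(spec)
    write_matrix(study.methylation, out / "methylation.tsv")
    cov = study.covariates.reset_index()
    write_table(cov, out / "covariates.csv")
    write_table(study.fitness.reset_index(), out / "fitness.csv")
    write_table(study.weights, out / "weights.tsv")
    write_series(study.ref_means, out / "ref_means.tsv")
    write_table(study.hazard, out / "hazard.csv")
    write_table(study.cvd_weights, out / "cvd_weights.csv")
    write_matrix(study.latent, out / "latent_episcores.csv")
    manifest = {
        "stage": "simulate",
        "seed": spec.seed,
        "n_samples": len(study.covariates),
        "n_proteins": spec.n_proteins,
        "n_cpgs": study.methylation.shape[0],
        "n_diseases": study.hazard["disease"].nunique(),
        "n_cvd_weights": len(study.cvd_weights),
        "n_clipped_betas": study.n_clipped,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write all artifacts plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except EpifitError as exc:
                raise EpifitError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- load -----------------------------------------------------------
    meth = _stage("read")(lambda: read_methylation(config.methylation, config.orientation))
    covariates = read_covariates(config.covariates)
    fitness = read_fitness(config.fitness)
    weights = read_weights(config.weights)
    ref_means = read_reference_means(config.ref_means)
    hazard = read_hazard(config.hazard)
    cvd_weights = read_cvd_weights(config.cvd_weights)
    sample_ids = covariates.index
    fitness = fitness.loc[sample_ids]
    manifest["stages"]["read"] = {"n_samples": len(sample_ids), "n_cpgs": meth.shape[0]}

    # --- project --------------------------------------------------------
    def _project():
        episcores, report = project_episcores(meth, weights, ref_means)
        if config.name_mapping is not None:
            mapping = read_name_mapping(config.name_mapping)
            resolved, log = harmonize_names(list(episcores.columns), mapping,
                                            strict=config.strict_names)
            episcores.columns = resolved
            write_table(log, out / "name_mapping_log.csv")
        return episcores.loc[sample_ids], report
    episcores, imputation = _stage("project")(_project)
    write_matrix(episcores, out / "episcores.csv")
    write_table(imputation, out / "imputation_report.csv")
    manifest["stages"]["project"] = {
        "n_proteins": episcores.shape[1],
        "n_imputed_values": int(imputation["n_imputed"].sum()),
    }

    # --- associate ------------------------------------------------------
    scan = _stage("associate")(
        lambda: association_scan(episcores, fitness, covariates, config.significance))
    write_table(scan, out / "associations.csv")
    sig = significant_associations(scan, config.significance)
    manifest["stages"]["associate"] = {"n_tests": len(scan), "n_significant": len(sig)}

    # --- link -----------------------------------------------------------
    def _link():
        links = link_fitness_disease(sig, hazard)
        links, n_consistent = assess_direction_consistency(links, config.expected_directions)
        return links, n_consistent
    links, n_consistent = _stage("link")(_link)
    write_table(links, out / "links.csv")
    manifest["stages"]["link"] = {**link_granularities(links), "n_consistent": n_consistent}

    # --- score ----------------------------------------------------------
    def _score():
        episcores_std = standardize_columns(episcores)
        fitness_std = standardize_columns(fitness)
        direct = compute_direct_risk(episcores_std, hazard)
        indirect = compute_indirect_risk(fitness_std, sig, hazard)
        risk = compute_risk_scores(direct, indirect, config.thresholds)
        categories = categorize_fitness(fitness, covariates, config.thresholds)
        top = rank_high_risk_patients(risk, config.top_k)
        return risk, categories, top
    risk, categories, top = _stage("score")(_score)
    write_matrix(risk.raw, out / "risk_raw.csv")
    write_matrix(risk.z, out / "risk_z.csv")
    write_matrix(risk.high_risk, out / "risk_flags.csv")
    write_matrix(categories, out / "fitness_categories.csv")
    write_table(top, out / "top_patients.csv")
    manifest["stages"]["score"] = {
        "n_diseases": risk.raw.shape[1],
        "n_flagged_any": int(risk.high_risk.any(axis=1).sum()),
        "pct_flagged_any": round(100.0 * risk.high_risk.any(axis=1).mean(), 2),
    }

    # --- validate -------------------------------------------------------
    def _validate():
        episcores_std = standardize_columns(episcores)
        cvd = compute_cvd_score(episcores_std, cvd_weights, strict=False)
        return cvd, validate_against_benchmark(risk, cvd, config.correlation_method)
    cvd_scores, report = _stage("validate")(_validate)
    write_series(cvd_scores, out / "cvd_scores.csv")
    write_table(report, out / "cvd_validation.csv")
    manifest["stages"]["validate"] = {
        "n_diseases": len(report),
        "n_significant_fdr_001": int((report["q_value"] < 0.001).sum()),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
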