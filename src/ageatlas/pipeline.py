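"""End-to-end orchestration: simulate → predict → lesion → annotate → enrich.

Each stage writes its outputs under the run directory; a final
``manifest.json`` records the configuration, package version, seeds and a
SHA-256 checksum per output file, so two runs with the same (config, seed)
produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .brainage import make_folds, run_cv, test_sex_difference, test_tiv_association
from .config import PipelineConfig
from .enrichment import read_gmt, run_ora, write_gmt
from .io import (read_cohort, read_expression, write_atlas, write_cohort,
                 write_expression)
from .lesion import network_age_correlations, run_lesion_analysis
from .synthetic_data import (CohortTruth, ExpressionTruth, generate_atlas,
                             generate_cohort, generate_expression,
                             generate_gene_sets)
from .transcriptomics import (map_samples_to_clusters, normalize_expression,
                              permutation_gene_association, select_genes)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run every stage in order and return the summary dictionary.

    Raises a stage-named error on any failure; partial outputs of completed
    stages remain on disk.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    summary: dict[str, Any] = {"config": config.to_dict(),
                               "version": __version__}

    # --- simulate or load -------------------------------------------------
    stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate:
            atlas = generate_atlas(config.n_rois, config.n_networks, seed=seed)
            truth = CohortTruth.default(
                config.n_networks, important_network=config.important_network,
                seed=seed)
            cohort = generate_cohort(atlas, config.n_subjects,
                                     config.age_range, truth)
            signal = [f"gene-{i:05d}" for i in range(1, config.n_signal_genes + 1)]
            etruth = ExpressionTruth(signal, config.important_network,
                                     config.effect_size, seed=seed)
            expression = generate_expression(
                atlas, config.n_donors, config.samples_per_donor,
                config.n_genes, etruth)
            gene_sets = generate_gene_sets(
                expression.gene_ids, config.n_terms, config.term_size_range,
                planted_term_from=signal, seed=seed)
            write_atlas(atlas, out / "atlas")
            write_cohort(cohort, out / "cohort")
            write_expression(expression, out / "expression")
            write_gmt(gene_sets, out / "gene_sets.gmt")
            summary["truth"] = {
                "important_network": config.important_network,
                "signal_genes": signal,
            }
        else:
            from .io import read_atlas

            cohort = read_cohort(config.cohort_dir)
            expression = read_expression(config.expression_dir)
            gene_sets = read_gmt(config.gmt_path)
            atlas = read_atlas(config.atlas_dir)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- predict ----------------------------------------------------------
    try:
        folds = make_folds(cohort.n_subjects, config.k, config.repeats, seed)
        full = run_cv(cohort.gmv, cohort.age, k=config.k,
                      repeats=config.repeats, seed=seed, kernel=config.kernel,
                      folds=folds)
        sex_test = test_sex_difference(full.brain_pad, cohort.sex, cohort.age)
        tiv_test = test_tiv_association(full.brain_pad, cohort.tiv)
        pd.DataFrame({
            "subject_id": cohort.subject_ids,
            "age": cohort.age,
            "predicted_age": full.mean_prediction,
            "brain_pad": full.brain_pad,
        }).to_csv(out / "predictions.tsv", sep="\t", index=False)
        summary["predict"] = {
            "mae": full.mae, "r": full.r,
            "r_per_repeat_mean": float(full.r_per_repeat.mean()),
            "mae_per_repeat_mean": float(full.mae_per_repeat.mean()),
            "kernel": config.kernel, "k": config.k, "repeats": config.repeats,
            "sex_test": asdict(sex_test), "tiv_test": asdict(tiv_test),
        }
        (out / "prediction_metrics.json").write_text(
            json.dumps(summary["predict"], indent=2))
    except Exception as exc:
        raise RuntimeError(f"stage 'predict' failed: {exc}") from exc

    # --- lesion -----------------------------------------------------------
    try:
        lesions = run_lesion_analysis(cohort, atlas, k=config.k,
                                      repeats=config.repeats, seed=seed,
                                      kernel=config.kernel, full_result=full)
        net_corrs = network_age_correlations(cohort, atlas)
        pd.DataFrame([asdict(r) for r in lesions]).to_csv(
            out / "lesion_report.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(c) for c in net_corrs]).to_csv(
            out / "network_age_correlations.tsv", sep="\t", index=False)
        top = lesions[0]
        summary["lesion"] = {
            "top_network": top.network_id, "top_z": top.z, "top_p": top.p,
            "ranking": [r.network_id for r in lesions],
            "all_network_age_r_negative": bool(all(c.r < 0 for c in net_corrs)),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'lesion' failed: {exc}") from exc

    # --- annotate ---------------------------------------------------------
    try:
        cluster = summary["lesion"]["top_network"]
        assignments = map_samples_to_clusters(
            expression.sample_world_coords, atlas.mask, atlas.network_grid(),
            atlas.affine, radius_mm=config.sphere_radius_mm,
            overlap_threshold=config.overlap_threshold)
        norm = normalize_expression(expression)
        assocs = permutation_gene_association(
            norm, assignments, cluster, expression.gene_ids,
            n_perm=config.n_perm, seed=seed, fwe=config.fwe_method,
            alpha=config.alpha_fwe)
        genes = select_genes(assocs, config.alpha_fwe)
        pd.DataFrame([asdict(a) for a in assocs]).to_csv(
            out / "gene_associations.tsv", sep="\t", index=False)
        (out / "significant_genes.txt").write_text("\n".join(genes) + "\n")
        summary["annotate"] = {
            "cluster": cluster,
            "n_admitted": sum(a.cluster is not None for a in assignments),
            "n_in_cluster": sum(a.cluster == cluster for a in assignments),
            "n_significant_genes": len(genes),
            "fwe_method": config.fwe_method,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc

    # --- enrich -----------------------------------------------------------
    try:
        if genes:
            results = run_ora(genes, gene_sets, expression.gene_ids,
                              alpha=config.alpha_fdr)
            pd.DataFrame([
                {**{k: v for k, v in asdict(r).items() if k != "overlap_genes"},
                 "overlap_genes": ";".join(r.overlap_genes)}
                for r in results
            ]).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["enrich"] = {
                "top_term": results[0].term,
                "top_term_q": results[0].q_value,
                "n_significant_terms": sum(r.significant for r in results),
            }
        else:
            summary["enrich"] = {"top_term": None, "top_term_q": None,
                                 "n_significant_terms": 0}
    except Exception as exc:
        raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    # --- manifest ---------------------------------------------------------
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {"version": __version__, "seed": seed,
                "config": config.to_dict(), "summary_keys": sorted(summary),
                "checksums": checksums}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
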