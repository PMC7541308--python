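"""End-to-end orchestration: QC -> differential -> network -> mapping -> enrichment.

Half-missing proteins (quantified in exactly one batch) never enter QC,
ANOVA or network construction — they lack cross-batch covariance — and are
annotated into the finished network afterwards by eigenprotein correlation
over their cognate samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import io as pio
from .config import RunConfig
from .differential import anova_tukey, classify_volcano
from .network import map_missing
from .network.estimator import CoexpressionModules
from .qc import sample_connectivity
from .simulate import SimConfig, simulate
from .types import AbundanceMatrix, GeneSetCollection

logger = logging.getLogger("protnet")


def _hash_array(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def run_pipeline(
    matrix: AbundanceMatrix,
    config: RunConfig,
    markers: GeneSetCollection | None = None,
    terms: GeneSetCollection | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis; returns a manifest with results attached.

    The manifest records the config echo, input hashes, per-stage timings,
    warnings, and (when ``out_dir`` is given) the written file set.  The
    ``results`` entry carries the in-memory tables.
    """
    manifest: dict = {
        "config": config.to_dict(),
        "input_hash": _hash_array(matrix.values[matrix.mask], matrix.mask),
        "timings": {},
        "warnings": [],
        "counts": {"proteins_in": matrix.n_proteins, "samples_in": matrix.n_samples},
    }
    results: dict = {}
    t0 = time.perf_counter()

    work = matrix
    if config.median_center:
        vals = work.values.copy()
        med = np.nanmedian(vals, axis=0, keepdims=True)
        vals = vals - (med - np.nanmedian(med))
        work = AbundanceMatrix(list(work.proteins), list(work.samples), vals, work.mask.copy())

    complete_idx = work.complete_index()
    half_idx = work.half_missing_index()
    complete = work.subset(complete_idx)
    manifest["counts"]["complete_proteins"] = int(complete_idx.size)
    manifest["counts"]["half_missing_proteins"] = int(half_idx.size)
    logger.info(
        "pipeline: %d complete, %d half-missing, %d other proteins",
        complete_idx.size, half_idx.size,
        work.n_proteins - complete_idx.size - half_idx.size,
    )

    # --- QC ------------------------------------------------------------------
    qc_report = sample_connectivity(complete, threshold_sd=config.outlier_sd)
    results["qc_report"] = qc_report
    manifest["timings"]["qc"] = time.perf_counter() - t0
    if qc_report["n_outliers"]:
        manifest["warnings"].append(f"{qc_report['n_outliers']} connectivity outlier(s) flagged")
    if config.drop_outliers and qc_report["n_outliers"]:
        keep = [
            i for i, s in enumerate(complete.samples)
            if not qc_report["samples"][s.sample_id]["outlier"]
        ]
        complete = AbundanceMatrix(
            list(complete.proteins),
            [complete.samples[i] for i in keep],
            complete.values[:, keep],
            complete.mask[:, keep],
        )
        logger.info("dropped %d outlier sample(s)", qc_report["n_outliers"])

    # --- differential abundance ----------------------------------------------
    t = time.perf_counter()
    de_wide = anova_tukey(complete)
    de_long = classify_volcano(
        de_wide,
        p_threshold=config.p_threshold,
        log2fc_threshold=config.log2fc_threshold,
        volcano_p=config.volcano_p,
    )
    results["de_wide"] = de_wide
    results["de_results"] = de_long
    manifest["timings"]["differential"] = time.perf_counter() - t

    # --- network -------------------------------------------------------------
    t = time.perf_counter()
    model = CoexpressionModules(
        beta=config.beta,
        network_type=config.network_type,
        corr_method=config.corr_method,
        tom_denom=config.tom_denom,
        deep_split=config.deep_split,
        min_module_size=config.min_module_size,
        merge_cut_height=config.merge_cut_height,
        pam_stage=config.pam_stage,
        reassign_threshold=config.reassign_threshold,
    ).fit(complete.values)
    bundle = model.module_set(complete.proteins, complete.sample_ids)
    results["model"] = model
    manifest["timings"]["network"] = time.perf_counter() - t
    manifest["counts"]["modules"] = len(model.module_ids_)
    manifest["counts"]["unassigned"] = int((model.labels_ == 0).sum())

    assignments = pd.DataFrame(
        {
            "protein": complete.proteins,
            "module": [f"M{m}" if m else "M0" for m in model.labels_],
            "kme_own": [
                model.kme_[i, model.module_ids_.index(m)] if m else np.nan
                for i, m in enumerate(model.labels_)
            ],
            "assigned_via": "complete",
            "n": complete.n_samples,
        }
    )

    # --- map half-missing proteins into the network --------------------------
    if half_idx.size and model.module_ids_:
        t = time.perf_counter()
        half = work.subset(half_idx)
        mapped = map_missing(
            half.values, half.mask, model.eigenproteins_, model.module_ids_
        )
        mapped.insert(0, "protein", half.proteins)
        mapped["module"] = [f"M{m}" if m else "M0" for m in mapped["module"]]
        mapped = mapped.rename(columns={"kme": "kme_own"})
        mapped["assigned_via"] = "half_missing"
        assignments = pd.concat(
            [assignments, mapped[["protein", "module", "kme_own", "assigned_via", "n"]]],
            ignore_index=True,
        )
        results["map_missing"] = mapped
        manifest["timings"]["map_missing"] = time.perf_counter() - t
    results["module_assignments"] = assignments

    # --- module-trait correlation --------------------------------------------
    t = time.perf_counter()
    trait_table = enr.module_trait_strata(
        model.eigenproteins_, model.module_ids_, complete.samples
    )
    results["module_trait"] = trait_table
    manifest["timings"]["module_trait"] = time.perf_counter() - t

    # --- enrichment ------------------------------------------------------------
    t = time.perf_counter()
    universe = list(complete.proteins)
    module_members = {
        f"M{m}": [p for p, lab in zip(complete.proteins, model.labels_) if lab == m]
        for m in model.module_ids_
    }
    tables = []
    if markers is not None and len(markers):
        cell = enr.fisher_celltype(module_members, markers, universe)
        cell.insert(0, "kind", "cell_type")
        tables.append(cell)
    if terms is not None and len(terms):
        onto = enr.zscore_enrichment(module_members, terms, universe)
        onto.insert(0, "kind", "ontology")
        tables.append(onto)
        if len(onto):
            sig = onto[onto["bh_p"] <= config.p_threshold]
            if len(sig) >= 2:
                results["term_clusters"] = enr.kappa_cluster(sig, terms, universe)
    results["enrichment"] = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    manifest["timings"]["enrichment"] = time.perf_counter() - t

    # --- reports ---------------------------------------------------------------
    report_bundle = {
        "de_results": de_long,
        "module_assignments": assignments,
        "eigenproteins": bundle["eigenproteins"].reset_index(names="module"),
        "kme": bundle["kme"].reset_index(names="protein"),
        "module_trait": trait_table,
        "enrichment": results["enrichment"],
        "qc_report": qc_report,
        "run_config": config.to_dict(),
    }
    if out_dir is not None:
        manifest["files"] = pio.write_reports(report_bundle, out_dir)
        if "term_clusters" in results:
            results["term_clusters"].to_csv(
                Path(out_dir) / "term_clusters.tsv", sep="\t", index=False
            )
        Path(out_dir, "run_manifest.json").write_text(
            json.dumps({k: v for k, v in manifest.items() if k != "results"},
                       indent=2, sort_keys=True, default=str) + "\n"
        )
    manifest["results"] = results
    manifest["total_time"] = time.perf_counter() - t0
    return manifest


def simulate_to_dir(sim_config: SimConfig, out_dir: str | Path) -> dict:
    """Emit the standard simulated inputs (TSV/CSV/GMT) plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth, markers = simulate(sim_config)
    pio.write_abundance(matrix, out / "abundance.tsv", out / "samples.csv")
    pio.write_gmt(markers, out / "markers.gmt")
    truth_dict = {
        "true_module": truth.true_module,
        "effect_genotype": truth.effect_genotype,
        "effect_age": truth.effect_age,
        "marker_members": truth.marker_members,
        "half_missing": truth.half_missing,
    }
    (out / "truth.json").write_text(json.dumps(truth_dict, indent=2, sort_keys=True) + "\n")
    return {
        "files": ["abundance.tsv", "samples.csv", "markers.gmt", "truth.json"],
        "n_proteins": matrix.n_proteins,
        "n_samples": matrix.n_samples,
    }
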