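"""End-to-end pipeline orchestration.

Reads a cohort directory (the formats the core readers consume), runs the
analysis stages in dependency order and writes one TSV per result plus a
JSON manifest with the config snapshot, input checksums and per-stage
output paths.  Stage order: differential -> promoter/TAD -> correlation ->
TAD statistics -> bivalent chromatin -> enhancers -> TF filtering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    PipelineConfig,
    read_contacts,
    read_gene_annotation,
    read_intervals,
    read_methylation,
    read_sample_sheet,
    read_signal_matrix,
    read_tads,
)
from .correlation import (
    bootstrap_overlap_p,
    gene_mark_correlations,
    select_high_rho,
)
from .differential import (
    active_genes,
    count_hypermethylated,
    differential_to_frame,
    log2_fold_changes,
    rank_test_differential,
    read_differential_table,
)
from .enhancers import (
    Enhancer,
    call_enhancers,
    compare_expression_by_class,
    contact_classes,
    correlation_permutation_null,
    differential_region_signal,
    enhancer_methylation,
    link_correlations,
    link_genes_to_enhancers,
    links_to_frame,
)
from .promoters import assign_genes_to_tads, make_promoters
from .tadstats import (
    bivalent_genes,
    enrichment_to_frame,
    permutation_homogeneity,
    tad_enrichment,
    tad_fc_correlation,
    tad_overlap_hypergeom,
)
from .tf import (
    filter_by_envelope,
    random_target_envelope,
    read_candidate_pairs,
    tf_records_to_frame,
    tf_target_correlations,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "differential",
    "tad_assignment",
    "correlation",
    "tad_stats",
    "bivalent",
    "enhancers",
    "tf",
)

MARK_KINDS = ("H3K4me3", "H3K27ac", "H3K27me3", "ATAC", "DNase")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_run_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg


def run_pipeline(
    config_path,
    outdir=None,
    seed: int | None = None,
    stages=None,
) -> dict:
    """Execute the pipeline described by a YAML run config.

    Returns the run manifest (also written to ``manifest.json``).
    """
    t0 = time.time()
    raw = load_run_config(config_path)
    cohort_dir = Path(raw.get("cohort_dir", "."))
    if not cohort_dir.is_absolute():
        cohort_dir = Path(config_path).parent / cohort_dir
    params = PipelineConfig(**raw.get("params", {}))
    if seed is not None:
        params.rng_seed = seed
    rng = np.random.default_rng(params.rng_seed)
    comparisons = [tuple(c) for c in raw.get("comparisons", [["PA", "GBM"]])]
    stages = tuple(stages or raw.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(outdir or raw.get("outdir", "gliotad_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- pre-flight: every referenced input must exist -------------------
    inputs = {
        "genes": cohort_dir / "genes.tsv",
        "tads": cohort_dir / "tads.bed",
        "samples": cohort_dir / "samples.tsv",
        "expression": cohort_dir / "expression.tsv",
        "enhancers": cohort_dir / "enhancers.bed",
        "enhancer_acetylation": cohort_dir / "enhancer_acetylation.tsv",
        "contacts": cohort_dir / "contacts.bedpe",
        "methylation": cohort_dir / "methylation.tsv",
    }
    for kind in MARK_KINDS:
        inputs[f"mark_{kind}"] = cohort_dir / f"mark_{kind}.tsv"
    missing = [str(p) for p in inputs.values() if not p.exists()]
    if missing:
        raise FileNotFoundError("missing inputs:\n" + "\n".join(missing))

    genes = read_gene_annotation(inputs["genes"])
    tads = read_tads(inputs["tads"])
    samples = read_sample_sheet(inputs["samples"])
    expression = read_signal_matrix(inputs["expression"], "expression")
    marks = {k: read_signal_matrix(inputs[f"mark_{k}"], k) for k in MARK_KINDS}
    enh_items = read_intervals(inputs["enhancers"])
    acet = pd.read_csv(inputs["enhancer_acetylation"], sep="\t", index_col=0)
    contacts = read_contacts(inputs["contacts"])
    methylation = read_methylation(inputs["methylation"])

    outputs: dict[str, str] = {}
    counts: dict[str, int | float] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs[name] = str(path)

    promoters = make_promoters(genes, params.promoter_flank)
    assignment = assign_genes_to_tads(genes, tads)
    group1, group2 = comparisons[0]

    deg_sets: dict[tuple[str, str], set[str]] = {}
    dem_sets: dict[tuple[str, str], dict[str, set[str]]] = {}

    # ---- differential ----------------------------------------------------
    if "differential" in stages:
        external = raw.get("external_differential")
        for cmp in comparisons:
            g1, g2 = cmp
            tag = f"{g1}_vs_{g2}"
            if external:
                recs = read_differential_table(
                    Path(config_path).parent / external
                )
            else:
                recs = rank_test_differential(
                    expression, samples, g1, g2,
                    correction="bh", alpha=params.deg_alpha,
                )
            emit(f"deg_{tag}", differential_to_frame(recs))
            deg_sets[cmp] = {r.feature_id for r in recs if r.significant}
            counts[f"n_deg_{tag}"] = len(deg_sets[cmp])
            dem_sets[cmp] = {}
            for kind, mat in marks.items():
                mrecs = rank_test_differential(
                    mat, samples, g1, g2, correction="bh",
                    alpha=params.deg_alpha,
                )
                emit(f"dem_{kind}_{tag}", differential_to_frame(mrecs))
                dem_sets[cmp][kind] = {
                    r.feature_id for r in mrecs if r.significant
                }
            hyper = count_hypermethylated(
                methylation, dict(promoters.items()), samples.sample_ids,
                params.beta_hyper,
            )
            hrecs = rank_test_differential(
                hyper, samples, g1, g2, correction="bh",
                alpha=params.deg_alpha, normalize=False,
            )
            emit(f"dem_methyl_{tag}", differential_to_frame(hrecs))
            dem_sets[cmp]["methyl"] = {
                r.feature_id for r in hrecs if r.significant
            }

    # ---- TAD assignment --------------------------------------------------
    if "tad_assignment" in stages:
        emit("gene_tad_assignment", assignment.to_frame())
        emit(
            "promoters",
            pd.DataFrame(
                [(g, iv.chrom, iv.start, iv.end)
                 for g, iv in promoters.items()],
                columns=["gene_id", "chrom", "start", "end"],
            ),
        )

    # ---- correlation -----------------------------------------------------
    if "correlation" in stages and deg_sets:
        degs = deg_sets[comparisons[0]]
        active = active_genes(expression, params.active_min_mean)
        rows = []
        for kind in ("H3K4me3", "H3K27ac"):
            recs = gene_mark_correlations(expression, marks[kind], degs)
            for r in recs:
                rows.append((r.gene_id, r.mark_kind, r.rho, r.n))
            high = select_high_rho(recs, params.rho_select)
            counts[f"n_high_rho_{kind}"] = len(high)
        emit("deg_mark_correlations",
             pd.DataFrame(rows, columns=["gene_id", "mark_kind", "rho", "n"]))
        dem_ac = dem_sets[comparisons[0]].get("H3K27ac", set())
        if degs and len(active - degs) >= len(degs) and dem_ac:
            counts["bootstrap_overlap_p"] = bootstrap_overlap_p(
                degs, dem_ac, active, expression,
                reps=params.n_boot, rng=rng,
            )

    # ---- TAD statistics --------------------------------------------------
    if "tad_stats" in stages:
        homog_rows = []
        fc_expr = log2_fold_changes(expression, samples, group1, group2)
        for kind, mat in list(marks.items()) + [("expression", expression)]:
            fc = (fc_expr if kind == "expression"
                  else log2_fold_changes(mat, samples, group1, group2))
            res = permutation_homogeneity(
                dict(fc), assignment, n_perm=params.n_perm, rng=rng
            )
            homog_rows.append(
                (kind, res.statistic, res.p_asymptotic, res.p_permutation,
                 res.n_perm, res.n_groups, res.n_values)
            )
        emit(
            "tad_homogeneity",
            pd.DataFrame(
                homog_rows,
                columns=["assay", "kw_statistic", "p_asymptotic",
                         "p_permutation", "n_perm", "n_tads", "n_genes"],
            ),
        )
        if deg_sets:
            degs = deg_sets[comparisons[0]]
            enr = tad_enrichment(assignment, degs,
                                 params.min_tad_genes, params.enrich_alpha)
            emit("tad_enrichment_deg", enrichment_to_frame(enr))
            counts["n_enriched_tads"] = sum(r.enriched for r in enr)
            deg_fc = {g: fc_expr[g] for g in degs if g in fc_expr}
            mark_fc = dict(
                log2_fold_changes(marks["H3K27ac"], samples, group1, group2)
            )
            try:
                tad_means, rho = tad_fc_correlation(deg_fc, mark_fc, assignment)
                emit("tad_fc_means", tad_means)
                counts["tad_fc_spearman_rho"] = rho
            except ValueError as exc:
                logger.warning("tad_fc_correlation skipped: %s", exc)

    # ---- bivalent chromatin ----------------------------------------------
    if "bivalent" in stages and deg_sets:
        degs = deg_sets[comparisons[0]]
        gbm = samples.samples_in("GBM") if "GBM" in samples.group_order else None
        bival = bivalent_genes(
            marks["H3K4me3"], marks["H3K27me3"], degs,
            top_n=params.bivalent_top_n, group_samples=gbm,
        )
        emit("bivalent_degs",
             pd.DataFrame({"gene_id": sorted(bival)}))
        counts["n_bivalent_degs"] = len(bival)
        enr = tad_enrichment(assignment, degs,
                             params.min_tad_genes, params.enrich_alpha)
        universe = {r.tad_id for r in enr if r.p_raw is not None}
        enriched = {r.tad_id for r in enr if r.enriched}
        marked = {
            assignment.gene_to_tad[g] for g in bival
            if assignment.gene_to_tad.get(g) in universe
        }
        if universe:
            counts["bivalent_tad_overlap_p"] = tad_overlap_hypergeom(
                enriched, marked, universe
            )

    # ---- enhancers ---------------------------------------------------------
    if "enhancers" in stages:
        peaks = [
            (iv, acet.loc[eid].to_dict())
            for eid, iv in enh_items if eid in acet.index
        ]
        called = call_enhancers(peaks, promoters)
        # keep original ids where intervals match so acetylation rows align
        iv_to_id = {(iv.chrom, iv.start, iv.end): eid for eid, iv in enh_items}
        called = [
            Enhancer(iv_to_id[(e.interval.chrom, e.interval.start,
                               e.interval.end)], e.interval, e.acetylation)
            for e in called
        ]
        counts["n_enhancers"] = len(called)
        links = link_genes_to_enhancers(
            promoters, called, contacts, params.contact_max_dist
        )
        emit("gene_enhancer_links", links_to_frame(links, promoters, called))
        classes = contact_classes(links)
        emit(
            "contact_classes",
            pd.DataFrame(
                [(g, t, c) for g, (t, c) in sorted(classes.items())],
                columns=["gene_id", "total_contacts", "contact_class"],
            ),
        )
        try:
            p_cls, medians = compare_expression_by_class(expression, classes)
            counts["expr_by_contact_class_p"] = p_cls
            counts["median_expr_multi"] = medians["multi"]
            counts["median_expr_few"] = medians["few"]
        except ValueError as exc:
            logger.warning("contact-class comparison skipped: %s", exc)
        acet_called = acet.loc[[e.enhancer_id for e in called]]
        diff_enh, p_enh = differential_region_signal(
            acet_called, samples, group1, group2, params.enhancer_diff_alpha
        )
        emit(
            "differential_enhancers",
            pd.DataFrame(
                {"enhancer_id": p_enh.index, "p_raw": p_enh.values,
                 "significant": [e in diff_enh for e in p_enh.index]}
            ),
        )
        counts["n_differential_enhancers"] = len(diff_enh)
        meth_rows = {
            e.enhancer_id: enhancer_methylation(
                methylation, e, samples.sample_ids
            )
            for e in called
        }
        meth_df = pd.DataFrame(meth_rows).T
        meth_df.index.name = "enhancer_id"
        meth_path = outdir / "enhancer_methylation.tsv"
        meth_df.to_csv(meth_path, sep="\t", float_format="%.10g")
        outputs["enhancer_methylation"] = str(meth_path)
        covered = meth_df.dropna()
        if not covered.empty:
            diff_met, p_met = differential_region_signal(
                covered, samples, group1, group2, params.enhancer_diff_alpha
            )
            counts["n_differential_methylation_enhancers"] = len(diff_met)
        if deg_sets:
            degs = deg_sets[comparisons[0]]
            deg_links = [
                l for l in links
                if l.gene_id in degs and l.enhancer_id in diff_enh
            ]
            counts["n_deg_diff_enhancer_links"] = len(deg_links)
            if deg_links:
                corr = link_correlations(
                    deg_links, expression, acet_called, samples, per_group=True
                )
                emit("link_correlations", corr)
                if len(deg_links) >= 2:
                    e_vec = np.array([
                        expression.values.loc[l.gene_id].to_numpy()
                        for l in deg_links
                    ])
                    a_vec = np.array([
                        acet_called.loc[l.enhancer_id].to_numpy()
                        for l in deg_links
                    ])
                    null_means = correlation_permutation_null(
                        e_vec, a_vec, reps=params.n_corr_perm, rng=rng
                    )
                    counts["link_corr_null_median"] = float(
                        np.nanmedian(null_means)
                    )
                    counts["link_corr_observed_median"] = float(
                        np.nanmedian(corr["rho_all"])
                    )

    # ---- TF filtering ------------------------------------------------------
    if "tf" in stages:
        cand_path = raw.get("tf_candidates")
        if cand_path:
            cand_file = Path(config_path).parent / cand_path
            candidates = read_candidate_pairs(cand_file)
            active = active_genes(expression, params.active_min_mean)
            records, medians = tf_target_correlations(candidates, expression)
            envelopes = {}
            targets_of: dict[str, set[str]] = {}
            for tf_id, tgt in candidates:
                targets_of.setdefault(tf_id, set()).add(tgt)
            for tf_id in sorted({r.tf_gene_id for r in records}):
                excl = targets_of.get(tf_id, set())
                # small cohorts cannot support 100 draws without replacement
                avail = len(active - excl - {tf_id})
                envelopes[tf_id] = random_target_envelope(
                    tf_id, active, expression,
                    n_draws=min(100, avail), rng=rng, exclude=excl,
                )
            records = filter_by_envelope(records, envelopes)
            emit("tf_targets", tf_records_to_frame(records, envelopes))
            counts["n_tf_pairs_retained"] = sum(
                r.passes_envelope for r in records
            )
        else:
            logger.info("tf stage: no tf_candidates input; skipped")

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(params),
        "comparisons": [list(c) for c in comparisons],
        "stages": list(stages),
        "rng_seed": params.rng_seed,
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)}
                   for k, p in inputs.items()},
        "outputs": {k: {"path": v, "sha256": _sha256(Path(v))}
                    for k, v in outputs.items()},
        "summary": {k: (float(v) if isinstance(v, (int, float)) else v)
                    for k, v in counts.items()},
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
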