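"""Enhancer calling, Hi-C-based gene-enhancer linking and enhancer statistics.

Enhancers are H3K27ac peaks lying entirely outside promoter windows.  A
contact pair links a gene to an enhancer when one anchor overlaps the
gene's promoter and the other overlaps the enhancer (either orientation)
and the promoter-enhancer midpoint distance is within the cap (2 Mb by
default).  Downstream: contact-multiplicity classes (1-5 vs >= 6),
differential acetylation/methylation of enhancer regions (raw Wilcoxon
p < 0.01, no correction — the stated procedure), per-link expression-vs-
acetylation correlations, and the random-pairing permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ContactPair,
    GenomicInterval,
    IntervalIndex,
    MethylationRecord,
    SampleSheet,
    SignalMatrix,
)
from .correlation import spearman
from .differential import mann_whitney_p
from .promoters import PromoterSet

logger = logging.getLogger(__name__)

__all__ = [
    "Enhancer",
    "GeneEnhancerLink",
    "call_enhancers",
    "link_genes_to_enhancers",
    "contact_classes",
    "compare_expression_by_class",
    "differential_region_signal",
    "enhancer_methylation",
    "link_correlations",
    "correlation_permutation_null",
    "links_to_frame",
]


@dataclass(frozen=True)
class Enhancer:
    enhancer_id: str
    interval: GenomicInterval
    acetylation: Mapping[str, float]  # per-sample H3K27ac signal


@dataclass(frozen=True)
class GeneEnhancerLink:
    gene_id: str
    enhancer_id: str
    n_contacts: int


def call_enhancers(
    peaks: Sequence[tuple[GenomicInterval, Mapping[str, float]]],
    promoters: PromoterSet,
) -> list[Enhancer]:
    """H3K27ac peaks with no overlap (>= 1 bp) of any promoter window."""
    index = promoters.index()
    out: list[Enhancer] = []
    n = 0
    for iv, signal in peaks:
        if index.query(iv):
            continue
        n += 1
        out.append(Enhancer(f"enh{n:05d}", iv, dict(signal)))
    logger.info("call_enhancers: %d of %d peaks kept as enhancers",
                len(out), len(peaks))
    return out


def link_genes_to_enhancers(
    promoters: PromoterSet,
    enhancers: Sequence[Enhancer],
    contacts: Sequence[ContactPair],
    max_dist: int = 2_000_000,
) -> list[GeneEnhancerLink]:
    """Assign enhancers to genes through chromatin contact pairs.

    A contact supports (gene, enhancer) iff one anchor overlaps the gene's
    promoter and the other overlaps the enhancer, in either orientation,
    and |promoter midpoint - enhancer midpoint| <= max_dist.  Multiple
    supporting contacts are collapsed into one link with their count.
    """
    prom_index = promoters.index()
    enh_index = IntervalIndex((e.enhancer_id, e.interval) for e in enhancers)
    enh_by_id = {e.enhancer_id: e for e in enhancers}
    counts: dict[tuple[str, str], int] = {}
    for pair in contacts:
        if pair.anchor_a.chrom != pair.anchor_b.chrom:
            continue
        for prom_anchor, enh_anchor in (
            (pair.anchor_a, pair.anchor_b),
            (pair.anchor_b, pair.anchor_a),
        ):
            genes = prom_index.query(prom_anchor)
            if not genes:
                continue
            enhs = enh_index.query(enh_anchor)
            if not enhs:
                continue
            for g in genes:
                pm = promoters[g].midpoint
                for eid in enhs:
                    em = enh_by_id[eid].interval.midpoint
                    if abs(pm - em) <= max_dist:
                        counts[(g, eid)] = counts.get((g, eid), 0) + 1
    return [
        GeneEnhancerLink(g, eid, n) for (g, eid), n in sorted(counts.items())
    ]


def contact_classes(
    links: Sequence[GeneEnhancerLink],
) -> dict[str, tuple[int, str]]:
    """Per gene: total supporting contacts and the multiplicity class.

    Classes follow the published bounds: none (0), few (1-5), multi (>= 6).
    """
    totals: dict[str, int] = {}
    for link in links:
        totals[link.gene_id] = totals.get(link.gene_id, 0) + link.n_contacts
    out: dict[str, tuple[int, str]] = {}
    for gene, total in totals.items():
        cls = "multi" if total >= 6 else ("few" if total >= 1 else "none")
        out[gene] = (total, cls)
    return out


def compare_expression_by_class(
    expression: SignalMatrix,
    classes: Mapping[str, tuple[int, str]],
    sample_ids: Sequence[str] | None = None,
) -> tuple[float, dict[str, float]]:
    """Two-sided Mann-Whitney comparing per-gene mean expression between
    the multi (>= 6 contacts) and few (1-5) classes."""
    vals = expression.values
    if sample_ids is not None:
        vals = vals[list(sample_ids)]
    means = vals.mean(axis=1)
    multi = [means[g] for g, (_, c) in classes.items()
             if c == "multi" and g in means.index]
    few = [means[g] for g, (_, c) in classes.items()
           if c == "few" and g in means.index]
    if not multi or not few:
        raise ValueError(
            f"both classes must be non-empty (multi={len(multi)}, few={len(few)})"
        )
    p = mann_whitney_p(np.asarray(multi), np.asarray(few))
    medians = {"multi": float(np.median(multi)), "few": float(np.median(few))}
    return p, medians


def differential_region_signal(
    signal: pd.DataFrame,
    samples: SampleSheet,
    group1: str,
    group2: str,
    alpha: float = 0.01,
) -> tuple[set[str], pd.Series]:
    """Per-region two-sided Mann-Whitney between two grade groups.

    Significance is raw p strictly below alpha, with no multiplicity
    correction — the stated cut-off for differential enhancer activity and
    enhancer CpG methylation.
    """
    g1 = samples.samples_in(group1)
    g2 = samples.samples_in(group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = signal[g1].to_numpy(dtype=float)
    b = signal[g2].to_numpy(dtype=float)
    p = pd.Series(
        [mann_whitney_p(a[i], b[i]) for i in range(signal.shape[0])],
        index=signal.index,
        name="p_raw",
    )
    significant = set(p.index[p < alpha])
    return significant, p


def enhancer_methylation(
    records: Sequence[MethylationRecord],
    enhancer: Enhancer,
    sample_ids: Sequence[str],
) -> pd.Series:
    """Per-sample mean beta over CpGs inside the enhancer interval.

    Samples with no covered CpG get NaN and are excluded from downstream
    correlations (logged).
    """
    sums: dict[str, float] = {s: 0.0 for s in sample_ids}
    counts: dict[str, int] = {s: 0 for s in sample_ids}
    iv = enhancer.interval
    for rec in records:
        if rec.sample_id in sums and iv.contains(rec.chrom, rec.pos):
            sums[rec.sample_id] += rec.beta
            counts[rec.sample_id] += 1
    out = pd.Series(
        {
            s: (sums[s] / counts[s]) if counts[s] else np.nan
            for s in sample_ids
        },
        name=enhancer.enhancer_id,
    )
    n_missing = int(out.isna().sum())
    if n_missing:
        logger.info(
            "enhancer_methylation: %s has %d samples with no covered CpG",
            enhancer.enhancer_id, n_missing,
        )
    return out


def link_correlations(
    links: Sequence[GeneEnhancerLink],
    expression: SignalMatrix,
    enhancer_acetylation: pd.DataFrame,
    samples: SampleSheet,
    per_group: bool = False,
) -> pd.DataFrame:
    """Spearman rho between gene expression and enhancer acetylation per
    link, overall and (optionally) within each grade group.

    Strata with fewer than 3 samples are skipped; undefined correlations
    (constant vectors) come back as NaN.
    """
    strata: dict[str, list[str]] = {"all": list(samples.sample_ids)}
    if per_group:
        for grp in samples.group_order:
            strata[grp] = samples.samples_in(grp)
    rows = []
    for link in links:
        if (link.gene_id not in expression.values.index
                or link.enhancer_id not in enhancer_acetylation.index):
            continue
        row: dict[str, object] = {
            "gene_id": link.gene_id,
            "enhancer_id": link.enhancer_id,
            "n_contacts": link.n_contacts,
        }
        for name, sids in strata.items():
            sids = [s for s in sids
                    if s in expression.values.columns
                    and s in enhancer_acetylation.columns]
            if len(sids) < 3:
                row[f"rho_{name}"] = np.nan
                continue
            e = expression.values.loc[link.gene_id, sids].to_numpy()
            a = enhancer_acetylation.loc[link.enhancer_id, sids].to_numpy()
            mask = ~(np.isnan(e) | np.isnan(a))
            if mask.sum() < 3:
                row[f"rho_{name}"] = np.nan
            else:
                row[f"rho_{name}"] = spearman(e[mask], a[mask])
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_permutation_null(
    link_expression: np.ndarray,
    link_acetylation: np.ndarray,
    reps: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of the mean link correlation under random pairing.

    Each replicate randomly re-pairs expression vectors with acetylation
    vectors (rows of the two arrays) and records the mean Spearman rho over
    pairs; the summary statistic of interest is the median of these means.
    """
    if link_expression.shape != link_acetylation.shape:
        raise ValueError("expression and acetylation arrays must align")
    n_links = link_expression.shape[0]
    if n_links < 2:
        raise ValueError("need >= 2 links for a permutation null")
    rng = np.random.default_rng() if rng is None else rng
    means = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(n_links)
        rhos = []
        for i in range(n_links):
            rho = spearman(link_expression[i], link_acetylation[perm[i]])
            if not np.isnan(rho):
                rhos.append(rho)
        means[r] = np.mean(rhos) if rhos else np.nan
    return means


def links_to_frame(
    links: Sequence[GeneEnhancerLink],
    promoters: PromoterSet,
    enhancers: Sequence[Enhancer],
) -> pd.DataFrame:
    enh_by_id = {e.enhancer_id: e for e in enhancers}
    rows = []
    for link in links:
        prom = promoters[link.gene_id]
        enh = enh_by_id[link.enhancer_id]
        rows.append(
            {
                "gene_id": link.gene_id,
                "enhancer_id": link.enhancer_id,
                "chrom": prom.chrom,
                "n_contacts": link.n_contacts,
                "distance": abs(prom.midpoint - enh.interval.midpoint),
            }
        )
    return pd.DataFrame(rows)
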