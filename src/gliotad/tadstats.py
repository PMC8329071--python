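"""TAD-level statistics.

Four procedures over the gene -> TAD partition:

* binomial enrichment of flagged (differential) genes per TAD, with a
  globally estimated background probability and BH correction;
* Kruskal-Wallis homogeneity of log2 fold changes grouped by TAD, with a
  permutation null that shuffles values among TADs while keeping each
  TAD's gene count;
* the per-TAD mean fold-change correlation between expression and a mark;
* bivalent-chromatin gene detection (top-N by H3K4me3 and by H3K27me3)
  and the hypergeometric test for the overlap of the enriched-TAD set with
  the bivalent-gene-containing TAD set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SignalMatrix
from .differential import bh_adjust
from .promoters import TadAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "TadEnrichmentRecord",
    "HomogeneityResult",
    "tad_enrichment",
    "kw_homogeneity",
    "permutation_homogeneity",
    "tad_fc_correlation",
    "bivalent_genes",
    "tad_overlap_hypergeom",
    "enrichment_to_frame",
]


@dataclass(frozen=True)
class TadEnrichmentRecord:
    tad_id: str
    n_genes: int
    n_flagged: int
    background_prob: float
    p_raw: float | None   # None for TADs excluded by the min-gene filter
    p_adj: float | None
    enriched: bool


@dataclass(frozen=True)
class HomogeneityResult:
    statistic: float
    p_asymptotic: float
    p_permutation: float | None = None
    n_perm: int = 0
    n_groups: int = 0
    n_values: int = 0


def tad_enrichment(
    assignment: TadAssignment,
    flagged: set[str],
    min_tad_genes: int = 3,
    alpha: float = 0.05,
) -> list[TadEnrichmentRecord]:
    """Binomial upper-tail enrichment of flagged genes per TAD.

    background_prob is the share of flagged genes among all TAD-assigned
    genes, estimated once globally; for each TAD with >= min_tad_genes
    genes, p_raw = P(X >= n_flagged) with X ~ Binomial(n_genes, background).
    TADs below the gene-count filter carry no p-value and are never
    enriched.  BH correction runs over the tested TADs only.
    """
    assigned = assignment.assigned_genes
    if not assigned:
        raise ValueError("no genes assigned to any TAD")
    assigned_set = set(assigned)
    outside = flagged - assigned_set
    if outside:
        logger.info("tad_enrichment: %d flagged genes outside TADs dropped",
                    len(outside))
    flagged_in = flagged & assigned_set
    background = len(flagged_in) / len(assigned_set)

    tested: list[tuple[str, int, int]] = []
    small: list[tuple[str, int, int]] = []
    for tad_id, genes in assignment.tad_to_genes.items():
        n = len(genes)
        k = sum(1 for g in genes if g in flagged_in)
        if n >= min_tad_genes:
            tested.append((tad_id, n, k))
        else:
            small.append((tad_id, n, k))

    records: list[TadEnrichmentRecord] = []
    if tested:
        # P(X >= k) = sf(k - 1); k = 0 gives exactly 1
        p_raw = np.array(
            [stats.binom.sf(k - 1, n, background) for _, n, k in tested]
        )
        p_raw = np.minimum(p_raw, 1.0)
        p_adj = bh_adjust(p_raw)
        for (tad_id, n, k), pr, pa in zip(tested, p_raw, p_adj):
            records.append(
                TadEnrichmentRecord(
                    tad_id, n, k, background, float(pr), float(pa),
                    bool(pa < alpha),
                )
            )
    for tad_id, n, k in small:
        records.append(
            TadEnrichmentRecord(tad_id, n, k, background, None, None, False)
        )
    return records


def enrichment_to_frame(records: Sequence[TadEnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tad_id": [r.tad_id for r in records],
            "n_genes": [r.n_genes for r in records],
            "n_flagged": [r.n_flagged for r in records],
            "background_prob": [r.background_prob for r in records],
            "p_raw": [np.nan if r.p_raw is None else r.p_raw for r in records],
            "p_adj": [np.nan if r.p_adj is None else r.p_adj for r in records],
            "enriched": [r.enriched for r in records],
        }
    )


def _group_layout(
    fold_changes: Mapping[str, float], assignment: TadAssignment
) -> tuple[np.ndarray, list[int]]:
    """Fold-change values laid out contiguously by TAD, plus group sizes.
    TADs with no fold-change-bearing genes are dropped."""
    values: list[float] = []
    sizes: list[int] = []
    for tad_id, genes in assignment.tad_to_genes.items():
        vals = [fold_changes[g] for g in genes if g in fold_changes]
        if vals:
            values.extend(vals)
            sizes.append(len(vals))
    return np.asarray(values, dtype=float), sizes


def _kw_statistic(ranks: np.ndarray, sizes: np.ndarray,
                  tie_correction: float) -> float:
    """Tie-corrected Kruskal-Wallis H for ranks laid out contiguously."""
    n = ranks.size
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    group_sums = np.add.reduceat(ranks, starts)
    h = 12.0 / (n * (n + 1)) * np.sum(group_sums**2 / sizes) - 3 * (n + 1)
    return float(h / tie_correction)


def kw_homogeneity(
    fold_changes: Mapping[str, float], assignment: TadAssignment
) -> HomogeneityResult:
    """Kruskal-Wallis test of log2 fold changes with TADs as groupings.

    Small asymptotic p means fold changes are more homogeneous within TADs
    than between them.  All-equal values carry no rank information and are
    reported as H = 0, p = 1.
    """
    values, sizes = _group_layout(fold_changes, assignment)
    if len(sizes) < 2:
        raise ValueError("need >= 2 TADs with fold-change-bearing genes")
    if np.all(values == values[0]):
        return HomogeneityResult(0.0, 1.0, None, 0, len(sizes), values.size)
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    n = values.size
    tie_c = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    h = _kw_statistic(ranks, np.asarray(sizes), tie_c)
    p = float(stats.chi2.sf(h, df=len(sizes) - 1))
    return HomogeneityResult(h, p, None, 0, len(sizes), n)


def permutation_homogeneity(
    fold_changes: Mapping[str, float],
    assignment: TadAssignment,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> HomogeneityResult:
    """Permutation version: shuffle fold changes among TADs keeping each
    TAD's gene count; p = (1 + #{H_perm >= H_obs}) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        logger.warning("permutation_homogeneity: n_perm=%d is low", n_perm)
    rng = np.random.default_rng() if rng is None else rng
    base = kw_homogeneity(fold_changes, assignment)
    values, sizes = _group_layout(fold_changes, assignment)
    sizes_arr = np.asarray(sizes)
    if np.all(values == values[0]):
        return HomogeneityResult(0.0, 1.0, 1.0, n_perm, base.n_groups,
                                 base.n_values)
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    n = values.size
    tie_c = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if _kw_statistic(perm, sizes_arr, tie_c) >= base.statistic - 1e-12:
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)
    return HomogeneityResult(base.statistic, base.p_asymptotic, p_perm,
                             n_perm, base.n_groups, base.n_values)


def tad_fc_correlation(
    expr_fc: Mapping[str, float],
    mark_fc: Mapping[str, float],
    assignment: TadAssignment,
) -> tuple[pd.DataFrame, float]:
    """Per-TAD mean expression and mark fold changes, and the Spearman rho
    between the two means across TADs.

    TADs missing either quantity are excluded; fewer than 3 usable TADs is
    an error (rank correlation needs at least 3 points).
    """
    rows = []
    for tad_id, genes in assignment.tad_to_genes.items():
        e = [expr_fc[g] for g in genes if g in expr_fc]
        m = [mark_fc[g] for g in genes if g in mark_fc]
        if e and m:
            rows.append((tad_id, float(np.mean(e)), float(np.mean(m))))
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} TADs with both means defined")
    df = pd.DataFrame(rows, columns=["tad_id", "mean_expr_fc", "mean_mark_fc"])
    rho = float(
        stats.spearmanr(df["mean_expr_fc"], df["mean_mark_fc"]).statistic
    )
    return df, rho


def _top_n_by_signal(summary: pd.Series, top_n: int) -> set[str]:
    # descending by signal, ties at the boundary broken lexicographically
    # by gene id so runs are reproducible
    order = sorted(summary.index, key=lambda g: (-summary[g], g))
    return set(order[:top_n])


def bivalent_genes(
    h3k4me3: SignalMatrix,
    h3k27me3: SignalMatrix,
    degs: set[str],
    top_n: int = 1000,
    group_samples: Sequence[str] | None = None,
    summary: str = "mean",
) -> set[str]:
    """DEGs whose promoters rank in the top-N by both H3K4me3 and H3K27me3.

    Signals are summarised per gene as the mean (or median) across the
    analysed group's samples.  If top_n exceeds the gene count the top set
    is all genes (logged).
    """
    common = sorted(set(h3k4me3.feature_ids) & set(h3k27me3.feature_ids))
    if not common:
        raise ValueError("no shared genes between the two mark matrices")
    if top_n > len(common):
        logger.info("bivalent_genes: top_n %d > %d genes; using all",
                    top_n, len(common))

    def summarise(mat: SignalMatrix) -> pd.Series:
        vals = mat.values.loc[common]
        if group_samples is not None:
            vals = vals[list(group_samples)]
        return vals.median(axis=1) if summary == "median" else vals.mean(axis=1)

    top_k4 = _top_n_by_signal(summarise(h3k4me3), top_n)
    top_k27 = _top_n_by_signal(summarise(h3k27me3), top_n)
    return top_k4 & top_k27 & degs


def tad_overlap_hypergeom(
    enriched_tads: set[str], marked_tads: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric p for the overlap of two TAD sets.

    P(X >= |enriched ∩ marked|) drawing |marked| TADs from |universe| with
    |enriched| successes.
    """
    if not universe:
        raise ValueError("empty TAD universe")
    if not enriched_tads <= universe or not marked_tads <= universe:
        raise ValueError("TAD sets must be subsets of the universe")
    k = len(enriched_tads & marked_tads)
    return float(
        stats.hypergeom.sf(
            k - 1, len(universe), len(enriched_tads), len(marked_tads)
        )
    )
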