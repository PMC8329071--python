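"""Differential feature calling between grade groups.

The built-in caller is the rank-test route: a two-sided
Mann-Whitney-Wilcoxon test per feature on library-size-normalised counts,
followed by Bonferroni or Benjamini-Hochberg correction.  Externally
produced differential tables (e.g. from a negative-binomial GLM) can be
injected through :func:`read_differential_table` in the same schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylationRecord, GenomicInterval, SampleSheet, SignalMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialRecord",
    "mann_whitney_p",
    "rank_test_differential",
    "bh_adjust",
    "bonferroni_adjust",
    "log2_fold_changes",
    "active_genes",
    "count_hypermethylated",
    "cpm_normalize",
    "differential_to_frame",
    "read_differential_table",
]


@dataclass(frozen=True)
class DifferentialRecord:
    feature_id: str
    log2fc: float
    p_raw: float
    p_adj: float
    significant: bool


def cpm_normalize(matrix: SignalMatrix) -> SignalMatrix:
    """Counts-per-million library-size scaling (columns sum to 1e6).

    All-zero libraries are left untouched rather than divided by zero.
    """
    totals = matrix.values.sum(axis=0)
    safe = totals.replace(0, 1.0)
    return SignalMatrix(matrix.values / safe * 1e6, matrix.kind)


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p-value with the degenerate all-tied guard.

    Exact null distribution when both groups have <= 8 observations and the
    pooled values are tie-free; otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # no information against the null
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and max(len(x), len(y)) <= 8:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def log2_fold_changes(
    matrix: SignalMatrix,
    samples: SampleSheet,
    group1: str,
    group2: str,
    pseudocount: float = 1.0,
    normalize: bool = True,
) -> pd.Series:
    """Per-feature log2((mean(group2)+c) / (mean(group1)+c))."""
    g1 = samples.samples_in(group1)
    g2 = samples.samples_in(group2)
    vals = cpm_normalize(matrix).values if normalize else matrix.values
    m1 = vals[g1].mean(axis=1)
    m2 = vals[g2].mean(axis=1)
    return np.log2((m2 + pseudocount) / (m1 + pseudocount))


def rank_test_differential(
    matrix: SignalMatrix,
    samples: SampleSheet,
    group1: str,
    group2: str,
    correction: str = "bonferroni",
    alpha: float = 0.01,
    pseudocount: float = 1.0,
    normalize: bool = True,
) -> list[DifferentialRecord]:
    """Call differential features between two grade groups.

    Per feature: two-sided Mann-Whitney on the per-sample values of the two
    groups; the chosen multiple-testing correction is applied across all
    tested features; fold change is log2 of group means with a pseudocount.
    """
    g1 = samples.samples_in(group1)
    g2 = samples.samples_in(group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"both groups need >= 2 samples "
            f"({group1}: {len(g1)}, {group2}: {len(g2)})"
        )
    matrix.check_samples(samples)
    vals = cpm_normalize(matrix).values if normalize else matrix.values
    a = vals[g1].to_numpy()
    b = vals[g2].to_numpy()

    p_raw = np.array(
        [mann_whitney_p(a[i], b[i]) for i in range(a.shape[0])]
    )
    if correction == "bonferroni":
        p_adj = bonferroni_adjust(p_raw)
    elif correction == "bh":
        p_adj = bh_adjust(p_raw)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    lfc = np.log2((b.mean(axis=1) + pseudocount) / (a.mean(axis=1) + pseudocount))
    return [
        DifferentialRecord(
            feature_id=fid,
            log2fc=float(lfc[i]),
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
            significant=bool(p_adj[i] < alpha),
        )
        for i, fid in enumerate(matrix.feature_ids)
    ]


def active_genes(expression: SignalMatrix, min_mean: float = 10.0) -> set[str]:
    """Genes with mean raw count across ALL samples >= min_mean (inclusive)."""
    if expression.values.empty:
        raise ValueError("empty expression matrix")
    means = expression.values.mean(axis=1)
    return set(means.index[means >= min_mean])


def count_hypermethylated(
    records: Sequence[MethylationRecord],
    regions: Mapping[str, GenomicInterval],
    sample_ids: Sequence[str],
    threshold: float = 0.8,
) -> SignalMatrix:
    """Per (region, sample) count of cytosines with beta >= threshold.

    The hypermethylation rule is inclusive at the threshold.  Regions or
    samples with no covered cytosines count 0 (explicit, never missing).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    region_items = list(regions.items())
    from .core import IntervalIndex

    index = IntervalIndex(region_items)
    counts = pd.DataFrame(
        0.0, index=[rid for rid, _ in region_items], columns=list(sample_ids)
    )
    unknown = 0
    for rec in records:
        if rec.beta < threshold:
            continue
        if rec.sample_id not in counts.columns:
            unknown += 1
            continue
        for rid in index.query_point(rec.chrom, rec.pos):
            counts.at[rid, rec.sample_id] += 1
    if unknown:
        logger.info(
            "count_hypermethylated: %d records with unknown sample ignored",
            unknown,
        )
    return SignalMatrix(counts, "methyl_count")


def differential_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
            "significant": [r.significant for r in records],
        }
    )


def read_differential_table(path) -> list[DifferentialRecord]:
    """Ingest an externally computed differential table (same TSV schema),
    e.g. output of a negative-binomial GLM run outside this package."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    for col in ("feature_id", "log2fc", "p_raw", "p_adj", "significant"):
        if col not in df.columns:
            raise ValueError(f"{path}: differential table needs column {col!r}")
    sig = df["significant"]
    if sig.dtype == object:
        sig = sig.astype(str).str.lower().isin(("true", "1", "yes"))
    return [
        DifferentialRecord(
            str(r.feature_id), float(r.log2fc), float(r.p_raw),
            float(r.p_adj), bool(s),
        )
        for r, s in zip(df.itertuples(index=False), sig)
    ]
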