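"""Expression-vs-epigenetic-mark correlation analysis.

Spearman correlations of promoter mark signal with expression across
patients, expression-matched random gene backgrounds, a bootstrap test for
the DEG/DEM overlap, and the prognostic-overlap proportions.  Prognostic
status is consumed as an input flag table; no survival model is fitted
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SignalMatrix
from .differential import mann_whitney_p

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationRecord",
    "spearman",
    "gene_mark_correlations",
    "matched_background",
    "bootstrap_overlap_p",
    "prognostic_overlap_ratio",
    "select_high_rho",
    "read_gene_flags",
]


@dataclass(frozen=True)
class CorrelationRecord:
    gene_id: str
    mark_kind: str
    rho: float  # NaN marks an undefined correlation (constant vector)
    n: int


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho with average ranks for ties; NaN when undefined.

    A constant vector has no rank variation, so rho is undefined rather
    than zero — callers exclude NaN records from summaries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def gene_mark_correlations(
    expression: SignalMatrix,
    marks: SignalMatrix,
    genes: Iterable[str],
) -> list[CorrelationRecord]:
    """Per-gene Spearman rho between expression and a promoter mark,
    computed across the samples both matrices share."""
    common = [s for s in expression.sample_ids if s in set(marks.sample_ids)]
    records: list[CorrelationRecord] = []
    skipped = 0
    if len(common) < 3:
        logger.info("gene_mark_correlations: only %d shared samples", len(common))
        return records
    e = expression.values[common]
    m = marks.values[common]
    for gid in genes:
        if gid not in e.index or gid not in m.index:
            skipped += 1
            continue
        rho = spearman(e.loc[gid].to_numpy(), m.loc[gid].to_numpy())
        records.append(CorrelationRecord(gid, marks.kind, rho, len(common)))
    if skipped:
        logger.info("gene_mark_correlations: %d genes missing from a matrix", skipped)
    return records


def matched_background(
    deg_set: set[str],
    pool: set[str],
    expression: SignalMatrix,
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> set[str]:
    """Random gene set of size |deg_set| from pool \\ deg_set whose overall
    mean expression is at least the DEG set's overall mean.

    Rejection sampling over whole sets; if the retry cap is hit, fall back
    to sampling stratified by expression decile (one draw per DEG from the
    matching or a higher decile), which biases the set mean upward.
    """
    candidates = sorted(pool - deg_set)
    k = len(deg_set)
    if len(candidates) < k:
        raise ValueError(
            f"background pool too small: {len(candidates)} < {k}"
        )
    means = expression.values.mean(axis=1)
    target = float(means.loc[sorted(deg_set)].mean())
    cand_means = means.loc[candidates].to_numpy()
    cand_arr = np.array(candidates)
    for _ in range(max_retries):
        idx = rng.choice(len(cand_arr), size=k, replace=False)
        if cand_means[idx].mean() >= target:
            return set(cand_arr[idx])
    # decile-stratified fallback: draw each replacement from candidates at or
    # above the decile of the matched DEG's expression
    order = np.argsort(cand_means)
    sorted_means = cand_means[order]
    sorted_ids = cand_arr[order]
    chosen: list[str] = []
    taken = np.zeros(len(sorted_ids), dtype=bool)
    for deg in sorted(deg_set, key=lambda g: -means.loc[g]):
        lo = np.searchsorted(sorted_means, means.loc[deg], side="left")
        avail = np.flatnonzero(~taken[lo:]) + lo
        if avail.size == 0:
            avail = np.flatnonzero(~taken)  # relax: anything left
        pick = rng.choice(avail)
        taken[pick] = True
        chosen.append(str(sorted_ids[pick]))
    chosen_set = set(chosen)
    if means.loc[sorted(chosen_set)].mean() < target:
        raise ValueError(
            "matched background infeasible: achieved mean "
            f"{means.loc[sorted(chosen_set)].mean():.3g} < target {target:.3g}"
        )
    return chosen_set


def bootstrap_overlap_p(
    deg_set: set[str],
    dem_set: set[str],
    pool: set[str],
    expression: SignalMatrix,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """P(random expression-matched gene set overlaps dem_set at least as
    much as deg_set does), with the (k+1)/(n+1) never-zero estimator."""
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng() if rng is None else rng
    observed = len(deg_set & dem_set)
    hits = 0
    for _ in range(reps):
        rand = matched_background(deg_set, pool, expression, rng)
        if len(rand & dem_set) >= observed:
            hits += 1
    return (1 + hits) / (reps + 1)


def prognostic_overlap_ratio(
    gene_sets: Mapping[str, set[str]],
    prognostic: set[str],
    denominator_sets: Mapping[str, set[str]],
) -> dict[str, float]:
    """|set ∩ prognostic| / |denominator| for each named comparison set."""
    out: dict[str, float] = {}
    for name, gset in gene_sets.items():
        denom = denominator_sets[name]
        if not denom:
            raise ValueError(f"empty denominator set for {name!r}")
        out[name] = len(gset & prognostic) / len(denom)
    return out


def compare_overlap_proportions(
    props_a: Sequence[float], props_b: Sequence[float]
) -> float:
    """Two-sided rank-test p comparing two sets of per-comparison
    proportions (e.g. high-rho DEGs vs all DEGs)."""
    return mann_whitney_p(np.asarray(props_a), np.asarray(props_b))


def select_high_rho(
    records: Sequence[CorrelationRecord], threshold: float = 0.7
) -> set[str]:
    """Genes with rho STRICTLY greater than the threshold; undefined rho
    (NaN) never qualifies."""
    return {
        r.gene_id for r in records if not np.isnan(r.rho) and r.rho > threshold
    }


def read_gene_flags(path, flag_column: str) -> set[str]:
    """Two-column TSV (gene_id, <flag>) -> set of flagged gene ids."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or flag_column not in df.columns:
        raise ValueError(f"{path}: needs columns gene_id and {flag_column!r}")
    flags = df[flag_column]
    if flags.dtype == object:
        flags = flags.astype(str).str.lower().isin(("true", "1", "yes"))
    return set(df.loc[flags.astype(bool), "gene_id"])
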