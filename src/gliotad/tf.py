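"""TF-target correlation filtering against a random-target envelope.

Candidate (TF, target) pairs are an input (derived upstream by motif
scanning, outside this package).  For each TF, the Spearman correlation
with each candidate target is compared against the envelope of that TF's
correlations with randomly drawn active genes: a pair is retained only if
its rho exceeds the envelope maximum (activating case) or lies below the
envelope minimum (repressive case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SignalMatrix
from .correlation import spearman

logger = logging.getLogger(__name__)

__all__ = [
    "TfTargetRecord",
    "Envelope",
    "tf_target_correlations",
    "random_target_envelope",
    "filter_by_envelope",
    "read_candidate_pairs",
]


@dataclass(frozen=True)
class TfTargetRecord:
    tf_gene_id: str
    target_gene_id: str
    rho: float
    passes_envelope: bool = False


@dataclass(frozen=True)
class Envelope:
    tf_gene_id: str
    min_rho: float
    max_rho: float
    median_rho: float
    n_draws: int


def tf_target_correlations(
    candidates: Sequence[tuple[str, str]],
    expression: SignalMatrix,
) -> tuple[list[TfTargetRecord], dict[str, float]]:
    """Spearman rho for each candidate (TF, target) pair across samples.

    Pairs with a gene missing from the expression matrix are skipped and
    counted in the log.  Also returns the per-TF median rho over that TF's
    scored pairs.
    """
    vals = expression.values
    records: list[TfTargetRecord] = []
    skipped = 0
    for tf, target in candidates:
        if tf not in vals.index or target not in vals.index:
            skipped += 1
            continue
        rho = spearman(vals.loc[tf].to_numpy(), vals.loc[target].to_numpy())
        records.append(TfTargetRecord(tf, target, rho))
    if skipped:
        logger.info("tf_target_correlations: %d candidate pairs skipped", skipped)
    medians: dict[str, float] = {}
    by_tf: dict[str, list[float]] = {}
    for r in records:
        if not np.isnan(r.rho):
            by_tf.setdefault(r.tf_gene_id, []).append(r.rho)
    for tf, rhos in by_tf.items():
        medians[tf] = float(np.median(rhos))
    return records, medians


def random_target_envelope(
    tf: str,
    pool: set[str],
    expression: SignalMatrix,
    n_draws: int = 100,
    rng: np.random.Generator | None = None,
    exclude: set[str] | None = None,
) -> Envelope:
    """Envelope (min, max, median) of the TF's Spearman rho against
    n_draws active genes drawn at random, excluding the TF itself and its
    real candidate targets."""
    rng = np.random.default_rng() if rng is None else rng
    exclude = set() if exclude is None else set(exclude)
    vals = expression.values
    candidates = sorted(
        g for g in pool
        if g != tf and g not in exclude and g in vals.index
    )
    if len(candidates) < n_draws:
        raise ValueError(
            f"pool too small for TF {tf!r}: {len(candidates)} < {n_draws}"
        )
    drawn = rng.choice(len(candidates), size=n_draws, replace=False)
    tf_vec = vals.loc[tf].to_numpy()
    rhos = []
    for i in drawn:
        rho = spearman(tf_vec, vals.loc[candidates[i]].to_numpy())
        if not np.isnan(rho):
            rhos.append(rho)
    if not rhos:
        raise ValueError(f"all random-target correlations undefined for {tf!r}")
    arr = np.asarray(rhos)
    return Envelope(tf, float(arr.min()), float(arr.max()),
                    float(np.median(arr)), n_draws)


def filter_by_envelope(
    records: Sequence[TfTargetRecord],
    envelopes: Mapping[str, Envelope],
) -> list[TfTargetRecord]:
    """Retain a pair iff rho > envelope max (positive branch) or
    rho < envelope min (negative branch); NaN rho never passes."""
    out: list[TfTargetRecord] = []
    for r in records:
        if r.tf_gene_id not in envelopes:
            raise KeyError(f"no envelope for TF {r.tf_gene_id!r}")
        env = envelopes[r.tf_gene_id]
        passes = (not np.isnan(r.rho)) and (
            r.rho > env.max_rho or r.rho < env.min_rho
        )
        out.append(
            TfTargetRecord(r.tf_gene_id, r.target_gene_id, r.rho, passes)
        )
    return out


def read_candidate_pairs(path) -> list[tuple[str, str]]:
    """TSV with columns tf_gene_id, target_gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("tf_gene_id", "target_gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: candidates table needs column {col!r}")
    return list(zip(df["tf_gene_id"], df["target_gene_id"]))


def tf_records_to_frame(
    records: Sequence[TfTargetRecord],
    envelopes: Mapping[str, Envelope] | None = None,
) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "tf_gene_id": r.tf_gene_id,
            "target_gene_id": r.target_gene_id,
            "rho": r.rho,
            "passes_envelope": r.passes_envelope,
        }
        if envelopes and r.tf_gene_id in envelopes:
            env = envelopes[r.tf_gene_id]
            row["envelope_min"] = env.min_rho
            row["envelope_max"] = env.max_rho
        rows.append(row)
    return pd.DataFrame(rows)
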