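"""Promoter windows, promoter signal aggregation and gene-to-TAD assignment.

Promoters are the symmetric window TSS +/- flank (default 2 kb), clipped at
the chromosome start; membership of a gene in a TAD is decided by its TSS
point, since the analysis is promoter-centric and gene bodies may straddle
TAD borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    GeneAnnotation,
    GenomicInterval,
    IntervalIndex,
    SignalMatrix,
    TadSegment,
    validate_tads,
)

logger = logging.getLogger(__name__)

__all__ = ["PromoterSet", "TadAssignment", "make_promoters",
           "aggregate_signal", "assign_genes_to_tads"]


@dataclass
class PromoterSet:
    """gene_id -> promoter window."""

    windows: dict[str, GenomicInterval]

    def __getitem__(self, gene_id: str) -> GenomicInterval:
        return self.windows[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.windows

    def __len__(self) -> int:
        return len(self.windows)

    def items(self):
        return self.windows.items()

    def index(self) -> IntervalIndex:
        return IntervalIndex(self.windows.items())

    def to_bed_items(self) -> list[tuple[str, GenomicInterval]]:
        return list(self.windows.items())


@dataclass
class TadAssignment:
    """Bidirectional gene <-> TAD maps; genes outside all TADs map to None."""

    gene_to_tad: dict[str, str | None]
    tad_to_genes: dict[str, list[str]]

    def genes_in(self, tad_id: str) -> list[str]:
        return self.tad_to_genes.get(tad_id, [])

    @property
    def assigned_genes(self) -> list[str]:
        return [g for g, t in self.gene_to_tad.items() if t is not None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.gene_to_tad),
                "tad_id": [t if t is not None else ""
                           for t in self.gene_to_tad.values()],
            }
        )


def make_promoters(genes: Sequence[GeneAnnotation], flank: int = 2000) -> PromoterSet:
    """Promoter = [max(0, tss - flank), tss + flank), strand-agnostic."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    windows = {
        g.gene_id: GenomicInterval(g.chrom, max(0, g.tss - flank), g.tss + flank)
        for g in genes
    }
    return PromoterSet(windows)


def aggregate_signal(
    peaks: Sequence[tuple[GenomicInterval, Mapping[str, float]]],
    regions: PromoterSet | Sequence[tuple[str, GenomicInterval]],
    sample_ids: Sequence[str],
    kind: str,
) -> SignalMatrix:
    """Sum per-sample peak signal into each region it overlaps.

    A peak overlapping several regions contributes its full value to each
    (no proportional splitting).  Regions with no overlapping signal get 0.
    """
    if isinstance(regions, PromoterSet):
        region_items = list(regions.items())
    else:
        region_items = list(regions)
    index = IntervalIndex(region_items)
    values = pd.DataFrame(
        0.0, index=[rid for rid, _ in region_items], columns=list(sample_ids)
    )
    known = set(sample_ids)
    for iv, per_sample in peaks:
        unknown = set(per_sample) - known
        if unknown:
            raise ValueError(f"unknown sample ids in signal: {sorted(unknown)}")
        hits = index.query(iv)
        if not hits:
            continue
        for rid in hits:
            for sid, v in per_sample.items():
                values.at[rid, sid] += v
    return SignalMatrix(values, kind)


def assign_genes_to_tads(
    genes: Sequence[GeneAnnotation], tads: Sequence[TadSegment]
) -> TadAssignment:
    """Assign each gene to the TAD containing its TSS (half-open test).

    Genes outside all TADs map to None and are excluded from TAD-level
    statistics downstream; their count is logged.
    """
    validate_tads(tads)
    index = IntervalIndex((t.tad_id, t.interval) for t in tads)
    gene_to_tad: dict[str, str | None] = {}
    tad_to_genes: dict[str, list[str]] = {t.tad_id: [] for t in tads}
    unassigned = 0
    for g in genes:
        hits = index.query_point(g.chrom, g.tss)
        if hits:
            tad_id = hits[0]  # TADs partition, so at most one hit
            gene_to_tad[g.gene_id] = tad_id
            tad_to_genes[tad_id].append(g.gene_id)
        else:
            gene_to_tad[g.gene_id] = None
            unassigned += 1
    if unassigned:
        logger.info("assign_genes_to_tads: %d genes outside all TADs", unassigned)
    return TadAssignment(gene_to_tad, tad_to_genes)
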