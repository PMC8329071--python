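"""Domain types, coordinate conventions and tabular genomic I/O.

All coordinates are held internally as 0-based half-open intervals
``[start, end)``.  Tables printed with 1-based inclusive coordinates (the
convention of most genome browsers) are converted at the I/O boundary and
converted back on write, so no off-by-one arithmetic leaks into the
statistics.

Chromosome names are matched as exact strings (``"chr5" != "5"``); readers
accept a ``chrom_prefix`` option that adds or strips the ``chr`` prefix at
load time for sources that disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "TadSegment",
    "ContactPair",
    "SampleSheet",
    "SignalMatrix",
    "MethylationRecord",
    "PipelineConfig",
    "IntervalIndex",
    "read_intervals",
    "write_intervals",
    "read_contacts",
    "write_contacts",
    "overlap_query",
    "read_signal_matrix",
    "read_sample_sheet",
    "read_methylation",
    "read_gene_annotation",
    "read_tads",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic range ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: [0,10) and [10,20) do NOT overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its canonical, strand-aware TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")


@dataclass(frozen=True)
class TadSegment:
    tad_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class ContactPair:
    """An intra-chromosomal pair of contact anchors from a Hi-C-derived map."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValueError("contact score must be non-negative")


class SampleSheet:
    """Sample -> grade-group assignment (default groups PA, DA, GBM).

    pGBM is pooled into GBM upstream; the sheet only knows the pooled label.
    """

    DEFAULT_GROUPS = ("PA", "DA", "GBM")

    def __init__(
        self,
        sample_ids: Sequence[str],
        groups: Sequence[str],
        group_order: Sequence[str] = DEFAULT_GROUPS,
    ) -> None:
        if len(sample_ids) != len(groups):
            raise ValueError("sample_ids and groups length mismatch")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids in sample sheet")
        unknown = set(groups) - set(group_order)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        self.sample_ids = list(sample_ids)
        self.group_of = dict(zip(sample_ids, groups))
        self.group_order = tuple(group_order)

    def samples_in(self, group: str) -> list[str]:
        if group not in self.group_order:
            raise KeyError(f"unknown group {group!r}")
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids,
             "group": [self.group_of[s] for s in self.sample_ids]}
        )


SIGNAL_KINDS = (
    "expression",
    "H3K4me3",
    "H3K27ac",
    "H3K27me3",
    "ATAC",
    "DNase",
    "methyl_count",
)


class SignalMatrix:
    """Feature x sample matrix of non-negative signal (counts or coverage)."""

    def __init__(self, values: pd.DataFrame, kind: str) -> None:
        if kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {kind!r}")
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("duplicate feature or sample ids")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("SignalMatrix must not contain missing cells")
        if (arr < 0).any():
            raise ValueError("SignalMatrix values must be non-negative")
        self.values = values.astype(float)
        self.kind = kind

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Sequence[str]) -> "SignalMatrix":
        missing = set(samples) - set(self.values.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        return SignalMatrix(self.values[list(samples)], self.kind)

    def check_samples(self, sheet: SampleSheet) -> None:
        missing = set(self.sample_ids) - set(sheet.sample_ids)
        if missing:
            raise ValueError(
                f"samples absent from sample sheet: {sorted(missing)}"
            )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


@dataclass(frozen=True)
class MethylationRecord:
    """One cytosine's methylation fraction (beta) in one sample."""

    chrom: str
    pos: int
    sample_id: str
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta {self.beta} outside [0, 1]")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


@dataclass
class PipelineConfig:
    """Every threshold the analysis uses, with the published value as default."""

    promoter_flank: int = 2000          # promoter = TSS +/- 2 kb
    deg_alpha: float = 0.01             # FDR cut-off for DEG/DEM calls
    active_min_mean: float = 10.0       # active gene: >= 10 reads on average
    rho_select: float = 0.7             # high-correlation DEGs: rho > 0.7
    beta_hyper: float = 0.8             # hypermethylated cytosine: beta >= 0.8
    enrich_alpha: float = 0.05          # BH threshold for TAD enrichment
    min_tad_genes: int = 3              # TADs with fewer genes excluded
    contact_max_dist: int = 2_000_000   # enhancer-promoter distance cap
    multi_contact_min: int = 6          # "multiple contacts" class boundary
    bivalent_top_n: int = 1000          # top-N genes per mark for bivalency
    enhancer_diff_alpha: float = 0.01   # raw-p cut-off, differential enhancers
    n_perm: int = 1000                  # homogeneity permutations
    n_boot: int = 1000                  # bootstrap replicates (overlap test)
    n_corr_perm: int = 100              # correlation permutation replicates
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("promoter_flank", "active_min_mean", "contact_max_dist",
                     "multi_contact_min", "bivalent_top_n", "min_tad_genes",
                     "n_perm", "n_boot", "n_corr_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("deg_alpha", "enrich_alpha", "enhancer_diff_alpha",
                     "beta_hyper", "rho_select"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# interval index / overlap queries
# ---------------------------------------------------------------------------


class IntervalIndex:
    """Per-chromosome interval tree over (id, GenomicInterval) targets."""

    def __init__(self, targets: Iterable[tuple[str, GenomicInterval]]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._targets = list(targets)
        for ident, iv in self._targets:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, ident
            )

    def query(self, query: GenomicInterval) -> list[str]:
        """Ids of all targets intersecting ``query`` (half-open semantics)."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return [hit.data for hit in sorted(tree.overlap(query.start, query.end))]

    def query_point(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in sorted(tree.at(pos))]


def overlap_query(
    targets: Sequence[tuple[str, GenomicInterval]], query: GenomicInterval
) -> list[str]:
    """One-shot overlap query; build an IntervalIndex for repeated use."""
    return IntervalIndex(targets).query(query)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _normalize_chrom(chrom: str, chrom_prefix: str | None) -> str:
    if chrom_prefix == "add" and not chrom.startswith("chr"):
        return "chr" + chrom
    if chrom_prefix == "strip" and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def _convert_coords(start: int, end: int, convention: str) -> tuple[int, int]:
    if convention == "bed0":
        return start, end
    if convention == "onebased_inclusive":
        return start - 1, end
    raise ValueError(f"unknown coordinate convention {convention!r}")


def read_intervals(
    path,
    convention: str = "bed0",
    chrom_prefix: str | None = None,
) -> list[tuple[str, GenomicInterval]]:
    """Read a BED-like table into (id, interval) pairs.

    Requires >= 3 columns (chrom, start, end); a 4th column, when present,
    is the feature id; otherwise ids ``row1, row2, ...`` are generated.
    Input order is preserved.
    """
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 columns, "
                    f"got {len(fields)}"
                )
            chrom = _normalize_chrom(fields[0], chrom_prefix)
            try:
                raw_start, raw_end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            start, end = _convert_coords(raw_start, raw_end, convention)
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start >= end after conversion"
                )
            if start < 0:
                raise ValueError(f"{path}: line {lineno}: negative start")
            ident = fields[3] if len(fields) > 3 and fields[3] else f"row{lineno}"
            out.append((ident, GenomicInterval(chrom, start, end)))
    return out


def write_intervals(
    path, items: Sequence[tuple[str, GenomicInterval]], convention: str = "bed0"
) -> None:
    with open(path, "w") as fh:
        for ident, iv in items:
            if convention == "bed0":
                s, e = iv.start, iv.end
            elif convention == "onebased_inclusive":
                s, e = iv.start + 1, iv.end
            else:
                raise ValueError(f"unknown coordinate convention {convention!r}")
            fh.write(f"{iv.chrom}\t{s}\t{e}\t{ident}\n")


def read_contacts(path, chrom_prefix: str | None = None) -> list[ContactPair]:
    """Read a BEDPE contact table; inter-chromosomal rows are dropped.

    The number of dropped pairs is logged so bookkeeping stays auditable.
    """
    pairs: list[ContactPair] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BEDPE needs >= 6 columns, "
                    f"got {len(fields)}"
                )
            ca = _normalize_chrom(fields[0], chrom_prefix)
            cb = _normalize_chrom(fields[3], chrom_prefix)
            a = GenomicInterval(ca, int(fields[1]), int(fields[2]))
            b = GenomicInterval(cb, int(fields[4]), int(fields[5]))
            score = None
            if len(fields) > 6 and fields[6] not in ("", "."):
                score = float(fields[6])
            if ca != cb:
                dropped += 1
                continue
            pairs.append(ContactPair(a, b, score))
    if dropped:
        logger.info("read_contacts: dropped %d inter-chromosomal pairs", dropped)
    return pairs


def write_contacts(path, pairs: Sequence[ContactPair]) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(
                f"{p.anchor_a.chrom}\t{p.anchor_a.start}\t{p.anchor_a.end}\t"
                f"{p.anchor_b.chrom}\t{p.anchor_b.start}\t{p.anchor_b.end}\t"
                f"{score}\n"
            )


def read_signal_matrix(path, kind: str) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SignalMatrix(df, kind)


def read_sample_sheet(path, group_order=SampleSheet.DEFAULT_GROUPS) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet needs a {col!r} column")
    return SampleSheet(df["sample_id"].tolist(), df["group"].tolist(), group_order)


def read_methylation(path) -> list[MethylationRecord]:
    """Read a bedGraph-like TSV: chrom, pos (0-based), sample_id, beta."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    for col in ("chrom", "pos", "sample_id", "beta"):
        if col not in df.columns:
            raise ValueError(f"{path}: methylation table needs column {col!r}")
    return [
        MethylationRecord(r.chrom, int(r.pos), r.sample_id, float(r.beta))
        for r in df.itertuples(index=False)
    ]


def write_methylation(path, records: Sequence[MethylationRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tsample_id\tbeta\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.sample_id}\t{r.beta:.6g}\n")


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """TSV with header: gene_id, chrom, strand, tss (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    for col in ("gene_id", "chrom", "strand", "tss"):
        if col not in df.columns:
            raise ValueError(f"{path}: gene table needs column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    return [
        GeneAnnotation(r.gene_id, r.chrom, r.strand, int(r.tss))
        for r in df.itertuples(index=False)
    ]


def write_gene_annotation(path, genes: Sequence[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def validate_tads(tads: Sequence[TadSegment]) -> None:
    """TADs on one chromosome must not overlap: the partition assumption
    underlies every TAD-level statistic, so a violation is an error."""
    by_chrom: dict[str, list[TadSegment]] = {}
    seen_ids: set[str] = set()
    for t in tads:
        if t.tad_id in seen_ids:
            raise ValueError(f"duplicate TAD id {t.tad_id!r}")
        seen_ids.add(t.tad_id)
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda t: t.interval.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.interval.start < prev.interval.end:
                raise ValueError(
                    f"overlapping TADs on {chrom}: "
                    f"{prev.tad_id} and {cur.tad_id}"
                )


def read_tads(path, convention: str = "bed0",
              chrom_prefix: str | None = None) -> list[TadSegment]:
    tads = [
        TadSegment(ident, iv)
        for ident, iv in read_intervals(path, convention, chrom_prefix)
    ]
    validate_tads(tads)
    return tads
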