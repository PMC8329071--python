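"""Synthetic glioma-cohort generator.

Builds a small genome partitioned into TADs, genes with strand-aware TSSs,
and a full multi-assay cohort with the statistical structure the analysis
assumes: negative-binomially distributed expression counts with grade
effects partly concentrated into designated "enriched" TADs, promoter mark
signal coupled to expression through a Gaussian copula on ranks, enhancers
with grade-specific acetylation, promoter-enhancer contact pairs, and
methylation betas anticorrelated with enhancer acetylation.

Ground truth (which genes are true DEGs, which TADs were spiked, which
enhancers are truly differential) is emitted alongside so every detection
stage can be scored.

Randomness: one seed in the config; every data type draws from its own
child stream derived from the seed by a fixed integer key, so adding a
data type never perturbs the others and identical configs give
byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ContactPair,
    GeneAnnotation,
    GenomicInterval,
    MethylationRecord,
    SampleSheet,
    SignalMatrix,
    TadSegment,
    write_contacts,
    write_gene_annotation,
    write_intervals,
    write_methylation,
)
from .promoters import make_promoters

__all__ = ["SimulationConfig", "GroundTruth", "Cohort",
           "generate_genome", "generate_expression", "generate_cohort",
           "write_cohort"]

# fixed sub-stream keys: adding a data type appends a key, never reorders
_STREAMS = {
    "genome": 0,
    "expression": 1,
    "marks": 2,
    "enhancers": 3,
    "contacts": 4,
    "methylation": 5,
}

MARK_KINDS_COUPLED = ("H3K4me3", "H3K27ac", "ATAC", "DNase")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Group sizes default to the study design this emulates: 11 pilocytic
    astrocytomas (PA), 7 diffuse astrocytomas (DA) and 15 glioblastomas
    (GBM, the single paediatric case pooled in).
    """

    n_chrom: int = 2
    chrom_length: int = 50_000_000
    n_tads: int = 50
    genes_per_tad: int = 8
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"PA": 11, "DA": 7, "GBM": 15}
    )
    nb_mean: float = 100.0
    nb_dispersion: float = 0.2
    frac_deg: float = 0.1
    lfc_effect: float = 2.0
    tad_coupling: float = 0.5
    n_enriched_tads: int = 5
    mark_coupling_rho: float = 0.7
    n_enhancers: int = 200
    frac_diff_enhancers: float = 0.2
    contacts_per_gene: float = 3.0
    methyl_anticorr: float = 0.7
    cpgs_per_enhancer: int = 6
    enhancer_width: int = 1500
    contact_max_dist: int = 2_000_000
    promoter_flank: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_deg", "tad_coupling", "frac_diff_enhancers",
                     "methyl_anticorr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not (0.0 <= self.mark_coupling_rho <= 1.0):
            raise ValueError("mark_coupling_rho must lie in [0, 1]")
        for name in ("n_chrom", "chrom_length", "n_tads", "genes_per_tad",
                     "n_enhancers", "cpgs_per_enhancer", "enhancer_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_enriched_tads < 0 or self.n_enriched_tads > self.n_tads:
            raise ValueError("n_enriched_tads must lie in [0, n_tads]")
        for g, n in self.n_samples_per_group.items():
            if n < 2:
                raise ValueError(f"group {g} needs >= 2 samples")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Everything needed to score the detection stages downstream."""

    deg_genes: dict[str, int]        # gene_id -> effect sign (+1 / -1)
    enriched_tads: set[str]
    gene_tad: dict[str, str]
    diff_enhancers: dict[str, int] = field(default_factory=dict)

    def to_gene_frame(self) -> pd.DataFrame:
        genes = sorted(self.gene_tad)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "tad_id": [self.gene_tad[g] for g in genes],
                "is_deg": [g in self.deg_genes for g in genes],
                "effect_sign": [self.deg_genes.get(g, 0) for g in genes],
            }
        )


@dataclass
class Cohort:
    genes: list[GeneAnnotation]
    tads: list[TadSegment]
    truth: GroundTruth
    samples: SampleSheet
    expression: SignalMatrix
    marks: dict[str, SignalMatrix]
    enhancers: list[tuple[str, GenomicInterval]]
    enhancer_acetylation: pd.DataFrame
    contacts: list[ContactPair]
    methylation: list[MethylationRecord]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def generate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneAnnotation], list[TadSegment], GroundTruth]:
    """Tile TADs over the chromosomes and drop genes into them.

    Every TAD receives exactly ``genes_per_tad`` genes; TSSs are drawn
    uniformly inside the TAD with a safety margin so promoter windows stay
    within the TAD.  True-DEG labels are assigned so that a fraction
    ``tad_coupling`` of them land in ``n_enriched_tads`` designated TADs.
    """
    rng = config.rng("genome")
    per_chrom = int(np.ceil(config.n_tads / config.n_chrom))
    tad_width = config.chrom_length // per_chrom
    margin = max(config.promoter_flank, 2500)
    if tad_width <= 2 * margin + config.genes_per_tad:
        raise ValueError(
            "chrom_length too small for the requested TAD/gene layout"
        )

    tads: list[TadSegment] = []
    genes: list[GeneAnnotation] = []
    gene_tad: dict[str, str] = {}
    gidx = 0
    for t in range(config.n_tads):
        chrom = f"chr{t % config.n_chrom + 1}"
        slot = t // config.n_chrom
        start = slot * tad_width
        tad = TadSegment(f"tad{t:04d}",
                         GenomicInterval(chrom, start, start + tad_width))
        tads.append(tad)
        positions = np.sort(
            rng.choice(
                np.arange(start + margin, start + tad_width - margin),
                size=config.genes_per_tad,
                replace=False,
            )
        )
        for pos in positions:
            gid = f"g{gidx:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneAnnotation(gid, chrom, strand, int(pos)))
            gene_tad[gid] = tad.tad_id
            gidx += 1

    n_genes = len(genes)
    n_deg = int(round(config.frac_deg * n_genes))
    enriched = set()
    deg_genes: dict[str, int] = {}
    if n_deg > 0:
        tad_ids = [t.tad_id for t in tads]
        enriched = set(
            rng.choice(tad_ids, size=config.n_enriched_tads, replace=False)
        )
        inside = [g.gene_id for g in genes if gene_tad[g.gene_id] in enriched]
        outside = [g.gene_id for g in genes if gene_tad[g.gene_id] not in enriched]
        n_inside = min(int(round(config.tad_coupling * n_deg)), len(inside))
        n_outside = min(n_deg - n_inside, len(outside))
        picked = list(rng.choice(inside, size=n_inside, replace=False))
        picked += list(rng.choice(outside, size=n_outside, replace=False))
        for g in picked:
            deg_genes[g] = 1 if rng.random() < 0.5 else -1
    truth = GroundTruth(deg_genes, enriched, gene_tad)
    return genes, tads, truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _make_samples(config: SimulationConfig) -> SampleSheet:
    ids, groups = [], []
    for grp, n in config.n_samples_per_group.items():
        for i in range(n):
            ids.append(f"{grp}{i + 1:02d}")
            groups.append(grp)
    return SampleSheet(ids, groups,
                       group_order=tuple(config.n_samples_per_group))


def _group_multiplier(group: str, sign: int, lfc: float) -> float:
    # grade-graded monotone effect: full shift in GBM, half in DA, none in PA
    if group == "GBM":
        return 2.0 ** (sign * lfc)
    if group == "DA":
        return 2.0 ** (sign * lfc / 2.0)
    return 1.0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + mu^2 * dispersion."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_expression(
    genes: list[GeneAnnotation],
    truth: GroundTruth,
    config: SimulationConfig,
    samples: SampleSheet | None = None,
) -> tuple[SignalMatrix, SampleSheet]:
    """Negative-binomial expression counts with grade effects for true DEGs."""
    rng = config.rng("expression")
    samples = _make_samples(config) if samples is None else samples
    gene_ids = [g.gene_id for g in genes]
    base = config.nb_mean * rng.lognormal(0.0, 0.5, size=len(gene_ids))
    counts = np.empty((len(gene_ids), len(samples)), dtype=float)
    for j, sid in enumerate(samples.sample_ids):
        grp = samples.group_of[sid]
        mult = np.array(
            [_group_multiplier(grp, truth.deg_genes.get(g, 0),
                               config.lfc_effect) if g in truth.deg_genes
             else 1.0
             for g in gene_ids]
        )
        counts[:, j] = _nb_draw(rng, base * mult, config.nb_dispersion)
    mat = SignalMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples.sample_ids),
        "expression",
    )
    return mat, samples


def _latent_from_ranks(values: np.ndarray) -> np.ndarray:
    """Normal scores of the ranks of a vector (ties averaged)."""
    ranks = stats.rankdata(values)
    return stats.norm.ppf(ranks / (len(values) + 1))


def _spearman_to_pearson(rho: float) -> float:
    """Latent Pearson correlation that yields the target Spearman rho for
    a bivariate Gaussian copula: r = 2 sin(pi * rho / 6)."""
    return float(2.0 * np.sin(np.pi * rho / 6.0))


def _coupled_signal(
    rng: np.random.Generator,
    anchor: np.ndarray,       # features x samples, the signal to couple to
    rho: float,
    base_mean: float,
) -> np.ndarray:
    """Lognormal signal whose per-feature Spearman correlation with the
    anchor rows targets ``rho`` via a Gaussian copula on ranks."""
    r = _spearman_to_pearson(rho)
    n_feat, n_samp = anchor.shape
    base = base_mean * rng.lognormal(0.0, 0.5, size=n_feat)
    out = np.empty_like(anchor, dtype=float)
    for i in range(n_feat):
        z = _latent_from_ranks(anchor[i])
        eps = rng.standard_normal(n_samp)
        latent = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        out[i] = base[i] * np.exp(0.5 * latent)
    return out


def generate_cohort(
    genes: list[GeneAnnotation],
    tads: list[TadSegment],
    truth: GroundTruth,
    config: SimulationConfig,
) -> Cohort:
    """Emit the complete multi-assay cohort for a generated genome."""
    expression, samples = generate_expression(genes, truth, config)
    gene_ids = [g.gene_id for g in genes]
    expr_arr = expression.values.to_numpy()

    # promoter marks: activating/open marks coupled to expression,
    # H3K27me3 (repressive) independent
    rng_marks = config.rng("marks")
    marks: dict[str, SignalMatrix] = {}
    for kind in MARK_KINDS_COUPLED:
        sig = _coupled_signal(rng_marks, expr_arr, config.mark_coupling_rho,
                              base_mean=50.0)
        marks[kind] = SignalMatrix(
            pd.DataFrame(sig, index=gene_ids, columns=samples.sample_ids), kind
        )
    k27me3 = 50.0 * rng_marks.lognormal(
        0.0, 0.5, size=(len(gene_ids), 1)
    ) * rng_marks.lognormal(0.0, 0.5, size=(len(gene_ids), len(samples)))
    marks["H3K27me3"] = SignalMatrix(
        pd.DataFrame(k27me3, index=gene_ids, columns=samples.sample_ids),
        "H3K27me3",
    )

    # enhancers: intervals outside all promoter windows, with per-sample
    # acetylation; a fraction get a grade-specific shift
    rng_enh = config.rng("enhancers")
    promoters = make_promoters(genes, config.promoter_flank)
    prom_index = promoters.index()
    chrom_len: dict[str, int] = {}
    for t in tads:
        chrom_len[t.interval.chrom] = max(
            chrom_len.get(t.interval.chrom, 0), t.interval.end
        )
    chroms = sorted(chrom_len)
    enh_items: list[tuple[str, GenomicInterval]] = []
    attempts = 0
    while len(enh_items) < config.n_enhancers and attempts < config.n_enhancers * 100:
        attempts += 1
        chrom = chroms[int(rng_enh.integers(len(chroms)))]
        start = int(rng_enh.integers(0, chrom_len[chrom] - config.enhancer_width))
        iv = GenomicInterval(chrom, start, start + config.enhancer_width)
        if prom_index.query(iv):
            continue
        enh_items.append((f"enh{len(enh_items):05d}", iv))
    if len(enh_items) < config.n_enhancers:
        raise ValueError("could not place enhancers outside promoters")

    n_diff = int(round(config.frac_diff_enhancers * len(enh_items)))
    diff_ids = list(
        rng_enh.choice([e for e, _ in enh_items], size=n_diff, replace=False)
    )
    truth.diff_enhancers = {
        e: (1 if rng_enh.random() < 0.5 else -1) for e in diff_ids
    }
    base = 30.0 * rng_enh.lognormal(0.0, 0.5, size=len(enh_items))
    acet = np.empty((len(enh_items), len(samples)))
    for j, sid in enumerate(samples.sample_ids):
        grp = samples.group_of[sid]
        mult = np.array(
            [_group_multiplier(grp, truth.diff_enhancers.get(eid, 0),
                               config.lfc_effect)
             if eid in truth.diff_enhancers else 1.0
             for eid, _ in enh_items]
        )
        acet[:, j] = base * mult * rng_enh.lognormal(0.0, 0.4,
                                                     size=len(enh_items))
    acet_df = pd.DataFrame(
        acet, index=[e for e, _ in enh_items], columns=samples.sample_ids
    )

    # contacts: each gene's promoter linked to Poisson-many enhancers on
    # the same chromosome within the distance cap
    rng_con = config.rng("contacts")
    enh_by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for eid, iv in enh_items:
        enh_by_chrom.setdefault(iv.chrom, []).append((eid, iv))
    contacts: list[ContactPair] = []
    for g in genes:
        prom = promoters[g.gene_id]
        eligible = [
            (eid, iv) for eid, iv in enh_by_chrom.get(g.chrom, [])
            if abs(prom.midpoint - iv.midpoint) <= config.contact_max_dist
        ]
        if not eligible:
            continue
        k = int(rng_con.poisson(config.contacts_per_gene))
        for _ in range(k):
            eid, iv = eligible[int(rng_con.integers(len(eligible)))]
            contacts.append(ContactPair(prom, iv))

    # methylation: CpG betas at enhancers, anticorrelated (on ranks) with
    # per-sample acetylation
    rng_met = config.rng("methylation")
    r = _spearman_to_pearson(config.methyl_anticorr)
    methylation: list[MethylationRecord] = []
    for row, (eid, iv) in enumerate(enh_items):
        positions = np.sort(
            rng_met.choice(
                np.arange(iv.start, iv.end), size=config.cpgs_per_enhancer,
                replace=False,
            )
        )
        z = _latent_from_ranks(acet[row])
        eps = rng_met.standard_normal(len(samples))
        latent = -r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        intercept = rng_met.normal(0.0, 0.5)
        for j, sid in enumerate(samples.sample_ids):
            mean_beta = 1.0 / (1.0 + np.exp(-(intercept + latent[j])))
            jitter = rng_met.normal(0.0, 0.05, size=len(positions))
            betas = np.clip(mean_beta + jitter, 0.0, 1.0)
            for pos, beta in zip(positions, betas):
                methylation.append(
                    MethylationRecord(iv.chrom, int(pos), sid, float(beta))
                )

    return Cohort(
        genes=genes,
        tads=tads,
        truth=truth,
        samples=samples,
        expression=expression,
        marks=marks,
        enhancers=enh_items,
        enhancer_acetylation=acet_df,
        contacts=contacts,
        methylation=methylation,
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Convenience wrapper: genome + cohort in one call."""
    genes, tads, truth = generate_genome(config)
    return generate_cohort(genes, tads, truth, config)


# ---------------------------------------------------------------------------
# on-disk cohort (the exact formats the core readers consume)
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write a cohort directory; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def note(key: str, p: Path) -> Path:
        paths[key] = str(p)
        return p

    write_gene_annotation(note("genes", outdir / "genes.tsv"), cohort.genes)
    write_intervals(
        note("tads", outdir / "tads.bed"),
        [(t.tad_id, t.interval) for t in cohort.tads],
    )
    cohort.samples.to_frame().to_csv(
        note("samples", outdir / "samples.tsv"), sep="\t", index=False
    )
    cohort.expression.to_tsv(note("expression", outdir / "expression.tsv"))
    for kind, mat in cohort.marks.items():
        mat.to_tsv(note(f"mark_{kind}", outdir / f"mark_{kind}.tsv"))
    write_intervals(note("enhancers", outdir / "enhancers.bed"),
                    cohort.enhancers)
    cohort.enhancer_acetylation.to_csv(
        note("enhancer_acetylation", outdir / "enhancer_acetylation.tsv"),
        sep="\t", index_label="enhancer_id",
    )
    write_contacts(note("contacts", outdir / "contacts.bedpe"),
                   cohort.contacts)
    write_methylation(note("methylation", outdir / "methylation.tsv"),
                      cohort.methylation)
    cohort.truth.to_gene_frame().to_csv(
        note("truth_genes", outdir / "truth_genes.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {"tad_id": [t.tad_id for t in cohort.tads],
         "is_enriched": [t.tad_id in cohort.truth.enriched_tads
                         for t in cohort.tads]}
    ).to_csv(note("truth_tads", outdir / "truth_tads.tsv"), sep="\t",
             index=False)
    pd.DataFrame(
        {"enhancer_id": [e for e, _ in cohort.enhancers],
         "is_differential": [e in cohort.truth.diff_enhancers
                             for e, _ in cohort.enhancers],
         "effect_sign": [cohort.truth.diff_enhancers.get(e, 0)
                         for e, _ in cohort.enhancers]}
    ).to_csv(note("truth_enhancers", outdir / "truth_enhancers.tsv"),
             sep="\t", index=False)
    return paths
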