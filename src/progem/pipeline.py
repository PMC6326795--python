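"""End-to-end integration: per-locus reports combining both evidence arms.

Concurrent candidates — genes found independently by the bottom-up and
top-down components — are designated the most likely causal genes. The
nearest-concurrent construction then forces exactly one gene per locus:
the concurrent candidate nearest the sentinel, or the plain nearest gene
when the concurrent set is empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .bottom_up import BottomUpEvidence, GeneEvidence, assemble_bottom_up, nearest_genes
from .model import (
    AnnotationGeneSet,
    ConsequenceRecord,
    EqtlAssociation,
    GeneModel,
    GeneRecord,
    ProxyVariant,
    SentinelVariant,
    most_severe,
)
from .top_down import TopDownEvidence, assemble_top_down, top_scoring

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CandidateGene",
    "LocusReport",
    "concurrent_genes",
    "nearest_concurrent",
    "build_locus_report",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the locus-to-gene run.

    Defaults: 3 nearest genes, ±500 kb TSS window, r² ≥ 0.8 proxies,
    ±5 kb LD-range padding, pre-filtered eQTLs (FDR 0.05 upstream) and a
    protein-coding-only gene model.
    """

    k_nearest: int = 3
    window: int = 500_000
    r2_threshold: float = 0.8
    ld_pad: int = 5000
    eqtl_mode: str = "pre-filtered"
    eqtl_threshold: float = 0.05
    biotypes: tuple[str, ...] | None = ("protein_coding",)
    include_sentinel_in_span: bool = True
    nearest_use_tss: bool = False
    match_on: str = "symbol"
    case_insensitive: bool = True

    def __post_init__(self) -> None:
        if self.k_nearest < 1 or self.window <= 0 or self.ld_pad < 0:
            raise ValueError("k_nearest, window must be positive; ld_pad >= 0")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must lie in [0, 1]")


@dataclass
class CandidateGene:
    """One candidate at one locus, with full evidence provenance."""

    sentinel_rsid: str
    gene: GeneRecord
    is_bottom_up: bool = False
    is_top_down: bool = False
    ld_overlap: bool = False
    nearest_rank: int | None = None
    nearest_distance: int | None = None
    eqtl_sentinel_tissues: set[str] = field(default_factory=set)
    eqtl_proxy_tissues: set[str] = field(default_factory=set)
    impact_sentinel: str | None = None
    impact_proxy: str | None = None
    sources: frozenset[str] = frozenset()

    @property
    def is_concurrent(self) -> bool:
        return self.is_bottom_up and self.is_top_down

    @property
    def score(self) -> int:
        return len(self.sources)


@dataclass
class LocusReport:
    """Integrated per-sentinel output."""

    sentinel: SentinelVariant
    candidates: dict[str, CandidateGene]      # gene_id -> candidate
    bottom_up: set[str]
    top_down: set[str]
    concurrent: set[str]
    top_scoring: set[str]
    nearest_concurrent: GeneRecord | None
    sentinel_impact_max: str | None = None    # most severe sentinel IMPACT at locus
    error: str | None = None


def concurrent_genes(bu: BottomUpEvidence, td: TopDownEvidence) -> set[str]:
    """Exact intersection of bottom-up and top-down candidate identities."""
    return bu.gene_ids & td.gene_ids


def nearest_concurrent(
    concurrent: set[str],
    sentinel: SentinelVariant,
    genes: GeneModel,
    use_tss: bool = False,
) -> GeneRecord:
    """One gene per locus: nearest concurrent candidate, else nearest gene.

    Ties are broken by (distance, start, gene_id), as in the nearest-gene
    ranking.
    """
    ranked = genes.nearest(sentinel.chrom, sentinel.pos, k=len(genes), use_tss=use_tss)
    if not ranked:
        raise ValueError(
            f"no genes on chromosome {sentinel.chrom} for {sentinel.rsid}"
        )
    if concurrent:
        for gene, _dist in ranked:
            if gene.gene_id in concurrent:
                return gene
        # concurrent genes may sit outside the gene model (e.g. distal eQTL
        # targets); fall back to lexicographic order for determinism
        return GeneRecord(
            gene_id=sorted(concurrent)[0],
            symbol=sorted(concurrent)[0],
            chrom=sentinel.chrom,
            start=1,
            end=1,
            strand="+",
            biotype="unknown",
        )
    return ranked[0][0]


def build_locus_report(
    sentinel: SentinelVariant,
    genes: GeneModel,
    proxies: Sequence[ProxyVariant],
    eqtls: Sequence[EqtlAssociation],
    consequences: Sequence[ConsequenceRecord],
    annotation_sets: Sequence[AnnotationGeneSet],
    config: PipelineConfig = PipelineConfig(),
) -> LocusReport:
    """Run both evidence arms for one sentinel and integrate them."""
    bu = assemble_bottom_up(
        sentinel,
        genes,
        proxies,
        eqtls,
        consequences,
        k=config.k_nearest,
        pad=config.ld_pad,
        include_sentinel_in_span=config.include_sentinel_in_span,
        nearest_use_tss=config.nearest_use_tss,
    )
    td = assemble_top_down(
        sentinel,
        genes,
        annotation_sets,
        window=config.window,
        match_on=config.match_on,
        case_insensitive=config.case_insensitive,
    )
    conc = concurrent_genes(bu, td)

    candidates: dict[str, CandidateGene] = {}
    for gene_id, ev in bu.genes.items():
        candidates[gene_id] = CandidateGene(
            sentinel_rsid=sentinel.rsid,
            gene=ev.gene,
            is_bottom_up=True,
            ld_overlap=ev.ld_overlap,
            nearest_rank=ev.nearest_rank,
            nearest_distance=ev.nearest_distance,
            eqtl_sentinel_tissues=set(ev.eqtl_sentinel_tissues),
            eqtl_proxy_tissues=set(ev.eqtl_proxy_tissues),
            impact_sentinel=ev.impact_sentinel,
            impact_proxy=ev.impact_proxy,
        )
    for gene_id in td.gene_ids:
        cand = candidates.get(gene_id)
        if cand is None:
            cand = candidates.setdefault(
                gene_id,
                CandidateGene(sentinel_rsid=sentinel.rsid, gene=td.genes[gene_id]),
            )
        cand.is_top_down = True
        cand.sources = td.sources[gene_id]

    sentinel_impacts = [
        c.impact_sentinel for c in candidates.values() if c.impact_sentinel
    ]
    return LocusReport(
        sentinel=sentinel,
        candidates=candidates,
        bottom_up=bu.gene_ids,
        top_down=td.gene_ids,
        concurrent=conc,
        top_scoring=top_scoring(td),
        nearest_concurrent=nearest_concurrent(
            conc, sentinel, genes, use_tss=config.nearest_use_tss
        ),
        sentinel_impact_max=most_severe(sentinel_impacts),
    )


def run_pipeline(
    sentinels: Sequence[SentinelVariant],
    genes: GeneModel,
    proxies: Sequence[ProxyVariant],
    eqtls: Sequence[EqtlAssociation],
    consequences: Sequence[ConsequenceRecord],
    annotation_sets: Sequence[AnnotationGeneSet],
    config: PipelineConfig = PipelineConfig(),
) -> list[LocusReport]:
    """One :class:`LocusReport` per sentinel, deterministic for fixed inputs.

    The gene model is restricted to ``config.biotypes`` before any query.
    Per-locus failures are isolated: a locus that raises is reported with an
    ``error`` set and empty candidate sets; the batch continues.
    """
    model = genes.subset(config.biotypes)
    proxies_by_sentinel: dict[str, list[ProxyVariant]] = {}
    for p in proxies:
        if p.r2 >= config.r2_threshold:
            proxies_by_sentinel.setdefault(p.sentinel_rsid, []).append(p)

    reports: list[LocusReport] = []
    for sentinel in sentinels:
        if sentinel.chrom not in model.chromosomes:
            logger.warning(
                "sentinel %s on chromosome %s absent from gene model; empty report",
                sentinel.rsid,
                sentinel.chrom,
            )
            reports.append(
                LocusReport(
                    sentinel=sentinel,
                    candidates={},
                    bottom_up=set(),
                    top_down=set(),
                    concurrent=set(),
                    top_scoring=set(),
                    nearest_concurrent=None,
                    error="chromosome absent from gene model",
                )
            )
            continue
        try:
            reports.append(
                build_locus_report(
                    sentinel,
                    model,
                    proxies_by_sentinel.get(sentinel.rsid, []),
                    eqtls,
                    consequences,
                    annotation_sets,
                    config,
                )
            )
        except Exception as exc:  # per-locus isolation: log, record, continue
            logger.exception("locus %s failed: %s", sentinel.rsid, exc)
            reports.append(
                LocusReport(
                    sentinel=sentinel,
                    candidates={},
                    bottom_up=set(),
                    top_down=set(),
                    concurrent=set(),
                    top_scoring=set(),
                    nearest_concurrent=None,
                    error=str(exc),
                )
            )
    return reports
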