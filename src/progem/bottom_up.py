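"""Variant-centric (bottom-up) candidate generation.

A gene becomes a bottom-up candidate at a locus when it satisfies at least
one of three criteria: it overlaps the sentinel's LD range, it is one of the
k nearest genes to the sentinel, or it is a significant cis-eQTL target of
the sentinel or any of its proxies. Candidates additionally carry coding
IMPACT flags (most severe consequence from the sentinel and, separately,
from any proxy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import (
    ConsequenceRecord,
    EqtlAssociation,
    GeneModel,
    GeneRecord,
    ProxyVariant,
    SentinelVariant,
    most_severe,
)

__all__ = [
    "LDRange",
    "GeneEvidence",
    "BottomUpEvidence",
    "build_ld_range",
    "nearest_genes",
    "ld_overlapping_genes",
    "eqtl_target_genes",
    "impact_flags",
    "assemble_bottom_up",
]


@dataclass(frozen=True)
class LDRange:
    """Genomic interval spanning a sentinel's proxies plus padding."""

    sentinel_rsid: str
    chrom: str
    start: int
    end: int


@dataclass
class GeneEvidence:
    """Bottom-up evidence accumulated for one candidate gene."""

    gene: GeneRecord
    ld_overlap: bool = False
    nearest_rank: int | None = None
    nearest_distance: int | None = None
    eqtl_sentinel_tissues: set[str] = field(default_factory=set)
    eqtl_proxy_tissues: set[str] = field(default_factory=set)
    impact_sentinel: str | None = None
    impact_proxy: str | None = None

    @property
    def has_eqtl(self) -> bool:
        return bool(self.eqtl_sentinel_tissues or self.eqtl_proxy_tissues)


@dataclass
class BottomUpEvidence:
    """Per-locus bottom-up candidate set with criterion flags."""

    sentinel_rsid: str
    ld_range: LDRange
    genes: dict[str, GeneEvidence]  # keyed by gene_id

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes)


def build_ld_range(
    sentinel: SentinelVariant,
    proxies: Iterable[ProxyVariant],
    pad: int = 5000,
    include_sentinel: bool = True,
) -> LDRange:
    """LD range: [leftmost, rightmost] variant position ± ``pad``, clipped at 1.

    With no proxies the range degenerates to sentinel ± pad. The sentinel
    position is included in the span by default (it is its own r²=1 proxy),
    which makes the no-proxy fallback the same rule.
    """
    positions = []
    for p in proxies:
        if p.chrom != sentinel.chrom:
            raise ValueError(
                f"proxy {p.rsid} on chromosome {p.chrom} but sentinel "
                f"{sentinel.rsid} on {sentinel.chrom}"
            )
        positions.append(p.pos)
    if include_sentinel or not positions:
        positions.append(sentinel.pos)
    return LDRange(
        sentinel_rsid=sentinel.rsid,
        chrom=sentinel.chrom,
        start=max(1, min(positions) - pad),
        end=max(positions) + pad,
    )


def nearest_genes(
    sentinel: SentinelVariant,
    genes: GeneModel,
    k: int = 3,
    use_tss: bool = False,
) -> list[tuple[GeneRecord, int, int]]:
    """The ``k`` genes nearest the sentinel as (gene, distance, rank).

    Distance is 0 inside the gene body, otherwise the smaller offset to
    either gene end (or to the strand-aware TSS when ``use_tss``). Ties are
    broken by (distance, start, gene_id). Fewer than ``k`` genes on the
    chromosome yields a shorter list; none yields an empty one.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = genes.nearest(sentinel.chrom, sentinel.pos, k=k, use_tss=use_tss)
    return [(g, d, rank) for rank, (g, d) in enumerate(hits, start=1)]


def ld_overlapping_genes(ld_range: LDRange, genes: GeneModel) -> list[GeneRecord]:
    """Genes whose closed interval intersects the closed LD range."""
    return genes.overlapping(ld_range.chrom, ld_range.start, ld_range.end)


def eqtl_target_genes(
    sentinel: SentinelVariant,
    proxies: Iterable[ProxyVariant],
    eqtls: Iterable[EqtlAssociation],
) -> dict[str, dict[str, set[str]]]:
    """cis-eQTL target genes of the sentinel and its proxies, across tissues.

    Returns ``{gene_id: {"sentinel": tissues, "proxy": tissues}}`` recording
    whether each tissue-level hit came from the sentinel itself or a proxy.
    """
    proxy_ids = {p.rsid for p in proxies}
    out: dict[str, dict[str, set[str]]] = {}
    for assoc in eqtls:
        if assoc.variant_rsid == sentinel.rsid:
            cls = "sentinel"
        elif assoc.variant_rsid in proxy_ids:
            cls = "proxy"
        else:
            continue
        rec = out.setdefault(assoc.gene_id, {"sentinel": set(), "proxy": set()})
        rec[cls].add(assoc.tissue)
    return out


def impact_flags(
    sentinel: SentinelVariant,
    proxies: Iterable[ProxyVariant],
    consequences: Iterable[ConsequenceRecord],
) -> dict[str, tuple[str | None, str | None]]:
    """Per-gene most-severe IMPACT from the sentinel and from any proxy.

    Returns ``{gene_id: (impact_sentinel, impact_proxy)}`` with ``None``
    where no consequence record exists for that class of variant.
    """
    proxy_ids = {p.rsid for p in proxies}
    sent_impacts: dict[str, list[str]] = {}
    proxy_impacts: dict[str, list[str]] = {}
    for rec in consequences:
        if rec.variant_rsid == sentinel.rsid:
            sent_impacts.setdefault(rec.gene_id, []).append(rec.impact)
        elif rec.variant_rsid in proxy_ids:
            proxy_impacts.setdefault(rec.gene_id, []).append(rec.impact)
    out: dict[str, tuple[str | None, str | None]] = {}
    for gene_id in set(sent_impacts) | set(proxy_impacts):
        out[gene_id] = (
            most_severe(sent_impacts.get(gene_id, [])),
            most_severe(proxy_impacts.get(gene_id, [])),
        )
    return out


def assemble_bottom_up(
    sentinel: SentinelVariant,
    genes: GeneModel,
    proxies: Iterable[ProxyVariant],
    eqtls: Iterable[EqtlAssociation],
    consequences: Iterable[ConsequenceRecord],
    k: int = 3,
    pad: int = 5000,
    include_sentinel_in_span: bool = True,
    nearest_use_tss: bool = False,
) -> BottomUpEvidence:
    """Union of the three bottom-up criteria with IMPACT flags attached.

    eQTL target genes absent from the gene model (e.g. filtered out by
    biotype) are still reported as candidates; their records carry no
    coordinates-derived evidence.
    """
    proxies = list(proxies)
    ld_range = build_ld_range(
        sentinel, proxies, pad=pad, include_sentinel=include_sentinel_in_span
    )
    evidence: dict[str, GeneEvidence] = {}

    def _get(gene: GeneRecord) -> GeneEvidence:
        return evidence.setdefault(gene.gene_id, GeneEvidence(gene=gene))

    for gene in ld_overlapping_genes(ld_range, genes):
        _get(gene).ld_overlap = True
    for gene, dist, rank in nearest_genes(sentinel, genes, k=k, use_tss=nearest_use_tss):
        ev = _get(gene)
        ev.nearest_rank = rank
        ev.nearest_distance = dist
    for gene_id, tissues in eqtl_target_genes(sentinel, proxies, eqtls).items():
        if gene_id in genes:
            gene = genes.get(gene_id)
        else:
            matches = genes.by_symbol(gene_id)
            gene = matches[0] if matches else GeneRecord(
                gene_id=gene_id,
                symbol=gene_id,
                chrom=sentinel.chrom,
                start=1,
                end=1,
                strand="+",
                biotype="unknown",
            )
        ev = _get(gene)
        ev.eqtl_sentinel_tissues |= tissues["sentinel"]
        ev.eqtl_proxy_tissues |= tissues["proxy"]

    flags = impact_flags(sentinel, proxies, consequences)
    for gene_id, (imp_s, imp_p) in flags.items():
        ev = evidence.get(gene_id)
        if ev is None:
            matches = genes.by_symbol(gene_id)
            if matches and matches[0].gene_id in evidence:
                ev = evidence[matches[0].gene_id]
        if ev is not None:  # flags attach to members only
            ev.impact_sentinel = imp_s
            ev.impact_proxy = imp_p

    return BottomUpEvidence(
        sentinel_rsid=sentinel.rsid, ld_range=ld_range, genes=evidence
    )
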