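"""Core data model: genes, variants, annotations and the gene-model index.

Coordinate convention is 1-based, closed intervals throughout (Ensembl GTF
dialect, GRCh37-style). Chromosome labels are normalized so that "chr1",
"Chr1" and "1" compare equal.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "IMPACT_ORDER",
    "normalize_chrom",
    "most_severe",
    "GeneRecord",
    "SentinelVariant",
    "ProxyVariant",
    "ConsequenceRecord",
    "EqtlAssociation",
    "AnnotationGeneSet",
    "ReferenceAssignment",
    "GeneModel",
]

#: VEP IMPACT classes ordered from most to least severe.
IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_IMPACT_RANK = {impact: rank for rank, impact in enumerate(IMPACT_ORDER)}


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label: strip a leading "chr", uppercase X/Y/MT.

    >>> normalize_chrom("chr1") == normalize_chrom("1")
    True
    """
    label = str(chrom).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.upper() in {"X", "Y", "MT", "M"}:
        label = "MT" if label.upper() in {"MT", "M"} else label.upper()
    return label


def most_severe(impacts: Iterable[str]) -> str | None:
    """Return the most severe IMPACT class among ``impacts`` (None if empty)."""
    best: str | None = None
    for impact in impacts:
        if impact not in _IMPACT_RANK:
            raise ValueError(f"unknown IMPACT class: {impact!r}")
        if best is None or _IMPACT_RANK[impact] < _IMPACT_RANK[best]:
            best = impact
    return best


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene on a 1-based closed interval.

    The transcription start site (TSS) is strand-aware: ``start`` on the +
    strand, ``end`` on the − strand.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def distance_to(self, pos: int) -> int:
        """Distance from ``pos`` to the gene body (0 if inside)."""
        if self.start <= pos <= self.end:
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


@dataclass(frozen=True)
class SentinelVariant:
    """QTL tag variant: the variant with the smallest association p-value."""

    rsid: str
    chrom: str
    pos: int
    trait: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass(frozen=True)
class ProxyVariant:
    """Variant in strong LD (r² above threshold) with its sentinel."""

    sentinel_rsid: str
    rsid: str
    chrom: str
    pos: int
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"{self.rsid}: r2={self.r2} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


@dataclass(frozen=True)
class ConsequenceRecord:
    """Most-severe per-gene consequence of one variant (VEP "per gene" style)."""

    variant_rsid: str
    gene_id: str
    consequence: str
    impact: str

    def __post_init__(self) -> None:
        if self.impact not in _IMPACT_RANK:
            raise ValueError(
                f"IMPACT must be one of {IMPACT_ORDER}, got {self.impact!r}"
            )


@dataclass(frozen=True)
class EqtlAssociation:
    """Significant cis-eQTL variant → target-gene association in one tissue."""

    variant_rsid: str
    gene_id: str
    tissue: str = "unspecified"


@dataclass(frozen=True)
class AnnotationGeneSet:
    """Curated domain gene list from one source (e.g. GO, KEGG, Reactome)."""

    source: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"annotation source {self.source!r} is empty")

    def contains(self, key: str) -> bool:
        return key in self.members


@dataclass(frozen=True)
class ReferenceAssignment:
    """High-confidence sentinel → causal-gene assignment used for benchmarking."""

    sentinel_rsid: str
    causal_gene: str


class GeneModel:
    """Indexed collection of :class:`GeneRecord` supporting locus queries.

    Overlap queries run on per-chromosome interval trees; nearest-gene
    queries on sorted coordinate arrays. All query intervals are closed.
    """

    def __init__(self, genes: Iterable[GeneRecord]):
        self._genes: list[GeneRecord] = list(genes)
        seen: set[str] = set()
        for g in self._genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in gene model")
            seen.add(g.gene_id)
        self._by_id = {g.gene_id: g for g in self._genes}
        self._trees: dict[str, IntervalTree] = {}
        self._sorted: dict[str, list[GeneRecord]] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._tss_sorted: dict[str, list[GeneRecord]] = {}
        self._tss_pos: dict[str, np.ndarray] = {}
        per_chrom: dict[str, list[GeneRecord]] = {}
        for g in self._genes:
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, recs in per_chrom.items():
            tree = IntervalTree()
            for g in recs:
                tree.addi(g.start, g.end + 1, g)  # half-open internally
            self._trees[chrom] = tree
            by_start = sorted(recs, key=lambda g: (g.start, g.gene_id))
            self._sorted[chrom] = by_start
            self._starts[chrom] = np.array([g.start for g in by_start])
            by_tss = sorted(recs, key=lambda g: (g.tss, g.gene_id))
            self._tss_sorted[chrom] = by_tss
            self._tss_pos[chrom] = np.array([g.tss for g in by_tss])

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def get(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def by_symbol(self, symbol: str) -> list[GeneRecord]:
        key = symbol.casefold()
        return [g for g in self._genes if g.symbol.casefold() == key]

    def subset(self, biotypes: Sequence[str] | None) -> "GeneModel":
        """Restrict to the given biotypes (None keeps everything)."""
        if biotypes is None:
            return self
        keep = set(biotypes)
        return GeneModel(g for g in self._genes if g.biotype in keep)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        """Genes whose closed interval intersects [start, end] (shared base counts)."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))

    def nearest(
        self, chrom: str, pos: int, k: int = 3, use_tss: bool = False
    ) -> list[tuple[GeneRecord, int]]:
        """The ``k`` genes nearest ``pos``, as (gene, distance) sorted by
        (distance, start, gene_id).

        Distance is to the gene body by default (0 inside), or to the
        strand-aware TSS when ``use_tss``.
        """
        chrom = normalize_chrom(chrom)
        recs = self._sorted.get(chrom, [])
        if not recs:
            return []
        starts = self._starts[chrom]
        if use_tss:
            dist = np.abs(np.array([g.tss for g in recs]) - pos)
        else:
            ends = np.array([g.end for g in recs])
            inside = (starts <= pos) & (pos <= ends)
            dist = np.minimum(np.abs(pos - starts), np.abs(pos - ends))
            dist[inside] = 0
        order = np.lexsort((starts, dist))  # ties: smaller start first;
        # recs are pre-sorted by (start, gene_id) so equal starts keep id order
        return [(recs[i], int(dist[i])) for i in order[:k]]

    def tss_within(self, chrom: str, pos: int, window: int) -> list[GeneRecord]:
        """Genes whose strand-aware TSS lies within ±window of ``pos`` (inclusive)."""
        chrom = normalize_chrom(chrom)
        recs = self._tss_sorted.get(chrom)
        if not recs:
            return []
        positions = self._tss_pos[chrom]
        lo = int(np.searchsorted(positions, pos - window, side="left"))
        hi = int(np.searchsorted(positions, pos + window, side="right"))
        return sorted(recs[lo:hi], key=lambda g: (g.start, g.gene_id))
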