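"""Synthetic locus generation for end-to-end testing and calibration.

Two generators live here:

* :func:`simulate_dataset` builds a complete, internally consistent random
  dataset — gene model, sentinels, LD proxies, per-gene consequences,
  cis-eQTL associations, domain annotation lists and a truth ledger of
  planted causal genes — under a seeded :class:`SimulationConfig`.
* :func:`table2_fixtures` builds three hand-laid loci whose candidate sets,
  top-down scores and concurrent genes match a published worked example for
  the sentinels rs1801133, rs1005390 and rs766420. Coordinates are
  synthetic but consistent with the printed nearest/overlap relationships.

Simulated proxies are positional stand-ins: positions are sampled around
the sentinel and r² values are stamped, not derived from genotypes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    AnnotationGeneSet,
    ConsequenceRecord,
    EqtlAssociation,
    GeneModel,
    GeneRecord,
    ProxyVariant,
    ReferenceAssignment,
    SentinelVariant,
)

__all__ = [
    "SimulationConfig",
    "LocusTruth",
    "LocusDataset",
    "simulate_dataset",
    "table2_fixtures",
]

ANNOTATION_SOURCES = ("GO", "KEGG", "MGI", "Orphanet", "Reactome")
TISSUES = ("liver", "whole_blood", "adipose", "muscle", "brain")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic locus generator.

    Defaults emulate a metabolite-QTL screen: ~20 candidate-bearing genes
    within a megabase of each sentinel, a causal gene that is usually but
    not always the nearest gene, occasional coding (moderate-impact)
    sentinels, frequent cis-eQTL support and domain-database membership
    spread over 0–5 sources.
    """

    n_chromosomes: int = 4
    genes_per_chromosome: int = 60
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    gap_range: tuple[int, int] = (10_000, 60_000)
    pseudogene_fraction: float = 0.05
    n_loci: int = 50
    p_causal_is_nearest: float = 0.7
    p_causal_coding: float = 0.2
    p_causal_eqtl: float = 0.5
    # probability that the planted causal gene appears in exactly k of the
    # five domain databases, k = 0..5
    causal_db_count_probs: tuple[float, ...] = (0.15, 0.25, 0.25, 0.20, 0.10, 0.05)
    p_decoy_eqtl: float = 0.04
    p_decoy_in_database: float = 0.04  # per gene per source
    n_proxies_range: tuple[int, int] = (0, 20)
    proxy_span: int = 25_000
    n_out_of_window: int = 0
    window: int = 500_000
    seed: int = 0

    def validate(self) -> None:
        for p in (
            self.p_causal_is_nearest,
            self.p_causal_coding,
            self.p_causal_eqtl,
            self.p_decoy_eqtl,
            self.p_decoy_in_database,
            self.pseudogene_fraction,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.causal_db_count_probs) - 1.0) > 1e-9 or len(
            self.causal_db_count_probs
        ) != 6:
            raise ValueError("causal_db_count_probs must be 6 values summing to 1")
        if self.n_loci > self.n_chromosomes * self.genes_per_chromosome // 3:
            raise ValueError(
                "too many loci for the configured gene model: causal genes "
                "are planted at least three gene positions apart"
            )
        reach = self.gap_range[1] + self.gene_length_range[1]
        if self.window < reach:
            raise ValueError(
                f"window ({self.window} bp) smaller than the maximal "
                f"gene-to-gene reach ({reach} bp): planted causal genes could "
                "fall outside the top-down window even when configured in-window"
            )


@dataclass(frozen=True)
class LocusTruth:
    """Realized evidence profile of one planted locus."""

    sentinel_rsid: str
    causal_gene_id: str
    causal_symbol: str
    is_nearest: bool
    coding: bool
    eqtl: bool
    n_databases: int
    out_of_window: bool


@dataclass
class LocusDataset:
    """A complete in-memory input bundle plus (optionally) planted truth."""

    genes: GeneModel
    sentinels: list[SentinelVariant]
    proxies: list[ProxyVariant]
    consequences: list[ConsequenceRecord]
    eqtls: list[EqtlAssociation]
    annotation_sets: list[AnnotationGeneSet]
    references: list[ReferenceAssignment]
    truth: list[LocusTruth] = field(default_factory=list)

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        """Emit the bundle in the exact dialects the readers consume."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {}

        gtf = os.path.join(out_dir, "genes.gtf")
        with open(gtf, "w") as fh:
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
                attrs = (
                    f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
        paths["gtf"] = gtf

        def _emit(name, rows, columns):
            path = os.path.join(out_dir, name)
            pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
            paths[name.split(".")[0]] = path

        _emit(
            "sentinels.tsv",
            [(s.rsid, s.chrom, s.pos, s.trait) for s in self.sentinels],
            ["rsid", "chrom", "pos", "trait"],
        )
        _emit(
            "proxies.tsv",
            [(p.sentinel_rsid, p.rsid, p.chrom, p.pos, p.r2) for p in self.proxies],
            ["sentinel_rsid", "rsid", "chrom", "pos", "r2"],
        )
        _emit(
            "consequences.tsv",
            [
                (c.variant_rsid, c.gene_id, c.consequence, c.impact)
                for c in self.consequences
            ],
            ["variant_rsid", "gene_id", "consequence", "impact"],
        )
        _emit(
            "eqtls.tsv",
            [(e.variant_rsid, e.gene_id, e.tissue) for e in self.eqtls],
            ["variant_rsid", "gene_id", "tissue"],
        )
        _emit(
            "annotation_sets.tsv",
            [
                (s.source, m)
                for s in self.annotation_sets
                for m in sorted(s.members)
            ],
            ["source", "gene"],
        )
        _emit(
            "reference.tsv",
            [(r.sentinel_rsid, r.causal_gene) for r in self.references],
            ["sentinel_rsid", "causal_gene"],
        )
        return paths


def _sample_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    for c in range(1, cfg.n_chromosomes + 1):
        pos = 1
        for i in range(cfg.genes_per_chromosome):
            gap = int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1))
            length = int(
                rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1)
            )
            start = pos + gap
            biotype = (
                "pseudogene"
                if rng.random() < cfg.pseudogene_fraction
                else "protein_coding"
            )
            genes.append(
                GeneRecord(
                    gene_id=f"SIMG{c:02d}{i:04d}",
                    symbol=f"GENE{c}_{i:04d}",
                    chrom=str(c),
                    start=start,
                    end=start + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype=biotype,
                )
            )
            pos = start + length
    return genes


def simulate_dataset(
    config: SimulationConfig, out_dir: str | os.PathLike | None = None
) -> LocusDataset:
    """Generate a seeded synthetic dataset with planted causal genes.

    Each locus plants one protein-coding causal gene and realizes an
    evidence profile drawn from the configured probabilities: whether the
    sentinel lands inside the causal gene (making it the nearest gene),
    whether the sentinel is a coding (moderate-impact) variant of it,
    whether it is a cis-eQTL target, and in how many domain databases the
    gene appears. Decoy eQTL targets are drawn only from within ±1 Mb of
    the sentinel (the cis definition); decoy database membership is sampled
    independently per gene and source. The first ``n_out_of_window`` loci
    plant their causal gene farther than ``window`` from the sentinel,
    reproducing the long-range failure mode. Identical config (including
    seed) yields byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _sample_genes(config, rng)
    model = GeneModel(genes)
    coding_genes = [g for g in genes if g.biotype == "protein_coding"]
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in coding_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for recs in by_chrom.values():
        recs.sort(key=lambda g: g.start)

    # plant causal genes at least 3 gene positions apart on a chromosome so
    # one locus's candidates cannot swallow another locus's planted gene
    eligible: list[GeneRecord] = []
    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        offset = int(rng.integers(3))
        eligible.extend(recs[offset::3])
    if len(eligible) < config.n_loci:
        raise ValueError(
            "could not place the requested number of loci with the required "
            "causal-gene spacing; enlarge the gene model"
        )
    picked = rng.permutation(len(eligible))[: config.n_loci]
    causal_genes = [eligible[int(i)] for i in picked]
    sentinels: list[SentinelVariant] = []
    proxies: list[ProxyVariant] = []
    consequences: list[ConsequenceRecord] = []
    eqtls: list[EqtlAssociation] = []
    references: list[ReferenceAssignment] = []
    truth: list[LocusTruth] = []
    db_members: dict[str, set[str]] = {s: set() for s in ANNOTATION_SOURCES}

    for li, causal in enumerate(causal_genes):
        chrom_genes = by_chrom[causal.chrom]
        ci = chrom_genes.index(causal)
        rsid = f"rs{li + 1:05d}"
        out_of_window = li < config.n_out_of_window
        coding = (not out_of_window) and rng.random() < config.p_causal_coding
        eqtl_flag = (not out_of_window) and rng.random() < config.p_causal_eqtl
        n_db = int(rng.choice(6, p=config.causal_db_count_probs))

        if out_of_window:
            # anchor the sentinel inside a gene > window away on the same chrom
            far = [
                g
                for g in chrom_genes
                if abs(g.start - causal.tss) > config.window + 100_000
            ]
            if not far:
                raise ValueError(
                    "cannot plant an out-of-window locus: chromosome too short "
                    "for the configured window"
                )
            host = far[int(rng.integers(len(far)))]
            is_nearest = False
        elif rng.random() < config.p_causal_is_nearest:
            host = causal
            is_nearest = True
        else:
            neighbors = [
                chrom_genes[j]
                for j in (ci - 1, ci + 1)
                if 0 <= j < len(chrom_genes)
            ]
            host = neighbors[int(rng.integers(len(neighbors)))]
            is_nearest = False
        pos = int(rng.integers(host.start, host.end + 1))
        sentinels.append(
            SentinelVariant(rsid=rsid, chrom=causal.chrom, pos=pos, trait=f"metab_{li}")
        )
        references.append(
            ReferenceAssignment(sentinel_rsid=rsid, causal_gene=causal.symbol)
        )

        # the sentinel's host gene gets an intronic record; a coding causal
        # sentinel gets a missense record
        consequences.append(
            ConsequenceRecord(
                variant_rsid=rsid,
                gene_id=host.gene_id,
                consequence="intron_variant",
                impact="MODIFIER",
            )
        )
        if coding:
            consequences.append(
                ConsequenceRecord(
                    variant_rsid=rsid,
                    gene_id=causal.gene_id,
                    consequence="missense_variant",
                    impact="MODERATE",
                )
            )

        n_prox = int(
            rng.integers(config.n_proxies_range[0], config.n_proxies_range[1] + 1)
        )
        locus_proxies = []
        for j in range(n_prox):
            offset = int(rng.integers(-config.proxy_span, config.proxy_span + 1))
            locus_proxies.append(
                ProxyVariant(
                    sentinel_rsid=rsid,
                    rsid=f"{rsid}_p{j}",
                    chrom=causal.chrom,
                    pos=max(1, pos + offset),
                    r2=float(np.round(rng.uniform(0.8, 1.0), 4)),
                )
            )
        # two sub-threshold rows exercise the r2 filter
        for j in range(2):
            locus_proxies.append(
                ProxyVariant(
                    sentinel_rsid=rsid,
                    rsid=f"{rsid}_w{j}",
                    chrom=causal.chrom,
                    pos=max(1, pos + int(rng.integers(-config.proxy_span, config.proxy_span + 1))),
                    r2=float(np.round(rng.uniform(0.3, 0.79), 4)),
                )
            )
        proxies.extend(locus_proxies)

        if eqtl_flag:
            n_tissues = int(rng.integers(1, 4))
            for t in rng.choice(len(TISSUES), size=n_tissues, replace=False):
                eqtls.append(
                    EqtlAssociation(
                        variant_rsid=rsid,
                        gene_id=causal.gene_id,
                        tissue=TISSUES[int(t)],
                    )
                )
        # decoy eQTL targets, cis only (±1 Mb)
        for g in chrom_genes:
            if g.gene_id != causal.gene_id and abs(g.tss - pos) <= 1_000_000:
                if rng.random() < config.p_decoy_eqtl:
                    src = rsid
                    strong = [p for p in locus_proxies if p.r2 >= 0.8]
                    if strong and rng.random() < 0.5:
                        src = strong[int(rng.integers(len(strong)))].rsid
                    eqtls.append(
                        EqtlAssociation(
                            variant_rsid=src,
                            gene_id=g.gene_id,
                            tissue=TISSUES[int(rng.integers(len(TISSUES)))],
                        )
                    )

        if n_db > 0:
            for s in rng.choice(len(ANNOTATION_SOURCES), size=n_db, replace=False):
                db_members[ANNOTATION_SOURCES[int(s)]].add(causal.symbol.casefold())

        truth.append(
            LocusTruth(
                sentinel_rsid=rsid,
                causal_gene_id=causal.gene_id,
                causal_symbol=causal.symbol,
                is_nearest=is_nearest,
                coding=coding,
                eqtl=eqtl_flag,
                n_databases=n_db,
                out_of_window=out_of_window,
            )
        )

    # decoy database membership, independent per gene and source
    causal_ids = {t.causal_gene_id for t in truth}
    for g in genes:
        if g.gene_id in causal_ids:
            continue
        for source in ANNOTATION_SOURCES:
            if rng.random() < config.p_decoy_in_database:
                db_members[source].add(g.symbol.casefold())

    # every source must be non-empty to load; seed a placeholder if needed
    for source in ANNOTATION_SOURCES:
        if not db_members[source]:
            db_members[source].add("placeholder_gene")

    annotation_sets = [
        AnnotationGeneSet(source=s, members=frozenset(db_members[s]))
        for s in ANNOTATION_SOURCES
    ]
    dataset = LocusDataset(
        genes=model,
        sentinels=sentinels,
        proxies=proxies,
        consequences=consequences,
        eqtls=eqtls,
        annotation_sets=annotation_sets,
        references=references,
        truth=truth,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset


# ---------------------------------------------------------------------------
# Worked-example fixtures (synthetic coordinates, published relationships)

_T2_GENES: list[tuple[str, str, int, int]] = [
    # chr1 locus: sentinel rs1801133 at 1:11,856,378 (no proxies)
    ("MTHFR", "1", 11_845_000, 11_866_000),
    ("C1orf167", "1", 11_880_000, 11_890_000),
    ("CLCN6", "1", 11_900_000, 11_920_000),
    ("NPPA", "1", 12_000_000, 12_005_000),
    ("MFN2", "1", 12_040_000, 12_070_000),
    ("PTCHD2", "1", 12_100_000, 12_110_000),
    ("MAD2L2", "1", 12_200_000, 12_210_000),
    # chr7 locus: sentinel rs1005390 at 7:150,543,721 (26 proxies)
    ("AOC1", "7", 150_520_000, 150_560_000),
    ("TMEM179A", "7", 150_570_000, 150_580_000),
    ("TMEM179B", "7", 150_600_000, 150_610_000),
    ("SMARCD3", "7", 150_650_000, 150_660_000),
    ("NOS3", "7", 150_690_000, 150_710_000),
    ("CHPF2", "7", 150_750_000, 150_760_000),
    # chrX locus: sentinel rs766420 at X:153,554,404 (no proxies)
    ("TKTL1", "X", 153_550_000, 153_560_000),
    ("FLNA", "X", 153_576_000, 153_603_000),
    ("TEX28", "X", 153_610_000, 153_620_000),
]

_T2_X_BLOCK = [
    "BRCC3", "DNASE1L1", "F8A1", "FAM3A", "FAM50A", "GDI1", "IRAK1",
    "LAGE3", "PLXNA3", "RPL10", "TAZ", "TMEM187", "G6PD", "IDH3G",
    "MECP2", "MPP1", "RENBP", "ATP6AP1", "DKC1", "IKBKG", "HCFC1", "SSR4",
]

_T2_EQTL_X = [
    "BRCC3", "DNASE1L1", "F8A1", "FAM3A", "FAM50A", "GDI1", "IRAK1",
    "LAGE3", "PLXNA3", "RPL10", "TAZ", "TMEM187",
]

_T2_SOURCES = {
    "GO": [
        "MTHFR", "NPPA", "PTCHD2",
        "AOC1", "SMARCD3",
        "DNASE1L1", "G6PD", "IDH3G", "MECP2", "MPP1", "RENBP", "TKTL1",
    ],
    "KEGG": ["MTHFR", "AOC1", "CHPF2", "NOS3", "ATP6AP1", "G6PD", "IDH3G", "TKTL1"],
    "MGI": ["MAD2L2", "NPPA", "NOS3", "DKC1", "IKBKG"],
    "Orphanet": ["MTHFR", "HCFC1", "SSR4", "TAZ"],
    "Reactome": [
        "MTHFR",
        "AOC1", "CHPF2", "NOS3", "SMARCD3",
        "G6PD", "IDH3G", "RPL10", "TAZ",
    ],
}


def table2_fixtures() -> LocusDataset:
    """Three hand-laid loci reproducing a published worked example.

    Sentinels rs1801133 (chr1, homocysteine; causal MTHFR), rs1005390
    (chr7, an acetamide metabolite; causal AOC1) and rs766420 (chrX,
    bilirubin; causal G6PD, which bottom-up evidence alone does not reach).
    Gene coordinates are synthetic but preserve every printed nearest-gene
    ordering, LD-range overlap, eQTL target list and per-database
    membership, so the integrated output matches the published cells.
    """
    gene_tuples = list(_T2_GENES)
    for i, symbol in enumerate(_T2_X_BLOCK):
        start = 153_640_000 + i * 15_000
        gene_tuples.append((symbol, "X", start, start + 8_000))
    genes = [
        GeneRecord(
            gene_id=sym, symbol=sym, chrom=chrom, start=start, end=end,
            strand="+", biotype="protein_coding",
        )
        for sym, chrom, start, end in gene_tuples
    ]
    sentinels = [
        SentinelVariant("rs1801133", "1", 11_856_378, trait="homocysteine"),
        SentinelVariant(
            "rs1005390", "7", 150_543_721,
            trait="X-03056 N-[3-(2-oxopyrrolidin-1-yl)propyl]acetamide",
        ),
        SentinelVariant("rs766420", "X", 153_554_404, trait="bilirubin"),
    ]
    proxies = [
        ProxyVariant(
            sentinel_rsid="rs1005390",
            rsid=f"rs1005390_p{i}",
            chrom="7",
            pos=150_530_000 + i * 800,
            r2=round(0.8 + 0.005 * i, 3),
        )
        for i in range(26)
    ]
    consequences = [
        ConsequenceRecord("rs1801133", "MTHFR", "missense_variant", "MODERATE"),
        ConsequenceRecord("rs1005390", "AOC1", "intron_variant", "MODIFIER"),
        ConsequenceRecord("rs766420", "TKTL1", "intron_variant", "MODIFIER"),
    ]
    eqtls = [
        EqtlAssociation("rs1801133", "MFN2", "whole_blood"),
        EqtlAssociation("rs1801133", "MTHFR", "liver"),
        EqtlAssociation("rs1005390", "AOC1", "liver"),
        EqtlAssociation("rs1005390_p0", "TMEM179A", "adipose"),
        EqtlAssociation("rs1005390_p1", "TMEM179B", "muscle"),
    ] + [EqtlAssociation("rs766420", g, "whole_blood") for g in _T2_EQTL_X]
    annotation_sets = [
        AnnotationGeneSet(
            source=s, members=frozenset(m.casefold() for m in members)
        )
        for s, members in _T2_SOURCES.items()
    ]
    references = [
        ReferenceAssignment("rs1801133", "MTHFR"),
        ReferenceAssignment("rs1005390", "AOC1"),
        ReferenceAssignment("rs766420", "G6PD"),
    ]
    return LocusDataset(
        genes=GeneModel(genes),
        sentinels=sentinels,
        proxies=proxies,
        consequences=consequences,
        eqtls=eqtls,
        annotation_sets=annotation_sets,
        references=references,
    )
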