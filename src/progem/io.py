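"""Readers and writers for the standard-format inputs and per-locus outputs.

All tabular inputs are tab-delimited with a header row; the gene model is an
Ensembl-dialect GTF. Every reader transparently accepts gzip-compressed
files (pandas/gffutils handle ``.gz`` by extension).
"""

from __future__ import annotations

import logging
import os
import warnings
from typing import Iterable, Mapping, Sequence

import gffutils
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
    most_severe,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_model",
    "read_sentinels",
    "read_proxies",
    "read_consequences",
    "read_eqtls",
    "read_annotation_sets",
    "read_reference",
    "write_locus_reports",
    "read_locus_reports",
    "DEFAULT_BIOTYPES",
]

#: Default biotype filter: protein-coding genes only.
DEFAULT_BIOTYPES: tuple[str, ...] = ("protein_coding",)

MAX_ANNOTATION_SOURCES = 5


def _create_gtf_db(path):
    return gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=False,
        disable_infer_transcripts=True,
    )


def _read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, **kwargs)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_gene_model(
    path: str | os.PathLike,
    biotype_filter: Sequence[str] | None = DEFAULT_BIOTYPES,
) -> GeneModel:
    """Read a GTF gene model into a :class:`GeneModel`.

    Gene-level features are used directly; if the file carries only
    transcripts, gene records are inferred by gffutils. ``biotype_filter``
    keeps only the listed biotypes (default protein_coding); pass ``None``
    to keep every gene.
    """
    try:
        with warnings.catch_warnings():
            # gene features may be present or inferred from transcripts; the
            # speed hint for the former case is irrelevant at our input sizes
            warnings.filterwarnings("ignore", message=".*gene feature.*")
            db = _create_gtf_db(path)
    except Exception as exc:  # gffutils reports the offending line
        raise ValueError(f"{path}: failed to parse GTF: {exc}") from exc
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        gene_id = (attrs.get("gene_id") or [feat.id])[0]
        symbol = (attrs.get("gene_name") or attrs.get("gene_id") or [feat.id])[0]
        biotype = (
            attrs.get("gene_biotype") or attrs.get("gene_type") or ["unknown"]
        )[0]
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                symbol=symbol,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                biotype=biotype,
            )
        )
    if biotype_filter is not None:
        keep = set(biotype_filter)
        genes = [g for g in genes if g.biotype in keep]
    if not genes:
        raise ValueError(
            f"{path}: no gene features remain after biotype filter "
            f"{sorted(biotype_filter) if biotype_filter else None}"
        )
    return GeneModel(genes)


def read_sentinels(path) -> list[SentinelVariant]:
    """Read the sentinel-variant table (columns rsid, chrom, pos[, trait])."""
    df = _read_table(path)
    _require_columns(df, ["rsid", "chrom", "pos"], path)
    if df["rsid"].duplicated().any():
        dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
        raise ValueError(f"{path}: duplicate sentinel rsid(s): {dups}")
    trait = df["trait"] if "trait" in df.columns else [""] * len(df)
    return [
        SentinelVariant(rsid=r, chrom=c, pos=int(p), trait=t or "")
        for r, c, p, t in zip(df["rsid"], df["chrom"], df["pos"], trait)
    ]


def read_proxies(path, r2_threshold: float = 0.8) -> list[ProxyVariant]:
    """Read the LD-proxy table, keeping rows with r² ≥ ``r2_threshold``.

    The threshold comparison is inclusive. Proxies naming a sentinel absent
    from the sentinel table are kept here and dropped at join time.
    """
    df = _read_table(path)
    if df.empty:
        return []
    _require_columns(df, ["sentinel_rsid", "rsid", "chrom", "pos", "r2"], path)
    r2 = df["r2"].astype(float)
    if ((r2 < 0) | (r2 > 1)).any():
        bad = df.loc[(r2 < 0) | (r2 > 1), "rsid"].tolist()
        raise ValueError(f"{path}: r2 outside [0, 1] for {bad}")
    keep = r2 >= r2_threshold
    return [
        ProxyVariant(
            sentinel_rsid=row.sentinel_rsid,
            rsid=row.rsid,
            chrom=row.chrom,
            pos=int(row.pos),
            r2=float(row.r2),
        )
        for row in df[keep].itertuples(index=False)
    ]


def read_consequences(path) -> list[ConsequenceRecord]:
    """Read the per-gene variant-consequence table (VEP-style).

    When a (variant, gene) pair appears more than once, only the record with
    the most severe IMPACT (HIGH > MODERATE > LOW > MODIFIER) is kept.
    """
    df = _read_table(path)
    if df.empty:
        return []
    _require_columns(df, ["variant_rsid", "gene_id", "consequence", "impact"], path)
    best: dict[tuple[str, str], ConsequenceRecord] = {}
    for row in df.itertuples(index=False):
        rec = ConsequenceRecord(
            variant_rsid=row.variant_rsid,
            gene_id=row.gene_id,
            consequence=row.consequence,
            impact=row.impact,
        )
        key = (rec.variant_rsid, rec.gene_id)
        prev = best.get(key)
        if prev is None or most_severe([prev.impact, rec.impact]) == rec.impact:
            # on equal severity the first record wins
            if prev is not None and prev.impact == rec.impact:
                continue
            best[key] = rec
    return list(best.values())


def read_eqtls(
    path, mode: str = "pre-filtered", p_threshold: float = 0.05
) -> list[EqtlAssociation]:
    """Read significant cis-eQTL variant–gene–tissue associations.

    ``mode="pre-filtered"`` (default) treats every row as significant, as in
    GTEx significant-pairs exports filtered upstream at FDR 0.05.
    ``mode="p-threshold"`` keeps rows with ``p_value`` ≤ ``p_threshold``.
    """
    if mode not in {"pre-filtered", "p-threshold"}:
        raise ValueError(f"unknown eQTL mode {mode!r}")
    df = _read_table(path)
    if df.empty:
        return []
    _require_columns(df, ["variant_rsid", "gene_id"], path)
    if "tissue" not in df.columns:
        logger.warning("%s: no tissue column; tissue set to 'unspecified'", path)
        df["tissue"] = "unspecified"
    if mode == "p-threshold":
        _require_columns(df, ["p_value"], path)
        df = df[df["p_value"].astype(float) <= p_threshold]
    return [
        EqtlAssociation(
            variant_rsid=row.variant_rsid,
            gene_id=row.gene_id,
            tissue=row.tissue or "unspecified",
        )
        for row in df.itertuples(index=False)
    ]


def read_annotation_sets(
    path, case_insensitive: bool = True
) -> list[AnnotationGeneSet]:
    """Read domain annotation gene lists from a two-column source/gene table.

    Between 1 and 5 sources are allowed (the top-down score is bounded at 5).
    Member keys are normalized case-insensitively by default so that curated
    symbol lists match regardless of capitalization.
    """
    df = _read_table(path)
    _require_columns(df, ["source", "gene"], path)
    sets: list[AnnotationGeneSet] = []
    for source, group in df.groupby("source", sort=True):
        members = {
            (g.casefold() if case_insensitive else g)
            for g in group["gene"].dropna()
            if str(g).strip()
        }
        if not members:
            raise ValueError(f"{path}: annotation source {source!r} is empty")
        sets.append(AnnotationGeneSet(source=str(source), members=frozenset(members)))
    if not sets:
        raise ValueError(f"{path}: no annotation sources found")
    if len(sets) > MAX_ANNOTATION_SOURCES:
        raise ValueError(
            f"{path}: {len(sets)} annotation sources exceed the maximum of "
            f"{MAX_ANNOTATION_SOURCES}"
        )
    return sets


def read_reference(path) -> list[ReferenceAssignment]:
    """Read the reference causal-gene table (columns sentinel_rsid, causal_gene)."""
    df = _read_table(path)
    _require_columns(df, ["sentinel_rsid", "causal_gene"], path)
    if df.empty:
        raise ValueError(f"{path}: reference assignment file is empty")
    if df["sentinel_rsid"].duplicated().any():
        dups = df.loc[df["sentinel_rsid"].duplicated(), "sentinel_rsid"].tolist()
        raise ValueError(f"{path}: duplicate reference assignment(s): {dups}")
    return [
        ReferenceAssignment(sentinel_rsid=row.sentinel_rsid, causal_gene=row.causal_gene)
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Per-locus report output

_BU_COLUMNS = [
    "sentinel_rsid",
    "gene_id",
    "symbol",
    "ld_overlap",
    "nearest_rank",
    "eqtl_sentinel_tissues",
    "eqtl_proxy_tissues",
    "impact_sentinel",
    "impact_proxy",
]
_TD_COLUMNS = ["sentinel_rsid", "gene_id", "symbol", "sources", "score"]
_CC_COLUMNS = ["sentinel_rsid", "gene_id", "symbol", "score", "nearest_rank"]
_NC_COLUMNS = ["sentinel_rsid", "gene_id", "symbol", "is_concurrent"]


def write_locus_reports(reports: Iterable, out_dir: str | os.PathLike) -> dict:
    """Write per-locus results as four tab-delimited tables.

    ``bottom_up.tsv``, ``top_down.tsv``, ``concurrent.tsv`` and
    ``nearest_concurrent.tsv`` are written under ``out_dir`` with fixed
    headers. Returns the mapping of table name to path.
    """
    os.makedirs(out_dir, exist_ok=True)
    bu_rows, td_rows, cc_rows, nc_rows = [], [], [], []
    for report in reports:
        sid = report.sentinel.rsid
        for cand in sorted(report.candidates.values(), key=lambda c: c.gene.gene_id):
            g = cand.gene
            if cand.is_bottom_up:
                bu_rows.append(
                    {
                        "sentinel_rsid": sid,
                        "gene_id": g.gene_id,
                        "symbol": g.symbol,
                        "ld_overlap": cand.ld_overlap,
                        "nearest_rank": cand.nearest_rank if cand.nearest_rank else "",
                        "eqtl_sentinel_tissues": ";".join(sorted(cand.eqtl_sentinel_tissues)),
                        "eqtl_proxy_tissues": ";".join(sorted(cand.eqtl_proxy_tissues)),
                        "impact_sentinel": cand.impact_sentinel or "",
                        "impact_proxy": cand.impact_proxy or "",
                    }
                )
            if cand.is_top_down:
                td_rows.append(
                    {
                        "sentinel_rsid": sid,
                        "gene_id": g.gene_id,
                        "symbol": g.symbol,
                        "sources": ";".join(sorted(cand.sources)),
                        "score": cand.score,
                    }
                )
            if cand.is_concurrent:
                cc_rows.append(
                    {
                        "sentinel_rsid": sid,
                        "gene_id": g.gene_id,
                        "symbol": g.symbol,
                        "score": cand.score,
                        "nearest_rank": cand.nearest_rank if cand.nearest_rank else "",
                    }
                )
        if report.nearest_concurrent is not None:
            nc_rows.append(
                {
                    "sentinel_rsid": sid,
                    "gene_id": report.nearest_concurrent.gene_id,
                    "symbol": report.nearest_concurrent.symbol,
                    "is_concurrent": bool(report.concurrent),
                }
            )
    paths = {}
    for name, rows, cols in [
        ("bottom_up", bu_rows, _BU_COLUMNS),
        ("top_down", td_rows, _TD_COLUMNS),
        ("concurrent", cc_rows, _CC_COLUMNS),
        ("nearest_concurrent", nc_rows, _NC_COLUMNS),
    ]:
        path = os.path.join(out_dir, f"{name}.tsv")
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def read_locus_reports(out_dir: str | os.PathLike) -> dict[str, dict[str, set[str]]]:
    """Re-read written report tables as per-locus candidate gene-id sets.

    Returns ``{"bottom_up": {sentinel: {gene_id, ...}}, "top_down": ...,
    "concurrent": ..., "nearest_concurrent": ...}`` — the set content used
    by round-trip checks and the benchmark CLI.
    """
    out: dict[str, dict[str, set[str]]] = {}
    for name in ("bottom_up", "top_down", "concurrent", "nearest_concurrent"):
        df = _read_table(os.path.join(out_dir, f"{name}.tsv"))
        per_locus: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            per_locus.setdefault(row.sentinel_rsid, set()).add(row.gene_id)
        out[name] = per_locus
    return out
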