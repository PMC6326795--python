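"""Benchmarking against reference causal-gene assignments.

Per-locus TP/FP/FN classification (one reference gene per locus), the
sensitivity percentage, two specificity variants differing in how true
negatives are counted, and criterion-stratified enrichment via Fisher's
exact test with Bonferroni correction.

Sensitivity = (100 / n) × TP over n benchmarked loci.
Specificity = TN / (TN + FP), where TN = ΣLG − (TP + FP) − FN counts local
protein-coding genes (mode ``lg``), or TN = ΣPG − (TP + FP) − FN counts all
candidates produced at the loci (mode ``pg``, used to compare components).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from scipy import stats

from .model import GeneModel, ReferenceAssignment
from .pipeline import LocusReport

__all__ = [
    "BenchmarkSummary",
    "EnrichmentResult",
    "classify_locus",
    "sensitivity",
    "specificity",
    "criterion_sets",
    "standard_criteria",
    "fisher_enrichment",
    "benchmark_run",
]


@dataclass(frozen=True)
class BenchmarkSummary:
    """Aggregate performance of one candidate-set definition."""

    name: str
    n: int
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float  # percentage in [0, 100]
    specificity: float | None  # fraction in [0, 1]; None when TN + FP == 0
    mode: str  # "lg" (local genes) or "pg" (pipeline candidates)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher's-exact enrichment of one criterion against the background."""

    criterion: str
    table: tuple[tuple[int, int], tuple[int, int]]  # [[crit&TP, crit&FP], [bg&TP, bg&FP]]
    odds_ratio: float  # conditional-MLE estimate; nan when undefined
    ci95: tuple[float, float]
    p_raw: float
    p_bonferroni: float
    n_tests: int
    degenerate: bool  # a zero margin: OR undefined, p forced to 1


def classify_locus(candidates: set[str], reference: str) -> tuple[int, int, int]:
    """(tp, fp, fn) for one locus given its candidate keys and reference key.

    The reference gene captured → (1, |candidates| − 1, 0); missed →
    (0, |candidates|, 1). Keys must be pre-normalized to a common
    vocabulary (gene ids or casefolded symbols).
    """
    if reference in candidates:
        return 1, len(candidates) - 1, 0
    return 0, len(candidates), 1


def sensitivity(n: int, tp: int) -> float:
    """Percentage of loci whose reference causal gene was captured."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= tp <= n):
        raise ValueError("tp must lie in [0, n]")
    return (100.0 / n) * tp


def specificity(
    tp: int, fp: int, fn: int, total_genes: int, mode: str = "lg"
) -> float | None:
    """TN/(TN+FP) with TN = total − (TP + FP) − FN.

    ``total_genes`` is ΣLG (local protein-coding genes across loci) in mode
    ``lg`` or ΣPG (all candidates across loci) in mode ``pg``. Returns None
    when TN + FP = 0 (undefined).
    """
    if mode not in {"lg", "pg"}:
        raise ValueError(f"mode must be 'lg' or 'pg', got {mode!r}")
    if total_genes < tp + fp + fn:
        raise ValueError("total_genes must be >= TP + FP + FN")
    tn = total_genes - (tp + fp) - fn
    if tn + fp == 0:
        return None
    return tn / (tn + fp)


# ---------------------------------------------------------------------------
# Criterion stratification

Instance = tuple[str, str]  # (sentinel_rsid, gene_id)


def _criterion_predicate(label: str) -> Callable:
    """Resolve a criterion label to a per-candidate predicate."""
    fixed: dict[str, Callable] = {
        "bottom_up": lambda c: c.is_bottom_up,
        "top_down": lambda c: c.is_top_down,
        "concurrent": lambda c: c.is_concurrent,
        "nearest": lambda c: c.nearest_rank == 1,
        "three_nearest": lambda c: c.nearest_rank is not None,
        "ld_overlap": lambda c: c.ld_overlap,
        "eqtl": lambda c: bool(c.eqtl_sentinel_tissues or c.eqtl_proxy_tissues),
        "eqtl_sentinel": lambda c: bool(c.eqtl_sentinel_tissues),
        "eqtl_proxy": lambda c: bool(c.eqtl_proxy_tissues),
    }
    if label in fixed:
        return fixed[label]
    if label.startswith("eqtl_sentinel:"):
        tissue = label.split(":", 1)[1]
        return lambda c: tissue in c.eqtl_sentinel_tissues
    if label.startswith("eqtl_proxy:"):
        tissue = label.split(":", 1)[1]
        return lambda c: tissue in c.eqtl_proxy_tissues
    if label.startswith("impact_sentinel:"):
        impact = label.split(":", 1)[1]
        return lambda c: c.impact_sentinel == impact
    if label.startswith("impact_proxy:"):
        impact = label.split(":", 1)[1]
        return lambda c: c.impact_proxy == impact
    if label.startswith("td_source:"):
        source = label.split(":", 1)[1]
        return lambda c: source in c.sources
    if label.startswith("td_score:"):
        score = int(label.split(":", 1)[1])
        return lambda c: c.score == score
    raise ValueError(f"unknown criterion label {label!r}")


def standard_criteria(reports: Sequence[LocusReport]) -> list[str]:
    """The default criterion family, with tissue/source labels discovered
    from the reports themselves."""
    labels = [
        "nearest",
        "three_nearest",
        "ld_overlap",
        "eqtl",
        "eqtl_sentinel",
        "eqtl_proxy",
        "impact_sentinel:HIGH",
        "impact_sentinel:MODERATE",
        "impact_proxy:HIGH",
        "impact_proxy:MODERATE",
        "concurrent",
        "nearest_concurrent",
        "bottom_up",
        "top_down",
    ]
    sources: set[str] = set()
    scores: set[int] = set()
    for rep in reports:
        for cand in rep.candidates.values():
            sources |= set(cand.sources)
            if cand.score:
                scores.add(cand.score)
    labels += sorted(f"td_source:{s}" for s in sources)
    labels += [f"td_score:{k}" for k in sorted(scores)]
    return labels


def criterion_sets(
    reports: Sequence[LocusReport],
    criteria: Sequence[str] | None = None,
    locus_filter: Callable[[LocusReport], bool] | None = None,
) -> dict[str, set[Instance]]:
    """(locus, gene) instance sets per criterion label.

    ``locus_filter`` drops whole loci before set construction — e.g.
    ``lambda r: r.sentinel_impact_max != "MODERATE"`` excludes loci tagged
    by a moderate-impact sentinel. The enrichment unit is the (locus, gene)
    instance, so one gene can contribute at several loci.
    """
    kept = [r for r in reports if locus_filter is None or locus_filter(r)]
    if criteria is None:
        criteria = standard_criteria(kept)
    out: dict[str, set[Instance]] = {}
    for label in criteria:
        if label == "nearest_concurrent":
            out[label] = {
                (r.sentinel.rsid, r.nearest_concurrent.gene_id)
                for r in kept
                if r.nearest_concurrent is not None
            }
            continue
        pred = _criterion_predicate(label)
        out[label] = {
            (r.sentinel.rsid, c.gene.gene_id)
            for r in kept
            for c in r.candidates.values()
            if pred(c)
        }
    return out


def fisher_enrichment(
    criterion_set: set[Instance],
    truth: set[Instance],
    background: set[Instance],
    n_tests: int = 1,
    criterion: str = "",
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of criterion membership vs truth.

    The 2×2 table is [[criterion∧TP, criterion∧FP], [background∧TP,
    background∧FP]], background being all remaining candidate instances.
    The odds ratio is the conditional maximum-likelihood estimate with an
    exact 95% CI. A zero margin yields p = 1 and an undefined (nan) OR,
    flagged via ``degenerate``.
    """
    bg = background - criterion_set
    a = len(criterion_set & truth)
    b = len(criterion_set - truth)
    c = len(bg & truth)
    d = len(bg - truth)
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return EnrichmentResult(
            criterion=criterion,
            table=table,
            odds_ratio=math.nan,
            ci95=(math.nan, math.nan),
            p_raw=1.0,
            p_bonferroni=1.0,
            n_tests=n_tests,
            degenerate=True,
        )
    _, p_raw = stats.fisher_exact(table, alternative="two-sided")
    orr = stats.contingency.odds_ratio(table, kind="conditional")
    ci = orr.confidence_interval(confidence_level=0.95)
    return EnrichmentResult(
        criterion=criterion,
        table=table,
        odds_ratio=float(orr.statistic),
        ci95=(float(ci.low), float(ci.high)),
        p_raw=float(p_raw),
        p_bonferroni=min(1.0, float(p_raw) * n_tests),
        n_tests=n_tests,
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# Orchestration


def _candidate_ids(report: LocusReport, which: str) -> set[str]:
    return {
        "total": set(report.candidates),
        "bottom_up": set(report.bottom_up),
        "top_down": set(report.top_down),
        "concurrent": set(report.concurrent),
        "nearest_concurrent": (
            {report.nearest_concurrent.gene_id}
            if report.nearest_concurrent is not None
            else set()
        ),
    }[which]


def _gene_matches(report: LocusReport, gene_id: str, ref: ReferenceAssignment) -> bool:
    """Reference gene may be stated as a gene id or a symbol (case-blind)."""
    if gene_id == ref.causal_gene:
        return True
    cand = report.candidates.get(gene_id)
    symbol = (
        cand.gene.symbol
        if cand is not None
        else (
            report.nearest_concurrent.symbol
            if report.nearest_concurrent is not None
            and report.nearest_concurrent.gene_id == gene_id
            else gene_id
        )
    )
    return symbol.casefold() == ref.causal_gene.casefold()


def benchmark_run(
    reports: Sequence[LocusReport],
    references: Sequence[ReferenceAssignment],
    genes: GeneModel | None = None,
    window: int = 500_000,
    mode: str = "lg",
    n_tests: int | None = None,
    locus_filter: Callable[[LocusReport], bool] | None = None,
    criteria: Sequence[str] | None = None,
) -> tuple[list[BenchmarkSummary], list[EnrichmentResult]]:
    """Aggregate benchmark over all loci with a reference assignment.

    Produces one :class:`BenchmarkSummary` per candidate-set definition
    (total, bottom-up, top-down, concurrent, nearest-concurrent) and the
    criterion-stratified enrichment table. Loci without a reference are
    excluded with a warning; mode ``lg`` needs ``genes`` to count local
    protein-coding genes within ±``window`` of each sentinel.
    """
    ref_by_sentinel = {r.sentinel_rsid: r for r in references}
    kept = [
        r
        for r in reports
        if r.sentinel.rsid in ref_by_sentinel
        and (locus_filter is None or locus_filter(r))
    ]
    if not kept:
        raise ValueError("no loci with reference assignments to benchmark")

    # ΣLG: local genes within ±window of each sentinel (gene-body overlap)
    sum_lg = 0
    if genes is not None:
        for r in kept:
            lo = max(1, r.sentinel.pos - window)
            sum_lg += len(genes.overlapping(r.sentinel.chrom, lo, r.sentinel.pos + window))
    sum_pg = sum(len(r.candidates) for r in kept)

    summaries: list[BenchmarkSummary] = []
    for which in ("total", "bottom_up", "top_down", "concurrent", "nearest_concurrent"):
        tp = fp = fn = 0
        for r in kept:
            ref = ref_by_sentinel[r.sentinel.rsid]
            ids = _candidate_ids(r, which)
            hit = any(_gene_matches(r, gid, ref) for gid in ids)
            tp += int(hit)
            fp += len(ids) - int(hit)
            fn += int(not hit)
        total = sum_lg if mode == "lg" else sum_pg
        total = max(total, tp + fp + fn)
        tn = total - (tp + fp) - fn
        spec = specificity(tp, fp, fn, total, mode=mode)
        summaries.append(
            BenchmarkSummary(
                name=which,
                n=len(kept),
                tp=tp,
                fp=fp,
                fn=fn,
                tn=tn,
                sensitivity=sensitivity(len(kept), tp),
                specificity=spec,
                mode=mode,
            )
        )

    # enrichment over (locus, gene) instances
    truth: set[Instance] = set()
    background: set[Instance] = set()
    for r in kept:
        ref = ref_by_sentinel[r.sentinel.rsid]
        for gid in r.candidates:
            inst = (r.sentinel.rsid, gid)
            background.add(inst)
            if _gene_matches(r, gid, ref):
                truth.add(inst)
    crit_sets = criterion_sets(kept, criteria=criteria, locus_filter=None)
    nt = n_tests if n_tests is not None else len(crit_sets)
    enrichments = [
        fisher_enrichment(instances, truth, background, n_tests=nt, criterion=label)
        for label, instances in crit_sets.items()
    ]
    return summaries, enrichments
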