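# Methods

## Model and assumptions

A gene is treated as a credible causal gene for a molecular QTL when two
independent requirements hold: (i) its product is plausibly altered in
structure, abundance or function by the sentinel variant or a variant in
strong LD with it, and (ii) it is already implicated in the biology of the
molecular phenotype. The bottom-up arm operationalizes (i) through
positional and regulatory evidence; the top-down arm operationalizes (ii)
through curated domain gene lists. The intersection (concurrent
candidates) inherits both lines of support and is the prioritized set.

The framework is deliberately rule-based — there is no fitted model and no
composite numeric score beyond the 1–5 source count — so every output is
reproducible from the inputs and a configuration.

## Coordinates and conventions

- All intervals are 1-based and closed (Ensembl GTF convention); overlap
  requires at least one shared base.
- Chromosome labels are normalized ("chr1" ≡ "1") before comparison.
- The TSS is strand-aware: interval start on +, interval end on −.
- The ±window and r² thresholds are inclusive at the boundary.
- Variant IMPACT severity is taken from the four-class VEP-style rating
  (HIGH > MODERATE > LOW > MODIFIER), never re-derived from consequence
  term ontologies; where a (variant, gene) pair appears multiple times the
  most severe record is kept.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_nearest` | 3 | nearest protein-coding genes per sentinel |
| `window` | 500 000 bp | TSS window for top-down flanking genes; also ΣLG |
| `r2_threshold` | 0.8 | minimum LD for a proxy (inclusive) |
| `ld_pad` | 5 000 bp | padding added to the proxy span |
| `eqtl_mode` | pre-filtered | eQTL rows already FDR-thresholded upstream (0.05) |
| `biotypes` | protein_coding | gene-model filter; `None` disables |

Raising `window` to 1 Mb and disabling the biotype filter recovers genes
missed under defaults (distal causal genes; pseudogene causal genes) at a
specificity cost — both are plain config switches.

## Design choices where the rules were open

- **LD span membership.** The sentinel's own position is included when
  taking the left-/right-most coordinates (it is its own r² = 1 proxy), so
  the no-proxy fallback (sentinel ± pad) is the same rule rather than a
  special case. A config flag excludes it.
- **Nearest-gene distance** is measured to the gene body (0 inside the
  interval, else the smaller offset to either end), with TSS distance as a
  config alternative. Ties break deterministically by (distance, interval
  start, gene id); the same ordering backs the nearest-concurrent rule, so
  equidistant concurrent candidates resolve reproducibly.
- **Annotation matching** defaults to case-insensitive gene symbols
  (curated lists are symbol-keyed); stable gene identifiers are a config
  alternative. Neither is asserted to be the only valid join key.
- **Benchmark decomposition.** With one reference gene per locus, a
  captured reference contributes TP = 1 and the remaining candidates at
  that locus are FPs; a miss contributes FN = 1 and all candidates are
  FPs. Aggregates are sums over loci, which makes TP + FN = n an invariant
  of every candidate-set definition.
- **Enrichment unit** is the (locus, gene) instance, not the unique gene:
  the background for each criterion is all remaining candidate instances
  across the dataset, so a gene that is a candidate at two loci counts
  twice. The Bonferroni divisor is caller-supplied (the criterion family
  size is an analysis decision, not inferable from one table).
- **ΣLG counting** uses gene-body overlap with the ±window interval.

## Numerical choices

- Fisher's exact p-values are two-sided (point-probability criterion, via
  scipy); the odds ratio is the conditional maximum-likelihood estimate
  with an exact 95% CI, matching standard exact-test routines. Tables with
  a zero margin are flagged degenerate: p = 1, OR undefined.
- A per-locus failure inside a batch run is isolated: the locus is
  reported with an `error` field and empty sets, and the batch continues —
  batch runs over hundreds of loci should not abort on one malformed
  locus. A sentinel on a chromosome absent from the gene model yields a
  warning and an empty report.
- Reported sensitivities are exact percentages; display rounding is
  nearest-integer at the reporting layer only.

## Synthetic data: what it emulates and what it does not

`simulate_dataset` generates gene models (per-chromosome, left-to-right
with sampled gap and length, a small pseudogene fraction), then plants one
causal protein-coding gene per locus and realizes an evidence profile:
sentinel inside the causal gene (probability `p_causal_is_nearest`),
moderate-impact coding sentinel (`p_causal_coding`), cis-eQTL support in
1–3 tissues (`p_causal_eqtl`), and membership in k of 5 domain databases
(`causal_db_count_probs`). Decoy eQTL targets are drawn only within ±1 Mb
of the sentinel (the cis definition) and decoy database membership is
sampled independently per gene and source, so scores 1–5 arise naturally.
`n_out_of_window` loci plant the causal gene beyond the window,
reproducing the long-range-miss failure mode. Defaults aim at a
metabolite-QTL-like regime: a causal gene that is usually but not always
nearest, a handful of candidates per locus, and high-but-imperfect
concurrent recovery.

Deliberate non-realism: proxy positions are sampled around the sentinel
and r² values are stamped rather than derived from haplotypes (no real LD
structure); genes never overlap each other; annotation lists have no
correlation between sources. Tests passing on these data therefore
validate the candidate-generation and accounting *rules*, not robustness
to real LD or annotation bias. Causal genes are planted at least three
gene positions apart so one locus's candidate set cannot absorb another
locus's planted gene, which is what makes "sole concurrent candidate"
recovery a construction guarantee under a decoy-free profile.

Determinism: a single `numpy` generator seeded from the config drives all
sampling; identical configs produce byte-identical files.

## Problem sizes used in the checks

The bundled worked example has 3 loci over 39 genes; property checks use
gene models up to 5 000 genes with brute-force oracles; the synthetic
benchmark in the acceptance script runs 200 loci over 720 genes, which
completes in seconds. These sizes were chosen as the smallest at which
every rule and invariant is exercised, including multi-chromosome layout
and criterion stratification.

## Known limitations

- No LD computation from genotypes: proxies are inputs.
- No colocalization statistics and no composite prioritization score.
- Full-cohort benchmark figures depend on external resources (a complete
  GTF, tissue-wide eQTL catalogues, curated reference sets) that are
  consumed as inputs, not bundled.
- eQTL target genes absent from the (biotype-filtered) gene model are
  kept as candidates but carry no positional evidence.
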