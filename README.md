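# progem

Identification and prioritization of candidate causal genes at molecular
QTLs (metabolite, protein or expression QTLs).

A genome-wide significant association tells you *where* a causal variant
lies, not *which* gene it acts through. `progem` implements a two-arm
framework for closing that gap at molecular QTLs, where the associated
trait is itself a molecular intermediate:

- **Bottom-up (variant-centric):** genes plausibly affected by the
  sentinel variant or its LD proxies (r² ≥ 0.8) — genes overlapping the
  LD range (left- to right-most proxy ± 5 kb), the 3 nearest
  protein-coding genes, and significant cis-eQTL target genes across
  tissues. Genes containing a sentinel or proxy variant of HIGH or
  MODERATE predicted impact are flagged.
- **Top-down (phenotype-centric):** genes with a transcription start site
  within ±500 kb of the sentinel that appear in curated domain gene lists
  (up to five sources, e.g. GO / KEGG / MGI / Orphanet / Reactome), scored
  1–5 by the number of sources reporting them.

Genes found by **both** arms — the *concurrent* candidates — are
designated the most likely causal genes. A *nearest-concurrent* assignment
forces exactly one gene per locus (the concurrent candidate nearest the
sentinel, or the nearest gene when no concurrent candidate exists).

Benchmarking utilities score candidate sets against reference causal-gene
assignments (one per locus):

```
sensitivity = (100 / n) · TP
specificity = TN / (TN + FP),   TN = ΣLG − (TP + FP) − FN
```

with ΣLG the local protein-coding genes within ±500 kb of each sentinel
(or ΣPG, all emitted candidates, when comparing components), plus
criterion-stratified enrichment by two-sided Fisher's exact test
(conditional-MLE odds ratio, exact 95% CI, Bonferroni correction).

## Worked example

Three bundled loci with known causal genes (MTHFR for homocysteine at
rs1801133, AOC1 for an acetamide metabolite at rs1005390, G6PD for
bilirubin at rs766420):

```python
from progem import table2_fixtures, run_pipeline, PipelineConfig

ds = table2_fixtures()
reports = run_pipeline(ds.sentinels, ds.genes, ds.proxies, ds.eqtls,
                       ds.consequences, ds.annotation_sets, PipelineConfig())
for r in reports:
    print(r.sentinel.rsid, sorted(r.concurrent),
          {g: r.candidates[g].score for g in sorted(r.top_scoring)})
```

```
rs1801133 ['MTHFR'] {'MTHFR': 4}
rs1005390 ['AOC1'] {'AOC1': 3, 'NOS3': 3}
rs766420 ['DNASE1L1', 'RPL10', 'TAZ', 'TKTL1'] {'G6PD': 3, 'IDH3G': 3}
```

At the first two loci the known causal gene is the sole concurrent
candidate. The third locus is the cautionary case: four concurrent
candidates, none of which is the causal gene G6PD — G6PD sits >200 kb
away and is reached only by the top-down arm (score 3, tied top scorer),
which is why concurrent status prioritizes but must not be used to discard
the rest.

## Command line

```bash
progem simulate --seed 1 --out sim/          # synthetic inputs + truth
progem run --sentinels sim/sentinels.tsv --proxies sim/proxies.tsv \
    --gtf sim/genes.gtf --consequences sim/consequences.tsv \
    --eqtls sim/eqtls.tsv --annotation-sets sim/annotation_sets.tsv \
    --out reports/
progem benchmark ... --reference sim/reference.tsv --out bench/
```

`progem run` writes `bottom_up.tsv`, `top_down.tsv`, `concurrent.tsv`,
`nearest_concurrent.tsv` and a config echo; `progem benchmark` writes
`summary.tsv` (TP/FP/FN/TN, sensitivity, specificity per candidate-set
definition) and `enrichment.tsv`.

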