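# tumorpool

Simulation and analysis of **multi-regional vs pooled tumor biopsy
sequencing**.

A single biopsy under-samples an intratumorally heterogeneous cancer;
sequencing several regions is sensitive but costly; physically pooling the
regions into one library is cheap but dilutes region-restricted variants.
`tumorpool` quantifies this trade-off in silico, for bioinformaticians and
biobank/sequencing-strategy designers: it simulates the clonal architecture
of a tumor sampled at several foci, sequences each region, builds pooled and
in-silico mixed libraries, and measures what the pool detects, dilutes, and
misses — at the variant and the gene-expression level.

## Model

**Variants.** Somatic variants are partitioned into *truncal* (present in all
`n` regions, VAF centered near 0.40), *shared* (a strict subset of ≥ 2
regions) and *private* (one region) classes, with subclonal VAFs drawn from a
low range (default 0.02–0.30); germline het/hom SNPs (VAF 0.5 / 1.0) carry
dbSNP/population-frequency annotation flags. Sequencing a locus of true VAF
`v` at depth `d` (negative-binomial around 137×) yields an alt count

    alt ~ Binomial(d, v·(1−e) + (1−v)·e/3),   e = per-base error rate (1e−3).

**Pooling.** A physical pool with weights `w` re-sequences the weighted mean
of the regional allele fractions, `f = Σ wᵢ·altᵢ/depthᵢ` — a variant private
to one of four equally weighted regions has its VAF diluted fourfold. An
in-silico mix instead draws 25% of each region's reads without replacement
and sums them.

**Calling and filtering.** A locus is detected iff `alt ≥ 4` and the exact
binomial tail `P(X ≥ alt | d, e) < 1e−6`. Detected calls then pass a
homozygous filter (VAF > 90%), a conjunctive germline filter (in dbSNP AND
population AF > 1% AND not in COSMIC/TCGA) and an optional 337-gene panel
filter. Variants are classified *common / shared / private / absent* by the
number of regional call sets they pass in, and the pool is scored by
per-class detection rates, the fraction of moderate-VAF (> 20% in some
region) variants it misses, and the Pearson correlation between pooled VAF
and mean regional VAF.

**Expression.** Per-region gene counts (negative binomial, 18,161 genes, a
configurable minority with region-specific fold changes) are filtered
(max count > 20), TMM-normalized, and compared by pairwise Pearson
correlation of log₂ values and by the fraction of genes beyond 2/3/4-fold
between every region pair and every region-vs-pool pair.

## Worked example

```python
import json
from tumorpool import SimulationConfig, run_experiment

cfg = SimulationConfig(seed=1)          # 4 regions, 137x, 18,161 genes
res = run_experiment(cfg)
agg = res.summary.aggregate
print("concordance:", json.dumps(agg["concordance_fractions"]))
print("pooled detection:", json.dumps(agg["pooled_detection"]["pooled_detection_rate"]))
print("VAF correlation:", json.dumps({k: round(v, 3) for k, v in agg["vaf_correlation"].items()}))
```

prints

```
concordance: {"common": 0.61, "shared": 0.19, "private": 0.2}
pooled detection: {"common": 1.0, "shared": 0.9473684210526315, "private": 0.5}
VAF correlation: {"pooled": 0.979, "mixed": 0.985}
```

Read: of the variants detected in ≥ 1 of the four regional call sets, 61%
were common to all four, 19% shared and 20% private. The pooled library
recovered every common variant but only half of the private ones (their VAF
is diluted fourfold), and its VAFs track the mean regional VAF closely
(r = 0.98). The same run reports expression-level agreement
(mean pairwise log₂ correlation 0.98 under the default 5% of genes with
region effects) and the fold-change fraction table.

The same pipeline is scriptable from the shell:

```sh
tumorpool run --seed 1 --outdir out/          # full experiment, all tables
tumorpool sweep --depth 137 --out power.tsv   # detection power vs VAF/depth
```

`tumorpool run` writes the truth VCF, per-sample call VCFs, the
classification TSV, the expression tables and a `summary.json`; re-running
with the same seed reproduces them byte for byte.

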