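# Methods

## The question being modeled

A tumor sampled at `n` spatially distinct foci (default 4) harbors somatic
variants at three levels of clonality: truncal variants present in every
region, shared variants in a strict subset of ≥ 2 regions, and private
variants confined to one region. Sequencing all regions separately detects
the most; sequencing one region misses everything outside it; pooling the
tissue into one library averages the allele fractions, so a variant present
in `k` of `n` equally weighted regions appears at roughly `k/n` of its
regional VAF. The package simulates this design end to end so the detection
consequences of pooling can be measured rather than argued.

## Truth model

* Truncal VAFs are Normal(0.40, 0.08) truncated to [0.05, 0.95], identical
  across regions (clonal origin). The 0.40 center reflects the typical
  clonal VAF of a ~60–80% pure tumor; the truncation keeps truth VAFs away
  from the homozygous-filter region.
* Shared/private VAFs are Uniform(0.02, 0.30) drawn independently per
  present region — subclonal variants sit at low allele fractions, which is
  exactly what makes them vulnerable to dilution. Shared presence sets have
  uniform size in {2, …, n−1} with uniformly chosen members; private
  variants land in a uniformly chosen region.
* Germline heterozygous/homozygous SNPs have VAF 0.5 / 1.0 in every region
  and are flagged dbSNP-member and population-AF > 1%; a small fraction
  (default 2%) additionally carries the COSMIC/TCGA flag so the rescue arm
  of the germline filter is exercised. Somatic variants carry the
  COSMIC/TCGA flag with probability 0.15 and the 337-gene-panel flag with
  probability 0.10 (both configurable).
* Loci are uniform over chr1–chr22 (1-based, VCF convention); coordinates
  carry no biology here beyond giving the VCF writers real positions.

## Sequencing model

* Depth per locus: negative binomial with mean 137 and shape 120, i.e.
  sd ≈ 17 — an exome-like coverage profile.
* Alt count: Binomial(depth, v(1−e) + (1−v)e/3) with e = 1e−3. The error
  term is substitution-symmetric (an error is any of 3 wrong bases with
  equal probability); it makes false positives a measurable, testable rate
  rather than an impossibility.
* Expression: counts are negative binomial with mean = baseline × region
  effect and shape 100 (CV ≈ 10% at high counts). Baselines are log-normal
  (median 200, log-sd 1.5) over 18,161 genes; 5% of genes (default) carry a
  2–6-fold effect, up or down, in one random region. The shape was chosen
  to match the tight intra-tumor expression agreement seen in well-behaved
  tumors (pairwise r² ≈ 0.97); it is the single knob controlling how "null"
  the null expression comparison is.

## Pooling routes

* `pool_physical`: the pooled allele fraction is the weighted mean of the
  *observed* regional fractions; a fresh depth (same negative-binomial
  model, mean = pooled depth) and a binomial alt draw represent
  re-sequencing one library made from mixed tissue. Expression is a
  multinomial re-sample of the weighted mixture of regional rates at the
  mean regional library size.
* `mix_in_silico`: per region and locus, `round(f·depth)` reads are drawn
  without replacement (hypergeometric over the alt/ref split) and summed
  across regions; default f = 0.25. Expression reads are thinned binomially
  at f per gene — a per-gene alt/ref split does not exist, so
  keep-each-read-with-probability-f is the natural analogue.
* With equal weights and equal depths both routes estimate the same
  per-locus quantity (the mean regional VAF); the tests assert this
  convergence empirically.

## Caller and filters

The stand-in caller is deliberately transparent: `alt ≥ min_alt` (4) and an
exact binomial tail below `alpha` (1e−6) against the error rate. At 137×
this means 5 alt reads; detection of a 5% VAF variant is near-certain,
detection of a 1% variant (a fourfold-diluted 4% private variant) is poor —
which is the phenomenon under study. Both parameters are exposed.

Filter semantics worth noting:

* homozygous filter is strict (`VAF > 0.90` fails; 0.90 passes);
* the germline filter is conjunctive — all three criteria must hold — and
  COSMIC/TCGA membership rescues a call regardless of the other two;
* filters are independent predicates on detection-stage attributes; a call
  failing several accumulates ';'-separated codes, so the PASS set is
  invariant under filter order (property-tested);
* the panel filter is off by default so class totals stay interpretable.

"Shared" is classified as passing in ≥ 2 and ≤ n−1 regions: together with
"common = all n" and "private = exactly 1" this partitions the detected
variants, and the partition (common + shared + private = detected in ≥ 1
region) is asserted on random call sets.

Two statistics have a deliberate, flagged choice of denominator:

* mean regional VAF averages over *all* n regions, zeros included — this is
  the quantity the dilution law predicts the pooled VAF to equal; the
  detected-regions-only mean is available behind a flag.
* the missed-moderate-VAF fraction is computed over all regionally detected
  variants with max regional VAF > 0.20 by default; a mode restricted to
  shared variants is provided (`restrict_moderate_to_shared`).

## Expression comparison

Genes with max count ≤ 20 across samples are dropped, then TMM factors are
computed exactly as the standard published procedure: reference = sample
whose library-size-scaled upper quartile is closest to the mean; M/A on
library-size-normalized counts over genes nonzero in both; 30% two-sided
trim on M and 5% on A (rank-based, average ranks on ties);
inverse-delta-method-variance weighting; 2^(weighted mean M). The factors
*returned* are effective factors — compositional factor × library size,
rescaled to geometric mean 1 — so identical libraries give exactly 1.0 and a
uniformly doubled library gets exactly twice its twin's factor. They are
cross-checked against the Bioconductor implementation (factor × library
size) in the test suite. Correlations and fold changes use
log₂(normalized + 1); pseudocount 1 is the zero-handling choice.

## Determinism

One integer seed drives everything. Named generator streams are derived via
`SeedSequence(seed, spawn_key=...)` with fixed keys per consumer ("truth",
("region", i), "pooled", "mixed", "sweep"), so adding a sample never
perturbs another's draws, and a rerun of `run_experiment` reproduces every
output file byte for byte. The power sweep reuses common random numbers
across the VAF grid (inverse-CDF sampling), making the estimated power
curves exactly monotone in VAF at finite replicate counts.

## Problem sizes

The default experiment (100 somatic + 300 germline variants, 4 regions,
18,161 genes) runs in about a second. The dilution-law and
pooled-sensitivity checks use 1000 truncal loci; the power sweep defaults to
2000 replicates per grid point; the null-expression check uses the full gene
universe. These sizes put Monte-Carlo error well below the margins being
asserted while keeping any run interactive.

## What the generator does and does not emulate

It reproduces the statistical skeleton the analysis depends on: class
structure and presence sets, VAF levels by class, depth overdispersion,
error-driven false calls, dilution arithmetic, library-size and
compositional effects in expression. It does **not** model alignment or
mappability artifacts, base-quality structure, strand bias, copy-number or
purity distortion of VAFs, indels, or correlated expression programs across
genes. Tests passing here therefore validate the pipeline's arithmetic and
its qualitative behavior, not the idiosyncrasies of any real tumor; the
per-tumor percentages a real dataset produces depend on its specific clonal
composition, which is a free input (`SimulationConfig`), not a prediction.

## Known limitations

* The binomial caller has no realignment or quality model, so its absolute
  sensitivity at a given VAF/depth is optimistic relative to production
  callers; comparisons *between* sampling strategies, which share the
  caller, are the intended use.
* Hypergeometric mixing assumes regional libraries are read-exchangeable;
  duplicate structure is not modeled.
* TMM assumes most genes are not differentially expressed between samples;
  with very large `frac_de_genes` the trimmed estimator, like the original,
  will absorb part of the signal into the factors.
* PCA of VAF profiles uses the observed VAF matrix with zeros for
  undetected loci; samples from different tumors should be compared over a
  joint variant universe.
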