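# Methods

This note documents the models, defaults and numerical choices behind
`ribostress`, and what the synthetic experiments do and do not demonstrate.

## Synthetic data model

**Composite reference.** Each of `n_parents` (default 8) parent RPG mRNAs is
a uniform random sequence of `mrna_len` (default 400) nt stored as its own
contig. Each pseudogene copy applies i.i.d. per-base substitutions at
`divergence_rate` (default 0.05, so a 60-nt read overlaps ≥1 diverged base
with probability ≈ 0.95) and is embedded between random 150-nt flanks in a
decoy contig. Every substituted position is recorded as ground truth.
Parent mRNAs are deliberately not embedded in genomic contigs: a read
matching both a parent mRNA and an exonic genomic copy would always be
multi-locus, which would make simulated truth ambiguous. Substitution-only
divergence (no indels) is a v1 simplification — under exact matching indels
would shift coordinates without changing the assignment logic.

**Reads.** Error-free exact substrings (default 60 nt, 40 per locus),
forward or reverse complement with equal probability, constant maximum
quality. Sequencing errors are omitted because the assigner forbids
mismatches: an erroneous read could only become unmapped and would not
exercise the disambiguation logic.

**Counts.** For gene g and sample s the log2 mean is

    log2 mu_gs = log2(base_g) + lfc_g * 1[stress] + sum_m lambda_gm * z_ms
                 + sum_c beta_gc * x_cs,

then columns are scaled so each sample's expected total equals a library
size drawn log-uniformly from (1.5e5, 4.5e5), and counts are drawn NB with
variance mu + phi*mu^2 (phi = 0.1, a typical bulk RNA-seq dispersion; phi = 0
degenerates to Poisson, verified by a variance/mean test at constant library
size). Gene base means are log-uniform on (30, 300). Module structure uses
one standard-normal latent factor z per module per sample with signed
per-gene loadings lambda (log2-scale sd units) — the simplest mechanism
giving controllable Spearman sign and strength. Covariates (age, RNA
integrity) are standard normal per sample with per-gene N(0, 0.2)
coefficients, exercising the adjustment stage.

**Demo design.** 2 species × 2 sexes × 2 groups with n = 24 per
(species, sex, group). Planted effects: 15 of the 80 RPG-family genes at
log2FC −1 (the real-world magnitude of stress-induced RPG change is not
publicly quantified; −1 is a clearly detectable but not trivial effect at
these sample sizes — detection power per gene is ≈ 0.95 under the q-rule at
the pooled n), the 10 RP pseudogenes at +1 with latent loading −0.8
(anti-correlated with the RPG module, loading +0.8), and 25 synapse genes
loading +0.8. The per-species contrast pools both sexes (sex enters the
covariate adjustment); sexes would individually be underpowered at n = 24
per group under the BH-corrected rule, and the pooled design matches how
the seeded networks are later stratified by sex anyway.

## Read assignment

The index hashes every k-mer (k = 16) of every locus on both strands; a
query anchors on its first k-mer and is verified by direct string
comparison, so matching is exact, not heuristic. Queries shorter than k
fall back to a direct scan. Distinct loci are counted once regardless of
how many offsets (or strands) match within a locus; the discard rule
operates on loci, not offsets. Unique → assigned; ≥2 loci → discarded;
0 → unmapped. Tests verify exact agreement with a naive both-strand
substring scan and with the simulator's truth table, including the
divergence-0 limit where every parent/pseudogene read is discarded.

## Differential expression

The low-count rule removes genes whose *mean* count across all samples is
≤ 5 (inclusive); a `row_sum` mode implements the alternative reading of the
same rule. Normalisation is log2(CPM + 1). Covariate adjustment replaces
each gene by OLS residuals on [intercept | covariates]; the group label is
never in that regression, and rank-deficient designs are rejected with the
offending columns named. The test is Welch's t on adjusted log-CPM — a
deliberate stand-in for an NB GLM, since the package's contribution is
downstream of DE and externally computed DE tables (gene, log2FC, p, q TSV)
can be dropped in at the file interface. Zero-variance genes with a nonzero
mean difference get p = the smallest positive float (with a logged warning)
rather than NaN. BH correction is the standard step-up procedure
(statsmodels), validated against the definitional min_{i≥k} m·p(i)/i oracle.

Calibration under the study conditions (n = 20/group, phi = 0.1): the null
false-discovery fraction at q < 0.05 is ≈ 0.0001 over 50 seeds, and planted
log2FC −1 genes are detected with correct sign in ≈ 100% of cases. The
point estimate of a planted −1 has sampling sd ≈ 0.148
(≈ sqrt(2·trigamma(1/phi))/(ln2·sqrt(n))), so the ±0.3 band around the true
value captures ≈ 95% of replicates — the unit test asserts unbiasedness and
a conservative ≥ 90% in-band rate rather than sitting on that boundary.

## Family enrichment and harmonisation

The hypergeometric upper tail P[X ≥ k] is computed by `scipy.stats.hypergeom`
and verified against exact rational enumeration for every configuration with
N ≤ 12. Only over-representation is tested. The universe defaults to the
conventional 21,196-gene background; synthetic runs pass the simulated
universe size instead. Harmonisation applies the explicit 1:1 ortholog map
first and the case convention (mouse `Rpl3` ↔ human `RPL3`) as fallback;
many-to-many maps are rejected. Pattern-only pseudogene suffix stripping
(`-ps\d*$`, `AS\d*$`) can collide with genuine symbols ending in "AS", so
callers holding a pseudogene annotation table should pre-filter to annotated
symbols.

## Seeded networks

Spearman rho uses average ranks. For tie-free vectors with n ≤ 9 the
two-sided p comes from the exact permutation null of rho, enumerated once
per n and cached — the t approximation's error against that null reaches
0.15 at n = 4 and only falls below 0.02 at n = 8, so small strata need the
exact form (this mirrors R's `cor.test`, which switches to the exact
distribution below n = 10). Ties or n ≥ 10 use
t = rho·sqrt((n−2)/(1−rho²)). No multiple-testing correction is applied to
the per-seed lists (the raw p < 0.05 rule is part of the analysis being
reproduced); FDR control happens in the downstream pathway enrichment.
Strata with fewer than 4 samples are skipped with a warning. On null data
the per-seed pass fraction at p < 0.05 is 0.05 ± 0.02 across 50 runs.

## GO themes

Annotations propagate to all is_a ancestors before testing; the enrichment
universe is the annotated gene set (configurable) rather than the 21,196
constant, since unannotated genes carry no information for term tests.
Theme assignment records *all* matching themes — case-insensitive keyword
substring on the term name, or descent from (or equality with) an anchor
term — with no priority between the two routes, and "unclassified" when
nothing matches. Stratum-level enrichment runs on the union of per-seed
correlate lists, while `contributing_seeds` counts the seeds whose own list
independently reaches q < 0.05 for the term (floored at 1 for terms that
only the union reaches, so the count is always meaningful).

## Pipeline

Stages exchange data only through TSV/FASTA/FASTQ/OBO/JSON files, so real
data can replace any stage input. A run is a pure function of (config,
seed, inputs); the manifest records thresholds, per-stage timings and
SHA-256 checksums, and repeated runs with the same seed produce
byte-identical TSVs. The full synthetic demo (toy reference of 26 loci,
1,040 reads, two 450-gene × 96-sample count matrices) completes in a few
seconds on one CPU.

## What the synthetic experiments do not show

The generator emulates the statistical structure the analysis assumes —
NB counts, planted fold changes, latent-factor modules, homologous
pseudogene sequences — not real transcriptomes: no isoforms, GC or length
bias, sequencing error, single-cell structure, correlated covariates, or
realistic ortholog complexity (the toy map is bijective). Passing tests
demonstrate that the pipeline recovers the effects it is designed to detect
when its assumptions hold, with calibrated error rates; they do not
validate the biological conclusions on any real cohort. Planted effect
sizes are configurable defaults, not calibrated to any public dataset.
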