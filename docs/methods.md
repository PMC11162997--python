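# Methods

## Junction classification model

A gene model lists the exons of one locus in transcriptional order with
1-based inclusive genomic coordinates, designating one constitutive *anchor*
exon, a cluster of microexons (each ≤ 30 nt), and the next constitutive
*terminal* exon.  The classifier derives from it:

- the **donor coordinate** — the first intronic base after the anchor's
  transcriptional 3′ end (`anchor.end + 1` on the + strand,
  `anchor.start − 1` on −), and
- an **acceptor map** — for each candidate downstream exon, the last
  intronic base before it (`exon.start − 1` on +, `exon.end + 1` on −),
  mapped to an isoform label.

Labels are generated from the architecture: the last microexon before the
terminal exon is present in every microexon-containing isoform, so a
junction straight to it is labeled `<anchor>:<len>bp`, a junction to an
earlier microexon `<anchor>:<len>bp/<earlier len>bp`, and a junction to the
terminal exon `<anchor>:<terminal>` (full skipping).  For the packaged
RPS24-style model this yields the four classes `ex4:22bp`, `ex4:22bp/3bp`,
`ex4:22bp/18bp`, `ex4:ex6`.

A junction record is classified by exact coordinate equality: records whose
donor-side coordinate differs from the anchor donor (or that sit on another
chromosome) are `not_anchor` and ignored; anchor-donor records with an
unknown acceptor are `unclassified`.  Classification is total and
deterministic, and invariant under reflecting the model and all junctions
through any genomic pivot onto the opposite strand.  Chromosome names are
compared after stripping an optional `chr` prefix (GTEx/TCGA dialects
differ); exact comparison is available via a flag.

Coordinates follow STAR's `SJ.out.tab` convention (9 tab-separated columns,
intron start/end as first/last intronic base, 1-based inclusive), so the
consumed format is used bit-compatibly, with no coordinate arithmetic at
read time.

## Quantification

Per sample, unique junction reads (STAR column 7) are accumulated per label;
multimapping reads are excluded unless requested, matching common practice
for splice-junction counting.  The denominator is the total over all
anchor-donor reads *including* `unclassified` — the natural reading of
"all reads leaving the anchor exon" — with a flag to exclude them; at
realistic noise levels (≲ 0.1 % of reads) the two conventions differ
negligibly.  Samples with zero anchor-donor reads have *missing*
proportions, never 0/0: a zero-expression sample carries no isoform
information, and missing values propagate so that downstream statistics
exclude such samples listwise per isoform.  Optional overhang and
unique-count filters default to 0 (no silent filtering).

## Cohort statistics

- **Tissue enrichment**: per-tissue arithmetic mean of a label's proportion
  over defined samples, top-k reported, ties broken by tissue name.
- **Group comparison**: difference in means with a Welch unequal-variance
  t-test (two-sided, Welch–Satterthwaite df).  Welch is used because group
  variances of compositional proportions routinely differ; the choice is
  recorded in output metadata.  Multi-isoform comparisons also carry a
  Benjamini–Hochberg column for transparency, but significance flags use
  raw p-values.
- **Subtype ANOVA**: one-way ANOVA on raw (untransformed) proportions;
  adjusted R² = 1 − (1 − R²)(n − 1)/(n − g) from the between/total sums of
  squares; the significance flag uses p < 0.001.  Subtypes with fewer than
  two defined samples are dropped with a warning.
- **Trend test**: Spearman rank correlation between time and proportion,
  requiring ≥ 3 distinct time points; constant proportions yield an
  undefined result rather than a spurious rho.

Elementary statistics (Welch t, ANOVA F, Spearman, Pearson, BH) are
delegated to scipy/statsmodels; the compositional bookkeeping, adjusted R²,
and all tie-break rules are defined here.

## Correlation screen

For each candidate gene, Pearson correlations are computed on
pairwise-complete observations against every configured isoform proportion
in every configured measurement layer (e.g. cohort mRNA, cohort protein).
Correlations are undefined (with a reason code) below `min_n = 10` complete
pairs or for constant vectors.  A gene is flagged when its maximum |r| over
all (layer × isoform) pairs **strictly** exceeds the threshold (default
0.4).  Both the layer list and the isoform list are configuration, so the
"maximum over three values" can be read either as three layers or as three
isoform ratios.  Expression is used as provided; a `--log2` switch applies
log2(x + 1).  Factors are ranked across cohorts by the number of cohorts in
which they were flagged, ties lexicographic.

## Pre-ranked GSEA

Genes are ranked by their correlation with an isoform proportion
(descending; ties broken by gene id so the ranking is deterministic).  For a
gene set S with n_S members present in a ranked list of N genes, the
running sum increments at hits by |s_i|^p / Σ_{j∈S} |s_j|^p and decrements
at misses by 1/(N − n_S); the enrichment score is the running-sum value of
maximum absolute deviation.  Weight p = 1, the classic choice.  If all
member scores are zero under p > 0, increments fall back to equal weights
(logged).  When the positive and negative extremes tie in magnitude within
1e−9, the earliest walk position wins — this keeps the score stable against
floating-point noise and makes two algebraically equivalent implementations
(the O(N) walk used for the public API and the hit-position form used for
permutations) agree to machine precision.

Because the input is pre-ranked, phenotype permutation is unavailable; the
null resamples member labels uniformly from the ranked universe.  Per set,
`n_perm` null scores are drawn (seeded); NES = ES / mean |null ES| of the
same sign; nominal p is the same-sign null tail fraction (reported as
1/n_perm when no same-sign null exists); FDR follows the standard pooled
positive/negative NES procedure, with BH on nominal p as an alternative.
Set sizes are bounded to [5, 500] after intersection with the ranked
universe.  Identical seeds give bit-identical results.

## Synthetic cohorts

The generator emulates the statistical structure of junction-count cohorts:

- **Isoform counts** (per sample): true proportions p ~ Dirichlet(α_group);
  depth ~ negative binomial (mean 2000, size 10, floored at 1); noise reads
  ~ Binomial(depth, noise_fraction) are placed on a spurious acceptor
  inside the first intron — anchor-donor but unmapped, so the
  `unclassified` path is exercised deterministically — and the remaining
  reads are Multinomial(p).  The default label order and the default
  composition (0.61, 0.15, 0.14, 0.10) follow the abundance order observed
  in healthy-tissue junction data.  Group α vectors with total
  concentration ≈ 100 give a between-sample proportion sd ≈ 0.05, a
  realistic cohort spread; concentration is the dial for tissue
  homogeneity.  noise_fraction is capped at 0.05 — spurious exon-4
  acceptors are rare in practice.
- **Correlated expression**: a target gene with planted correlation r is
  r·z + sqrt(1 − r²)·ε, with z the standardized isoform proportion and ε
  unit normal, so the population correlation is exactly r; background genes
  are independent noise.
- **EMT time courses**: one isoform's proportion follows a monotone
  logistic interpolation between the start and end levels, with truncated
  Gaussian noise on (0, 1); the other isoforms keep their relative base
  composition scaled to the remainder, so every row stays on the simplex.
  The logistic half-range (steepness) defaults to 3: each of ~5 sampled
  time points then shows appreciable progression, as in published EMT
  induction series; much larger values degenerate toward a step function
  whose flat ends are indistinguishable under measurement noise.

One global seed spawns an independent stream per sample
(`numpy.random.SeedSequence.spawn`), so sample subsets are reproducible on
their own and identical seeds reproduce files byte-for-byte.

What the generator does **not** emulate: read-level errors and alignment
ambiguity, GC/length biases, overdispersion beyond Dirichlet-multinomial,
correlated noise between samples (batch effects), and realistic expression
distributions (backgrounds are Gaussian scores, not counts).  Tests passing
on these cohorts therefore demonstrate the correctness of the counting,
classification, and statistical machinery — not robustness to upstream
alignment artifacts.

## Numerical and design notes

- Proportions are exact integer ratios; conservation (Σ counts = total) and
  scale invariance hold identically.
- Pearson correlations are clipped to [−1, 1] against rounding.
- All rankings break ties lexicographically on the entity name, so outputs
  are stable under input permutation.
- Problem sizes in the test suite and acceptance script (cohorts of 100–200
  samples, 200 replicates, 200–500 permutations, ranked lists of 200 genes)
  were chosen as the smallest sizes at which the targeted statistical
  properties are sharp; all complete in seconds.
- The gene model ships as an editable YAML config with toy coordinates;
  real hg38 coordinates can be filled in from a GTF (the file documents
  how).  No genomic coordinates are hard-coded as ground truth.

## Known limitations

- The classifier is anchored to one configured gene; it generalizes by
  config, not to GTF-wide discovery of microexon events.
- Full-length isoform structure is not resolved — junction reads identify
  only the first downstream exon; long reads would be needed for more.
- The ANOVA operates on raw proportions; no logit or arcsine transform is
  applied (a transform column could be added where compositional
  heteroscedasticity matters).
- The GSEA null is gene-label resampling; it does not model inter-gene
  correlation, so nominal p on strongly co-expressed sets is optimistic —
  a caveat shared by all pre-ranked GSEA implementations.
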