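# Methods

## Pangenome clustering

Gene clusters are built by deterministic greedy centroid clustering on
amino-acid k-mer sets. Genes are visited in lexicographic `gene_id`
order; a gene joins the first existing cluster (creation order) whose
*founder's* k-mer set has Jaccard similarity ≥ the threshold, else it
founds a new cluster. Defaults: k = 4, threshold 0.7. The founder-as-
centroid rule keeps the procedure order-stable and testable against a
naive all-pairs oracle; production pangenomes computed with
blastp+MCL-style workflows enter through the membership-table import
path instead, which is the fidelity route for real data.

Core/accessory partition: a cluster is core iff detected in at least
⌈f·N⌉ of the N genomes, f = 1.0 by default (strict presence in all
genomes). A small epsilon guards the ceiling against binary-float
artifacts (0.8 × 5 must need 4 genomes, not 5). The partition is always
exhaustive and disjoint, and lowering f can only grow the core.

## Read recruitment

The bundled pseudo-mapper is an exact k-mer screen (k = 21): a read maps
iff ≥ 5 of its k-mers occur in the genome on either strand. Mapped reads
are assigned to the gene whose interval holds the majority of matched
k-mer start positions; ties are discarded from per-gene counts
(conservative, union-style counting). Multi-mapping across genomes is
allowed — competitive screening treats each genome independently, as in
all-against-all alignment. Reference selection ranks genomes by mean
mapped reads across libraries, then mean mapping rate, then genome id.
The pseudo-mapper is a desk-scale screen, not an aligner: no gaps, no
qualities, no SAM output; real aligner summaries are imported as
library/genome/mapped/total tables, with rates recomputed rather than
trusted.

## Differential expression

The test operates on **raw counts**; TPM (rate = count/length·10³,
scaled to 10⁶ per sample) is computed only for reporting and export.
Feeding a count model with rescaled values would invalidate its variance
assumptions, so the two streams are kept separate by construction.

Per contrast (treatment vs biotic control, all timepoints pooled by
default, or one sampling day in per-timepoint mode):

- **Size factors**: median-of-ratios with the all-positive-gene
  geometric-mean reference.
- **Dispersion**: per-gene method-of-moments on normalized counts within
  condition groups, α = max(0, (s²−μ)/μ²), pooled with weights (n−1);
  a parametric trend α(μ) = a₀ + a₁/μ is fitted by non-negative least
  squares over informative genes, and the working estimate is the
  arithmetic blend w·trend + (1−w)·raw with w = m₀/(m₀+df), m₀ = 8
  prior degrees of freedom (df = residual degrees of freedom). With few
  replicates the estimate leans on the trend, which is what makes the
  test usable at n = 3 per group. Floor 10⁻⁸.
- **Wald statistic**: group rates q = (Σy + ½)/(Σs) (the ½
  pseudo-fraction keeps zero-count groups finite), LFC = log₂(q_t/q_b),
  SE² = (1/I_b + 1/I_t)/ln²2 with Fisher information I = Σ μ/(1+αμ),
  two-sided normal p-value.
- **Cook's distance**: D = r²_P·h / (p(1−h)²) with NB working weights,
  p = 2 coefficients, flagged when max D > F(2, n−2) at the 99th
  percentile. D is evaluated at the **trend** dispersion, not the
  gene-wise estimate: an outlier inflates its own gene's dispersion
  estimate and would otherwise mask itself. Flagged genes are dropped
  from testing (status `outlier`), not refit. Note a structural limit:
  at 3 vs 3 a single wild replicate is absorbed by the fitted group mean
  and its Cook's distance cannot exceed the F threshold; outlier control
  becomes effective from ~5 replicates per group.
- **Filtering and FDR**: genes with mean normalized count < 1 get status
  `low_count`; outliers and low-count genes are excluded from the BH
  step-up, which runs over the remaining p-values (missing values pass
  through). DE ⇔ padj < 0.05, direction by LFC sign.

Calibration: under a simulated NB null (α = 0.1, 3 vs 3, 2,000 genes)
the raw p < 0.05 rate is ≈ 0.055–0.07 — the Wald statistic with plug-in
dispersion is known to be slightly anticonservative at three replicates,
and BH discoveries at this scale are essentially zero. Power on planted
|log₂FC| = 2 signals at 5 vs 5 and moderate counts is ≈ 99–100%.

The regularized-log reporting transform is log₂(count/s + 1); it is
never used for testing.

## CA-Metatranscriptome

A cluster is flagged in a (treatment, direction) layer when ≥ 1 of its
reference-genome member genes has that DE status in that contrast; a
cluster may carry both directions. The headline fraction counts a
cluster as DE when flagged in **any** layer (clusters recur across
treatments but count once), so

core % = 100 · |DE ∩ core| / |DE|,  accessory % = 100 − core %.

Per-treatment tallies and per-direction gene counts are also emitted.
With zero DE clusters the percentages are reported missing, never 0/0.
Reference genes absent from every cluster are reported as orphans.
Detection layers report the continuous mean covered fraction per
(sample, cluster); for presence/absence displays a cluster counts as
detected at mean fraction ≥ 0.5 (the cutoff is a display convention,
not part of any statistic).

## Synthetic data

The generator emulates the target study design: treatments BC, DISP,
WAF, CEWAF, CEWAFN; triplicates; sampling days 0/7/17/28/42 with CEWAFN
at 0/7/42 only (69 libraries). Defaults, chosen once as a realistic
desk-scale stand-in for a genus-level pangenome experiment:

| parameter | default | note |
|---|---|---|
| genomes | 10 | |
| core / accessory clusters | 300 / 500 | accessory occupancy Bernoulli(0.5), ≥ 1 genome |
| gene length | 300–900 nt | uniform, multiples of 3 |
| per-copy aa mutation rate | 0.005 | keeps member↔founder Jaccard ≈ 0.9, well above the 0.7 clustering threshold |
| NB dispersion α | 0.1 | typical bulk RNA-seq overdispersion |
| baseline mean | 100, log-normal sd 1 | per-gene |
| library size factor | log-uniform [0.5, 2] | |
| planted DE genes | 250, |log₂FC| = 2 | one per chosen cluster, random non-BC treatment and sign |
| ρ_core | 0.4 | fraction of DE-containing clusters that are core |

DE genes are placed by first choosing round(ρ·n) core and the remaining
accessory clusters among those containing the reference genome, then
planting one DE gene per cluster, so the truth's core DE fraction equals
ρ up to rounding. Each artifact (pangenome, counts, reads) draws from
its own RNG stream spawned from (master seed, fixed tag): adding an
output never perturbs the others, and identical configurations are
byte-identical. A cross-check routine (`validate_truth`) asserts the
emitted truth against the emitted data.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: sequencing error profiles and
quality scores, paralogy and domain shuffling (clusters are point-mutated
copies, so clustering recovery on real proteins will be harder),
community context (one species at a time), compositional effects between
species, batch effects, and time-varying expression within a treatment.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale: 2,000
genes for null calibration, 100 planted signals for power, 20 genomes ×
500 clusters for partition recovery, and the default simulation
(~5,500 genes, 802 recovered clusters, 265 DE clusters) for the
end-to-end fraction — sizes at which every stage completes in seconds
while keeping the Monte-Carlo error of the checked rates small relative
to their tolerance bands. The published genome-scale totals (1,598 and
826 clusters from 77 and 171 NCBI genomes; tens of millions of SRA
reads) require the deposited external datasets and are represented here
only through the worked-example fraction computation, which takes the
printed DE-cluster counts as input.

Ties in greedy clustering are impossible by construction (first match in
creation order); ties in read→gene assignment discard the read from
per-gene counts; all-zero TPM columns stay all-zero; zero usable
reference genes for size factors raise an error suggesting a
pseudocount fallback rather than silently imputing one.
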