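# Methods

## The analysis model

The package targets a specific study design: a diploid plant propagated
vegetatively (by cuttings) for a known number of years, with around a dozen
clonal individuals whole-genome resequenced at moderate depth, a subset of
them re-sequenced in triplicate, and two related outgroup taxa available for
polarization. Somatic mutations are genotype differences among clone-mates.
Three structural facts of clonal inheritance drive the downstream analyses:

1. every mutation present in a cutting's parent sector is inherited by the
   cutting, so carrier sets of shared mutations are nested (or disjoint) and
   reconstruct the propagation pedigree as a perfect phylogeny;
2. a mutation shared by several individuals arose once, on one haplotype, so
   in phased data its carriers must show it co-phased with the same flanking
   heterozygous alleles;
3. calls are dominated by artifacts unless read-level evidence (strand
   balance, residual-allele checks) and replicate concordance are used to
   calibrate the error rates that enter the rate estimate.

## Rate estimation and calibration

The corrected rate is `mean_count × (1 − fp) / (years × 2 × G × s)` with `G`
the haploid genome size and `s` the detection sensitivity. Two deliberate
design choices:

**Replicate concordance measures erroneous calls, not read-sampling noise.**
Each replicate is pushed through the same filter cascade as the main call
set, and a candidate is any confident genotype departing from the clone
founder (majority) genotype whose allele claim is supported: a gained allele
needs at least one supporting read, a lost allele needs zero residual reads
at informative depth. The strand-bias ratio test is *not* applied inside the
concordance protocol: it is a stochastic read-level filter whose
per-replicate pass rate at 25× is far from 1, and including it would make
the three-way intersection measure sampling recall (≈ r³) rather than
erroneous calls — the `(1 − fp)` term of the formula corrects for false
calls, and the union/intersection protocol is only a valid estimator of that
quantity when per-replicate recall of true candidates is near 1.

**Loss-of-allele calls require dropout-proof depth.** At 25× a heterozygous
site yields all-one-allele reads with probability 2^(1−d) for depth d —
about 7 × 10⁻⁶ per genotype, which over a few times 10⁴–10⁶ heterozygous
sites produces confidently wrong homozygous calls that masquerade as
het→hom somatic events and (being replicate-independent) inflate the
false-positive estimate. A carrier may therefore only be declared to have
*lost* an allele when its depth makes dropout negligible: 2^(−d) < 10⁻⁶,
i.e. d ≥ 20 reads (`somaclone.calling.LOSS_DEPTH_MIN`). Gains
(hom→het) are instead gated by the two-strand test.

**Spike-in zygosity.** `spike_in_sensitivity` defaults to homozygous
spike-ins, the convention of read-modification sensitivity protocols. The
pipeline's own rate correction passes `zygosity="het"`: the mutations being
corrected are heterozygous, and only spike-ins at the same allele fraction
estimate the caller's recall of them (the suite verifies that heterozygous
spike-in sensitivity matches empirical recall within binomial error).

Confidence intervals are a nonparametric percentile bootstrap (1000
replicates) over the per-sample counts; no distributional form is assumed.

## The synthetic generator

`SimConfig` describes one study. Defaults are the study conditions the
package is built around, chosen once:

| parameter | default | rationale |
|---|---|---|
| `genome_length`, `n_chromosomes` | 408 Mb, 19 | poplar-scale diploid genome |
| `gc_content` | 0.35 | placeholder composition, not an estimate |
| `het_density` | 8 /kb | ≈ 3.3 M heterozygous sites on 408 Mb: elevated clonal heterozygosity |
| `pedigree_newick` | 11 leaves, 67 y | cutting pedigree with one four-leaf cluster; all root-to-tip paths 67 y |
| `snv_rate`, `indel_rate` | 9.24e-9, 1.77e-9 /bp/yr | study-scale rates |
| `context_multipliers` | CpG 2.5, CHG 1.5, CHH 1, non-C 1 | methylation-linked elevation typical of plant spectra |
| `mean_depth` | 25× | per-sample short-read depth |
| `seq_error` | 0.005 /read-base | Illumina-scale error |
| `strand_imbalance_sd` | 0.05 | mild forward/reverse dispersion |
| `n_replicate_samples` | 5 | five samples sequenced in triplicate |
| `phase_block_bp` | 500 kb | phase-set N50 of a long-read scaffold |

Mechanics: per-branch SNV counts are Poisson with mean
`snv_rate × years × 2 × genome_length`; positions are uniform then thinned
by the *relative* context multiplier (rejection sampling), so multipliers
shape where mutations land while `snv_rate` remains the genome-wide mean
rate — recovery tests compare against `snv_rate` directly. Mutations avoid
positions already heterozygous or mutated (collisions are redrawn and
counted), so simulated truth transitions are hom→het; het→hom and
hom→hom-alt classification is exercised with hand-built genotype tables in
the unit tests. Indels are 1–10 bp, geometric(0.5) length, insertion or
deletion with equal probability. Reads are Poisson depth, binomial allele
sampling at VAF 0.5 (het) or `seq_error/3` (hom-ref), binomial strand split
with a Normal-dispersed per-site strand probability; genotypes are called by
a three-hypothesis binomial likelihood with GQ the Phred-scaled margin.
Site-level INFO annotations are drawn from mostly-passing null
distributions. Triplicates share all truth and differ only in read draws.
Phased genotypes are emitted from truth in fixed-size phase blocks with the
haplotype label randomly flipped per (sample, block), as a read-based phaser
would produce. One run seed drives everything through named sub-streams, so
identical configurations are byte-identical and stages can be re-run alone.

What the generator does **not** emulate: alignment and mapping artifacts,
coverage heterogeneity along the genome (depth is position-independent, so
"callable fraction" effects are absent), CNV/SV signal beyond user-supplied
mask intervals, linked selection, indel-realignment errors, switch errors in
phasing, or somatic mutations at already-heterozygous sites. Passing tests
therefore demonstrate the statistical machinery is correct under the stated
read model, not that real-data artifact modes are handled.

## Numerical and procedural choices

- All printed percentages round half away from zero; one decimal by default,
  two where the quantity is conventionally printed with two.
- Hard-filter comparisons are strict, exactly as printed (`FS > 60` removes
  61 and keeps 60); missing annotations make a rule non-evaluable.
- Depth bounds use per-sample means over the filtered input; depth and GQ
  violations mask the genotype, and missingness (strictly > 25%) is
  assessed after masking. Indel footprints span
  `pos … pos + max(len(ref), len(alt)) − 1`, padded by 5 bp on both sides.
- The founder genotype is the majority among non-missing clone-mates; ties
  break toward the homozygous-ancestral genotype when outgroups are
  supplied, else toward the lower genotype code.
- SV masks require strictly more than half of samples to support a region
  (per SV type, breakpoint-sweep counting); containment uses half-open
  intervals, so the last covered base of an interval is masked.
- Context enrichment is normalized to the non-cytosine baseline class (the
  class that carries no methylation-linked elevation); a genome-mean
  normalization is also emitted (`enrichment_vs_mean`) but the baseline
  version is the one a multiplier-recovery experiment inverts. Significance
  is an exact two-sided binomial test of context-vs-baseline mutation
  counts against the corresponding genomic site share, BH-corrected.
- Pedigree reconstruction is greedy: carrier sets placed largest-first,
  accepted when nested or disjoint with all accepted clades; conflicts are
  reported as homoplasy, never placed. Equal-size conflicts resolve in
  genomic order. The output is deterministic and, on compatible matrices,
  invariant to input permutation.
- The haplotype identity test anchors each shared call on the nearest
  neighbor site heterozygous and phased in the same phase set for every
  carrier; single-carrier calls with an anchor are reported "phased"
  (cross-carrier identity needs two carriers). No anchor → "unphased".
- Heterozygosity-vs-distance profiles report per-bp heterozygous-genotype
  density and per-bp nucleotide diversity (π as mean pairwise difference
  with the 2n/(2n−1) small-sample factor); bin denominators are exact
  merged-interval base-pair counts, and empty bins are missing, not zero.
- Recombination windows are grouped by exact somatic count with the top
  class pooled (0,1,…,≥6 for seven groups; a quantile mode exists), then
  unweighted OLS of group mean ρ on group index with a two-sided slope test,
  skipped with a warning when fewer than two groups are populated.
- The annotation test is a Yates-corrected two-cell goodness-of-fit
  (in-class vs not) against the expected genomic fraction, df = 1.

## Problem sizes in the test suite

Unit tests run on 100 kb – 3 Mb genomes. The statistical acceptance checks
use the sizes their scenarios state: rate recovery simulates cohorts of
eight independent 10 Mb, 10-leaf, 67-year studies per seed at 25× and
averages their corrected estimates (a single 10 Mb study realizes only ~7–27
mutations per sample, so one study's Poisson fluctuation would dominate the
calibration error under test); context recovery uses 5 Mb with ~3,600
mutations; pedigree recovery 1 Mb with ≥ 20 mutations per branch. The full
suite completes in a few minutes on one CPU.

## Known limitations

- Sensitivity calibration shares the generator's read model with the data it
  calibrates; on real data the spike-ins would have to be injected into
  reads (the published approach) rather than drawn from the model.
- The union-based false-positive protocol triple-counts replicate-private
  artifacts, so `fp_rate` is a conservative (upward-biased) estimate of the
  false-call fraction; with the dropout-proof loss rule the bias is small.
- `point_rate` with study-scale printed inputs reproduces the printed rate
  only to ~0.5%: the printed inputs are themselves rounded.
- Multiallelic sites are excluded at VCF ingestion (counted), not
  decomposed.
- The greedy perfect phylogeny has no error model; a single miscalled
  carrier turns a true clade mutation into homoplasy rather than perturbing
  the topology.
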