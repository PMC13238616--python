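# Methods

`abalonepg` re-implements, as a tested and config-driven pipeline, the
whole-genome population-genomics workflow used to study a marine mollusk
(Northern abalone-like) population that is weakly structured, extremely
diverse, and recovering from a severe census decline.  Every statistic is
exercised end-to-end on forward Wright–Fisher simulations whose ground
truth is known, so each claim the pipeline makes about real data has a
matching parameter-recovery or oracle test.

## Dataset stratification and QC

Variants pass three filters, in a fixed order that is part of the
contract: (1) per-genotype depth masking — a call whose depth falls
outside [4, 30] (≈⅓× to 3× a 10× mean coverage) becomes missing; (2)
non-biallelic records and indels are removed; (3) sites with more than
15% missing calls (evaluated **after** masking) are removed.  Whether a
depth filter of this kind acts per genotype or on mean site depth is
ambiguous in common tooling; the per-genotype reading is adopted because
it is deterministic and testable, and the choice is surfaced here rather
than hidden.  Samples with more than 15% missing calls are flagged, never
silently dropped — exclusion is an explicit subset in the driver.

The filtered ("full") dataset is split by minor allele frequency computed
across all individuals: **common** (MAF ≥ 0.05, used for differentiation
and structure) and **rare** (MAF < 0.05, used for occupancy/connectivity).
The boundary MAF = 0.05 goes to common; a MAF tie at 0.5 takes the alt
allele as minor (nothing downstream depends on it).  Missing genotypes are
excluded from every frequency denominator and never imputed; the one
exception is PCA (below).

## Diversity

* **π** per site is the unbiased estimator (n/(n−1))·2p̂q̂ with n the
  non-missing allele count; a window's value is Σπ_site divided by the
  window's physical length (per-bp π), so monomorphic windows meaningfully
  report 0.  Windows are non-overlapping 50-kb tiles; the terminal partial
  tile keeps its true length as denominator.
* **Tajima's D** uses the canonical 1989 constants.  With missingness the
  allele count varies across sites, so one window-level n is required: the
  median non-missing allele count over the window's segregating sites — a
  robust choice among several defensible ones.  D is undefined (NaN) when
  S = 0 or n < 4.  A group-level "mean D" does not fix a weighting, so
  both the unweighted window mean and the S-weighted mean are reported.
* **Individual heterozygosity** is het calls / non-missing calls per
  sample, on whichever stratum is supplied.

## Differentiation

Per-SNP FST is the Weir–Cockerham (1984) two-population diploid estimator
θ̂ = a/(a+b+c) built from the among-population (a), between-individual (b)
and within-individual (c) variance components, with unequal sample sizes
and observed heterozygosity; sites where either group has < 2 non-missing
genotypes are undefined; negative estimates are reported as-is.  Windowed
FST is the **ratio of sums** Σa/Σ(a+b+c) — not the mean of per-SNP ratios,
which is biased upward by low-information SNPs (the per-SNP *mean* is still
reported because published per-SNP averages use it).

Outlier windows use the nearest-rank empirical percentile (default 99.9)
over defined windows, with an optional minimum-scaffold-length filter
(default 125 kb) because outliers on very short scaffolds are likely
artifacts.  Top-N ranking breaks θ̂ ties by genome order so results are
reproducible.  Fixation calls (fixed_ref / fixed_alt / variable) require
exact 0/1 frequencies by default, with a configurable tolerance; "shared
fixed differences" between two units count SNPs where both are fixed for
the same allele opposing a group fixed for the other allele.
Closest-gene assignment is strand-agnostic bp distance to interval edges;
BED (0-based half-open) and GFF3 (1-based inclusive) are both converted to
the internal 1-based half-open convention in one place.

## Population structure and the detectability scan

PCA uses EIGENSTRAT-style normalization — center by 2p̂, scale by
√(p̂(1−p̂)) — with missing calls mean-substituted (they contribute zero
after centering), monomorphic sites given zero weight, a full SVD, and
signs fixed by forcing each PC's largest-magnitude loading positive.

Published analyses of this kind judge "structure detected" from PCA plots
by eye; that is not testable, so separation is quantified as the
two-group standardized mean difference of PC1,
|mean_A − mean_B| / pooled within-group SD, with detection declared above
2.0.  The threshold was chosen so that clean two-cluster toys always pass
and label-free noise essentially never does (null separations on random
genotype matrices sit well below 1.5); it is configurable.  The scan draws
either random SNP subsets (several replicates per size) or the
deterministic top-N by FST, runs PCA, and reports per-size separation.

## Runs of homozygosity

Detection is the classic scanning-window hit-rate algorithm with the
standard tool's v1.9 defaults (window 50 SNPs, ≤ 1 het, ≤ 5 missing per
window, hit-rate ≥ 0.05, ≥ 100 SNPs, gap ≤ 1000 kb, density ≥ 1 SNP/50 kb)
and the minimum segment length overridden to 100 kb — appropriate for a
high-diversity invertebrate whose ROHs are short.  Segments of one sample
on one scaffold are disjoint by construction and re-checked post hoc.

Cross-individual collapsing is single-linkage: two segments link when
their overlap exceeds 50% **of the longer segment** (the stricter of the
plausible readings of "overlapped by more than 50%"; `shorter` and
`reciprocal` denominators are available).  The consensus interval of a
cluster is the median member start to the median member end — the
construction used by the published analysis is unstated, so this
assumption is surfaced.  Location sharing is the Gram matrix M = XᵀX of
the (unique ROH) × location carrier-count incidence; it is symmetric PSD
and its diagonal counts within-location sharing.  F_ROH is the genome
fraction in segments ≥ 1.5 Mb (the inbreeding-linked length class), with
the genome length taken from the VCF header scaffold lengths.

Coalescent ages use t = 100/(2·L·r) generations (L in Mb, r in cM/Mb):
recombination erodes IBD tracts, so long segments are young.  Ages are
exactly ∝ 1/r, which is why every dated quantity is reported at r ∈
{0.5, 1, 2} cM/Mb, the span of measured mollusk recombination rates.

## Rare-allele occupancy

"Singleton/doubleton" follows the occupancy usage: a variant carried by
exactly one individual as one (het) or both (hom) alleles.  This is not
the classical allele-count definition; both nomenclatures appear in the
docstrings to prevent confusion.  "Private" means carried in one sampling
location.  All fractions are recomputable from the per-site records;
display rounding (whole %, het share at 0.1%) never feeds back into
computation.

## LD-based Ne trajectory

Input preparation mirrors the standard protocol: thin to > 1 kb spacing
(greedy left-to-right), keep scaffolds ≥ 10 Mb, randomly cap at 500k SNPs
(all three scale down for simulated genomes; the thinning log records
every count and seed).  For same-scaffold SNP pairs, bp distance maps to
Morgans via the assumed rate and to recombination fraction c through the
Haldane function c = (1 − e^(−2d))/2.  LD is the squared genotype
correlation (Rogers–Huff style, unphased, pairwise-complete over missing
calls), adjusted for sample-induced association by r²_adj = r² − 1/n
(1/(2n) available for phased-equivalent data).  Pairs land in 20
log-spaced c bins spanning t ≈ 5–140 generations via t = 1/(2c̄); bins
with fewer than 100 pairs are undefined.  Replicate spread comes from 40
SNP-bootstrap replicates (a pair enters with the product of its SNPs'
bootstrap multiplicities).

Two inversions are provided:

1. **Per-bin Sved inversion** — Ne(t) = (1/r²_adj − 1)/(4c̄) per bin.
   Simple and accurate for near-constant histories (constant-N recovery
   within a factor of ~1.3 in the tests), but it assigns each map distance
   a single Ne, so a recent drift burst — which adds ≈ Σ_g e^(−2cg)/(2N_g)
   to r² at *every* distance — contaminates the ancient bins and caps the
   apparent ancient size.
2. **Epoch deconvolution** — under piecewise-constant Ne the same
   superposition is linear in 1/(2N_j), so the binned decay is inverted by
   smoothed nonlinear least squares in log space over ~11 log-spaced
   epochs (all sizes strictly positive; truncation at 300 generations).
   The first-difference smoothing weight (0.3) was calibrated on
   constant-size and two-epoch simulations: constant histories stay within
   a factor of two of truth across the reported range, while a genuine
   2000 → 40 → 200 crash-and-recovery is resolved (recent ≈ 170 vs
   ancient ≈ 2200 against truths 200 and 2000).  This estimator is used
   wherever the question is *contrast between epochs*; the per-bin
   inversion remains the reference level estimate.

Neither estimator re-implements the genetic-algorithm fitting of the
dedicated reconstruction software; trajectories are comparable in shape,
not in exact values, to that tool's output, and no quantitative claim is
made at that level.

Time axes: the bin definition uses recombination fractions, so `t`
( = 1/(2c̄)) scales only approximately as 1/r across assumed rates — the
Haldane map is nonlinear.  The reported `t_linear` ( = 1/(2d̄), map
distance) scales exactly as 1/r and is the axis used for rate-sensitivity
statements.

## The synthetic-data generator

A forward-time Wright–Fisher diploid simulator with: equilibrium-SFS
initialization in place of burn-in (site count ~ Poisson(θL·Σ1/i),
derived-copy numbers ∝ 1/i); fitness-weighted parent sampling with
additive selection (1, 1+s/2, 1+s) restricted to the advantaged deme —
an entry for the ref allele at the same position expresses antagonistic
local adaptation; migrant offspring with probability m; Poisson(rate·L)
crossovers with uniform breakpoints, scaffolds assorting independently;
infinite-sites mutation at unused positions; fixed sites pruned each
generation (counted).  Output is a genotype matrix with two groups mapped
over pseudo-locations, written as VCF 4.2 + metadata TSV + ground-truth
JSON, byte-reproducible from the seed.

The SFS initialization seeds correct *diversity* instantly but no
*haplotype structure*: LD-dependent analyses therefore only read epochs
the simulation has actually run (roughly 1/(2c) generations for map
distance c), and every scenario below respects that.

Scenario presets (the study conditions for the tests; genome sizes of
2–6 Mb and population sizes ≤ 2000 keep a full run in seconds to a few
minutes on one core):

* **Two demes with concentrated selection** (5 × 600 kb scaffolds,
  N = 1000 per deme, 12-generation split, μ = 10⁻⁷, 8 antagonistic loci
  with s = 0.5 along scaffold 1).  A recent split of a large population
  keeps neutral background FST near T/(4N) ≈ 0.005 — low enough that tens
  or hundreds of random SNPs carry no usable signal at the separation
  threshold — while selection drives the designated loci most of the way
  to alternative fixation.  This reproduces, at reduced scale, the
  published pattern: structure invisible in small random panels, obvious
  in ten top-FST SNPs, with the outlier windows and top-SNP concentration
  on a single scaffold.  The split duration was set from measured margins
  across seeds (longer splits push the 100-random-SNP separation into the
  detection band; shorter ones leave selection too little time).
* **Severe bottleneck with modest re-expansion** (3 × 1 Mb, μ = 6×10⁻⁸):
  N = 50 ancestral → 2000 at ~225 generations before sampling → 40 for 5
  generations → 200 for the last 20.  The long-term expansion is what
  produces the genome-wide rare-allele excess (negative Tajima's D,
  single-individual variant surplus); the recent census crash is
  coalescently mild — it barely dents the SFS — but its drift burst is
  unmistakable in LD.  That separation of signals is the scientific point
  the scenario encodes: a recent bottleneck alone *prunes* rare alleles
  and pushes D positive (verified against an independent coalescent
  simulator), so a "decline with negative D" necessarily implies deeper
  expansion.
* **Constant N = 500** (4 × 1.5 Mb, μ = 10⁻⁷, 250 generations of run-in)
  for Ne-recovery calibration, and a **dense-SNP ROH scenario** (N = 500,
  5 generations, μ = 2×10⁻⁷, high recombination) whose short run and
  rapid map keep the background free of genuine long IBD tracts so that
  planted tracts have known truth.

Simulated recombination is 10–100 cM/Mb — far above the ~1 cM/Mb assumed
for real data — purely to compress the informative map-distance range
onto Mb-scale scaffolds; analyses always use the simulation's true rate.

What passing tests do **not** show about real data: the generator has no
sequencing error, no reference bias, uniform depth, a single recombination
rate, free-mixing demes without geography, and sample sizes ~3× smaller
than a real cohort.  Estimator *correctness* (oracle equivalence, exact
arithmetic, recovery of known truth) transfers; absolute power and
calibration on a real 56M-SNP dataset do not.

## Reproducibility

A single global seed fans out to per-stage seeds by hashing the stage
name (CRC32), so any randomized stage can be re-run alone with its logged
seed; every output table carries its parameters in header comments, and
`summary.json` is byte-identical across reruns with the same inputs and
seed.

## Known limitations

* Tajima's D with heavy, non-random missingness leans on the median-n
  choice; extremely patchy data would warrant per-site rarefaction.
* The ROH scanning algorithm inherits the reference tool's insensitivity
  to short, SNP-sparse tracts; with < 1 SNP/kb the 100-SNP gate dominates.
* The LD deconvolution's epoch resolution is log-coarse and its smoothing
  trades variance for a mild flattening of sharp size changes; confidence
  intervals are SNP-bootstrap, not model-based.
* The simulator's SFS initialization under-represents ancestral LD for
  epochs older than the run-in, so trajectory estimates at the oldest
  reported times drift upward on constant histories (visible, and within
  the stated factor-two band, in the calibration runs).
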