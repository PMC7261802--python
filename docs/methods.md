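# Methods

## Scope and model

`domestiscan` re-implements the population-genomic core of a crop
domestication study: windowed diversity (θπ, θw, Tajima's D),
between-population differentiation (Hudson FST, the wild/domesticated
diversity ratio), LD decay, an XP-CLR selective-sweep scan, a
joint-outlier domestication-region caller, population-structure views
(p-distance NJ trees with bootstrap, allele-frequency-normalized PCA),
and genic dN/dS from SNP counts. All coordinates are 0-based half-open
internally; VCF and GFF3 convert at the file boundary.

## Forward simulator

The generator is a discrete-generation Wright–Fisher simulator:
binomial resampling of diploid parents, per-site binary mutation (the
first retained mutation defines the derived allele; a site whose
derived allele is lost may mutate again, a site fixed for the derived
allele is retired), single-crossover-per-meiosis recombination with the
crossover point uniform on the sequence, clean population splits off
the progenitor lineage, per-epoch population sizes, and an optional
additive sweep (fitness 1, 1+s/2, 1+s). Burn-in runs 8N generations
before the most ancient configured event, well beyond the ~4N expected
TMRCA, so initial monomorphism is forgotten. Sampled panels drop sites
monomorphic in the sample, and per-call missingness is applied
independently after sampling. A single seeded generator drives every
draw, so identical configurations are byte-identical.

Two sweep options extend the basic single-copy sweep. With
`initial_frequency > 0` the beneficial allele starts as standing
variation at that frequency with **all copies on one haplotype
background**, so the sweep is hard (every swept lineage coalesces into
the founding haplotype) yet completes within a short domestication
episode — the fixation time of a single new copy at s = 0.1 exceeds
any split time over which allele-frequency drift remains moderate at
desk-scale N. With `sample_at_fixation` the panel is sampled the
generation the allele fixes, the convention of sweep-detection power
studies; without it, at the rescaled mutation rates needed to hold
θ = 4Nμ at realistic per-site values with small N, post-fixation
mutational recovery refills the diversity trough orders of magnitude
faster than it would in real populations.

The simulator is validated against a standard coalescent: mean π
matches 4Nμ within sampling error, mean Tajima's D is ~0 at
equilibrium, and the single-site site-frequency spectrum is
statistically indistinguishable (two-sample chi-square) from msprime
at matched θ.

## Estimator conventions

- Missing data: per-variant chromosome counts n use non-missing calls
  only; Tajima's D constants use the window's median n; per-site
  scaling divides by window span (no accessibility mask exists for
  synthetic data).
- FST: Hudson's estimator with ratio-of-averages window aggregation
  (robust to unequal sample sizes); a two-population Weir–Cockerham
  variant (haploid allele-count form) sits behind `estimator=` for
  sensitivity analysis. Negative windowed values are reported, not
  clamped.
- Diversity ratio: oriented wild/domesticated so that larger values
  mean diversity loss in the domesticate; windows with zero
  domesticated diversity and positive wild diversity are flagged
  infinite and always counted as outliers.
- LD decay distance: the distance at which the monotone-smoothed
  bin-mean r² first falls to half its maximum (configurable to a fixed
  threshold); pairs below a MAF floor of 0.05 are excluded and pair
  counts above 2×10⁶ are subsampled with a seed. The definition is
  stamped into every output because published decay values rarely
  state one.
- dN/dS: Nei–Gojobori unweighted site counting; premature stops count
  as nonsynonymous; codons with several segregating sites are
  classified per SNP against the reference codon. Both pooled-count
  and per-sample-average ratios are emitted.
- p-distance: mean |cA−cB|/2 over jointly non-missing diploid counts,
  matching how distance tools consume unphased VCFs. NJ breaks
  Q-criterion ties toward the lexicographically smallest label pair
  and clamps negative branch estimates to zero, moving the residual to
  the sibling. Bootstrap resamples variants, never samples. PCA
  centers each variant by mean count, scales by √(p(1−p)), mean-imputes
  missing calls, and fixes component signs so the largest-magnitude
  coordinate is positive.

## XP-CLR implementation

The drift parameter ω is a moment estimate of E[(p₂−p₁)²/(p₁(1−p₁))]
over SNPs segregating in the reference, with the binomial sampling
variance of both sample frequencies subtracted (unbiased p(1−p) via
n/(n−1)) and clamped at zero. The neutral density of p₂ given p₁ is
Normal(p₁, ω·p₁(1−p₁)) truncated to (0,1) with the escaped mass as
point masses at 0 and 1. Integration over p₂ uses Gauss–Legendre nodes
placed through the inverse-CDF (probability-domain) transform of the
untruncated normal — the same node budget as a fixed grid on (0,1) but
accurate for arbitrarily small ω, where the density is a spike
narrower than any fixed node spacing; 64 nodes by default, and doubling
them moves scores by far less than 0.1. The sweep model keeps the
neutral density with escape probability c = 1 − exp(−(r/s)·ln 2Ns) and
otherwise drags the frequency to fixation of its background, weighting
fixation by the pre-sweep mean frequency. Scores are
2·maxₛ Σ w·(log-ratio), the s grid includes 0 (ratio 0), so scores are
non-negative by construction. SNP weights are 1/m for clusters of m
SNPs whose reference-population r² exceeds `r2_max`; SNPs nearly fixed
in the reference sample (MAF < 0.05 by default) are excluded because
the drift model's tails are unstable there. Physical distance converts
to genetic distance with a single uniform cM/Mb rate. Polarized
(ancestral-state) frequencies are used throughout, as the simulator
provides truth.

## Region calling

Quantiles are computed genome-wide over finite window values; ties at
the threshold are included and infinite-flag windows always pass. A
window is selected when its own mask is true and at least one selected
XP-CLR grid point lies inside it; selected windows within `merge_gap`
collapse into one region whose span runs from the first to the last
selected window (bridged gaps are inside the region). Genes overlap
regions by at least `min_overlap_bp` (half-open arithmetic: an abutting
gene does not overlap).

## Canonical synthetic study conditions

Scenario presets (`domestiscan.scenarios`) define the conditions under
which the pipeline's statistical behaviour is demonstrated; effective
sizes are illustrative round numbers, as the organism's true history is
not inferred here, and mutation rates are rescaled so θ = 4Nμ holds
realistic per-site values at simulable N.

- Neutral calibration: constant N = 50, θ = 0.005/site, 10 kb loci,
  20 sampled chromosomes, 500 replicates.
- Differentiation: clean two-population splits at 20/100/500
  generations, N = 50, 30 kb loci, 8 replicates per time point; the
  500-generation (10N) split reproduces the near-fixed differentiation
  regime (genome-wide FST > 0.8) seen between a cultivated species and
  a long-diverged wild relative.
- Sweep scan: ancestral N = 200 expanding to N = 500 at a split 200
  generations before present; 40 wild + 25 domesticated diploids
  sampled over 1 Mb; μ = 6×10⁻⁷, r = 10⁻⁷ per bp per generation
  (10 cM/Mb); hard sweep at s = 0.1 from 10% standing frequency
  introduced at the split, sampled at fixation; planted 3 kb gene at
  the swept site. Scans use a 5 kb grid, 50 kb radius, s grid
  {0, 0.025, 0.05, 0.1}, the true recombination rate, and 20 kb ratio
  windows with a 20 kb merge gap. Twelve sweep and twelve neutral
  replicates are evaluated.
- Structure: FST ≈ 0.1 panels (split 14 generations, N = 50, 100 kb,
  15+15 samples, 2×10⁻⁵ recombination), 50 replicates for PC1
  separation; one deep-split panel (400 generations) for bootstrap
  support.
- Coding: 200 single-exon 300 bp toy genes with SNPs placed uniformly
  in CDS (neutral expectation dN/dS ≈ 1) or only at
  fourfold-degenerate third positions (dN/dS = 0).

## What the synthetic data do and do not show

The generator emulates allele-frequency drift, splits, bottlenecks,
hard sweeps, recombination, and missing calls. It does not emulate
sequencing or genotyping error, uneven coverage beyond random
missingness, gene conversion, migration after splits, selfing, linked
background selection, or reference bias; passing tests therefore
demonstrate the correctness and calibration of the estimators and scan
under the stated models, not robustness to those artifacts.

A desk-scale limitation worth stating plainly: with s = 0.1 a sweep
lasts on the order of 150 generations, during which recombination
(escape) and rescaled-μ mutational input put a floor under the
diversity trough; the resulting wild/domesticated ratio at the swept
window is ~3–6×, comparable to the genealogical noise of per-window π
in 10–20 kb windows at these locus sizes. The XP-CLR localization and
the neutral specificity of the joint rule are strong under these
conditions, but the probability that the exact gene-containing window
clears the genome-wide top-5% ratio cut plateaus near 50–60% — real
domestication data, with deep bottlenecks, long selection episodes and
windows averaging thousands of SNPs, present far stronger ratio
contrasts than any desk-scale rescaling can.

## Numerical and degenerate-input choices

Windows with S = 0 report D as absent, not 0. FST windows with no
usable site report an absent value. Quantile masks require at least 20
finite values. The NJ pair choice and all stochastic components
(simulator, bootstrap, LD pair subsampling, PCA sign) are deterministic
given their seeds; the demo pipeline writes SHA-256 checksums of all
artifacts and reruns byte-identically.
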