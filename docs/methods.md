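# Methods

## The two-pool design

An F2 population from a biparental cross segregates 1:2:1 at every locus.
Sequencing two DNA pools — the `k` highest- and `k` lowest-phenotype
individuals out of `n` — turns a QTL into an allele-frequency contrast: at
a causal locus the high pool is enriched for the high-parent allele, the
low pool for the low-parent allele, and the contrast decays with map
distance at the local recombination rate. All four per-variant statistics
are functions of the 2×2 read-count table (ref, alt) × (high, low) at a
variant where the parents are opposite homozygotes.

Counts are polarized so "alt" always means the high-parent allele
(ref/alt are swapped at sites where the high parent is homozygous
reference). A positive Δ(SNP-index) therefore always reads as
high-parent-allele enrichment in the high pool; negative peaks (low-parent
alleles driving the trait) are detected by thresholding |Δ| two-sidedly.

## Statistics

- `SNP-index = alt/(ref+alt)` per pool; `Δ = index_H − index_L ∈ [−1, 1]`.
- `ED = √[(a_H−a_L)² + (r_H−r_L)²]` over allele fractions; at a biallelic
  site `ED = √2·|Δ fraction|` exactly. Reported raised to a configurable
  power (default 2) to sharpen peaks; the power does not change which
  windows rank highest, only the visual contrast and the threshold scale.
- `G = 2 Σ n ln(n/ê)`, the log-likelihood-ratio test of independence, with
  `ê` from the margins; empty cells contribute 0, and a degenerate table
  (zero row/column margin) is exactly independent, G = 0.
- Fisher's exact two-sided p: the sum of hypergeometric probabilities of
  all tables with the observed margins at most as probable as the observed
  one (relative tolerance 1+10⁻⁷ on the comparison, the convention of most
  statistical software). Implemented vectorized via the hypergeometric
  log-pmf (gammaln) because per-variant exact-test calls are the bottleneck
  of replicate studies; tests verify it against both full enumeration and
  `scipy.stats.fisher_exact`. Benjamini–Hochberg q-values are computed over
  all variants with a defined p.

Sites with zero depth in either pool get NaN for every statistic and are
excluded from window averages; nothing is imputed.

## Windowing

Windows of 1000 kb advance in 10 kb steps (both configurable); window
starts are 1, 10,001, 20,001, …, the trailing windows truncated at the
chromosome end. A window's value is the arithmetic mean of its member
variants' statistic. Windows with fewer than `min_snps_per_window`
(default 10) informative variants are masked rather than zero-filled — an
empty window is absence of evidence, not evidence of absence. Fisher
windows additionally carry the minimum member q-value (q-values are
monotone in p, so this is the q of the window's best variant).

## Thresholds ("99% confidence")

Each statistic uses its native notion of a 99% threshold:

- **Δ(SNP-index)**: a Monte-Carlo null envelope as a function of read
  depth. A null F2 site is simulated as: pool allele count ~
  Binomial(2k, ½) (an F2 genotype is two independent Bernoulli(½)
  alleles), pool frequency = count/2k, read counts ~ Binomial(depth,
  frequency) per pool. The envelope is the 99% quantile of |Δ| per depth,
  interpolated at each window's mean depth. The envelope shrinks with
  depth and pool size but has a floor: with k = 30 the pool itself samples
  only 60 allele copies, so even infinite depth leaves ±≈0.25 of pooling
  noise at the 99% level.
- **ED and G** (default `simulation`): the 99% quantile of null
  *window-mean* values, simulated with the same null-site machinery using
  the design's pool size, each pool's mean depth (Poisson) and the typical
  number of variants per window. The genome-wide empirical quantile of
  observed window values is available as an alternative
  (`ScanConfig.ed_g_threshold_kind = "empirical"`), but it is circular on
  small genomes: when a single strong QTL's selection plateau occupies
  more than 1% of all windows, the 99th percentile falls *inside* the
  signal and the called interval collapses to an unstable top slice. The
  null simulation measures noise, not signal, and is unaffected by how
  much of the genome is truly linked; on large genomes with sparse signal
  the two constructions agree closely.
- **Fisher**: a window is significant when its minimum member q < 0.01.

## Intervals and consensus

Maximal runs of consecutive significant windows form one interval from the
first window's start to the last window's end (gap tolerance 0: a single
below-threshold or masked window breaks the run). Because windows overlap
100-fold at the default geometry, two runs split by one noisy window still
span overlapping base ranges; bp-overlapping intervals of one method are
merged, while intervals separated by ≥ 1 bp stay separate. Consensus uses
a position sweep: events at interval endpoints, maximal stretches covered
by ≥ `min_support` methods (default: all four). For single intervals at
full support this reduces to `[max of starts, min of ends]`. A maximal-
clique formulation of partial support is deliberately avoided; the sweep's
"support count per position" semantics is simpler, linear, and
permutation-invariant. Regions are named qBBN1…N in natural chromosome
order, then ascending start.

## GWAS side

Association rows with p ≤ 10⁻⁵ are kept; duplicate (SNP, model, year) rows
are rejected; the chromosome column is trusted over the SNP-id prefix when
they disagree (a warning is logged). Unique SNPs are single-link-clustered
per chromosome with gap ≤ 100 kb (the LD-decay scale is an input, not
computed from genotypes). Each locus gets a fixed-width window (default
260 kb) centred on the midpoint of its member positions — midpoint
centring, not peak centring, reproduces the published chromosome-2 window
from its two clustered SNPs — clipped at chromosome ends. Locus windows ×
BSA consensus regions are intersected pairwise; genes overlap an interval
under any-overlap (≥ 1 bp) semantics, not containment. Phenotype summaries
use the sample SD, CV% = 100·SD/mean, and the small-sample bias-corrected
(spreadsheet-convention) skewness and excess kurtosis conventional in
agronomic trait tables (moment estimators by flag).

## The simulator

`SimConfig` defaults emulate the motivating experiment: 860 F2 plants
phenotyped for branch number, pools of 30+30, pools ~20× and parents ~30×
(the experiment reported both 20×/30× and 50×/30× in different places, so
both depths are plain parameters), and one strong QTL near 12.3 Mb of a
chromosome-2-like scaffold. The desk-scale genome is 2 × 50 Mb with a
marker every 50 kb (2,000 variants) at 2.5 cM/Mb — enough bases for a
realistic window grid while keeping a replicate under a second; everything
scales up by configuration.

- **Genotypes**: per chromosome, each gamete is a Markov chain over
  markers — first allele fair, each interval switching parental phase with
  Haldane probability `r = (1−e^(−2d))/2`. No interference.
- **Phenotype**: `μ + Σ_q [a_q(g_q−1) + d_q·1{g_q=1}] + N(0, σ)`, truncated
  below at 0 and rounded — branch counts are non-negative integers
  (observed range 0–10), and the rounding produces the heavy phenotype
  ties a real integer trait has, which the pool selection must (and does)
  break deterministically. Baseline μ = 3.4 (the cross midparent), default
  a = 1.5, σ = 1.5: with parental means 6.1 vs 0.7 the cross implies a
  strong locus, and a = 1.5 attributes a bit over half the parental
  difference to the planted QTL. Multiple additive QTLs are supported
  (`extra_qtls`); epistasis is not.
- **Selection**: one stable ascending sort on phenotype; low pool = first
  k indices, high pool = last k. On ties the low pool prefers the smallest
  indices and the high pool the largest — an arbitrary but documented and
  deterministic direction; the pools are always disjoint for k ≤ n/2.
- **Reads**: true pool alt fraction = Σg/2k; depths fixed or Poisson;
  alt reads Binomial(depth, fraction). Parents are fully homozygous,
  fully informative, with an optional contamination fraction (default 0).

What the simulator does **not** emulate: sequencing error, mapping bias,
reference bias, InDel realignment artifacts, segregation distortion, and
uneven marker density. Passing recovery tests therefore establishes that
the statistics, windowing, thresholds and consensus logic are correct and
calibrated under clean pooled-binomial sampling — not that the pipeline is
robust to alignment artifacts in real data (the filter policy exists for
that, with thresholds exposed because the appropriate values are
data-dependent).

## Validation studies and problem sizes

`bsaqtl.validation.run_replicates` runs the two standard studies at the
design above; design-level thresholds (Δ envelope, ED/G null quantiles,
10,000 reps each) are computed once per study and shared across
replicates, since they depend on the design rather than on any one
replicate's reads.

- **Null** (a = 0), 200 replicates: genome-wide mean Δ within 3 SE of 0;
  no four-method consensus called in ≥ 95% of replicates. In practice the
  Fisher q < 0.01 rule is the binding guard: under the null, BH keeps the
  probability of any q < 0.01 near 1%, and a false consensus additionally
  requires the other three methods to fire at the same place.
- **Recovery** (a = 1.5, σ = 1.5), 100 replicates: the consensus covers
  the true position in ≥ 90% and the |Δ| peak lands within 2 Mb in ≥ 90%.
  The 2 Mb tolerance reflects real jitter: extreme-tail selection (30/860
  ≈ 3.5% tails) produces an allele-frequency plateau several Mb wide, and
  the realized peak wanders within it even in the noiseless pool
  frequencies.

## Numerical notes

- Fisher p-values use a 1+10⁻⁷ relative tolerance when comparing table
  probabilities (ties at machine precision count as "as probable").
- G is clipped at 0 against round-off; `xlogy` handles empty cells.
- Quantiles use numpy's default (linear interpolation) estimator.
- `empirical_threshold` refuses fewer than 100 unmasked windows — a 99th
  percentile of fewer values is noise.
- Coordinates are 1-based inclusive everywhere (VCF/GFF convention); BED
  input is converted on read. Window starts satisfy `start ≡ 1 (mod
  step)`.
- All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give byte-identical outputs.

## Known limitations

Two pools only (no multi-pool or RIL designs); no genotype-likelihood
calling; no tricube/G′ or loess smoothing (plain window means only); LD is
an input scale, never estimated; the association model itself (MLM/BLINK)
is upstream of this package — we consume its output table.
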