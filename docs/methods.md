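# Methods

## Orientation model

Every analysis rests on a single orientation rule. A repeat tract is a
maximal run of its unit on the reference strand: homopolymers are runs of
one base (emitted at any length; runs beyond 10 bp are flagged `over_max`
and pooled into a "10+" stratum in length-stratified outputs), and
dinucleotide tracts are whole-unit repeats of the eight orientable units
GT/TG/AC/CA/CT/TC/AG/GA — palindromic units (AT/TA/GC/CG) cannot be
assigned a strand and homo-pair units (AA/…) reduce to homopolymers, so
neither is emitted. Dinucleotide phase ambiguity is resolved by a greedy
leftmost-longest scan: at each position the longest tract starting there is
taken and the scan jumps past it, which guarantees non-overlapping output.

A tract lying fully inside a gene body (annotated start to end, introns
included) is oriented by the gene's strand: its *non-template reading* is
the reference unit for a (+) gene and the reverse complement for a (−)
gene. Tracts straddling a gene boundary are dropped from genic analyses;
a tract inside two overlapping genes contributes one oriented record per
gene (an `exclude_bidirectional` flag drops doubly-covered tracts for
sensitivity analysis). These conventions give three exact identities that
the test-suite checks on every synthetic run: flipping all gene strands
swaps every non-template/template count pair; non-template plus template
counts for a base equal the number of oriented tracts of that base or its
complement; and the bias for unit U equals one minus the bias for its
reverse complement.

## Overlap and normalization

An indel overlaps a tract when its deleted interval intersects the tract,
or its insertion point lies anywhere across the tract or immediately
before/after it. Overlap is positional only; requiring the indel sequence
to match the tract base is available (`require_base_match`) but off by
default, since the positional definition is the one the intersection-based
workflow implies. Indels are represented with 0-based half-open
coordinates (insertions as a zero-width point) and are left-aligned against
the reference before any intersection. Within a homopolymer every
placement of a one-unit indel hits the same tract, so left-alignment only
matters at tract boundaries; it is idempotent and never changes the kind,
length or base multiset of the event, which is property-tested.

## The bias statistic and inference

With hit counts n_NT, n_T and oriented occurrence counts m_NT, m_T for a
target unit, A = n_NT/m_NT and B = n_T/m_T are per-strand mutational
densities; bias = A/(A+B) and the corrected excess is (A/B − 1)·100%. The
occurrence denominators absorb the reference genome's own strand skew
(polyT sits ~1.14-fold more often on the non-template strand,
occurrence-weighted), so bias = 0.5 means "no asymmetry beyond the
background". Scaling one strand's counts and motifs together leaves the
bias unchanged, an invariant in the suite.

Inference:

- **Gene bootstrap.** Genes are resampled with replacement (same number of
  genes, 1000 iterations by default), the four counts re-summed and the
  bias recomputed; the standard deviation over iterations is the reported
  dispersion. Iterations with an undefined bias (a zero denominator after
  resampling) are redrawn, with a warning above a 1% redraw rate. One
  seeded generator per invocation; seeds are recorded in outputs.
- **Binomial test.** Exact test of n_NT successes in n_NT+n_T trials
  against p₀ = m_NT/(m_NT+m_T). The motif-share null is the default
  because all analyses correct for the skewed background; `null_half`
  reproduces the uncorrected p₀ = 0.5 variant for comparison.
- **Group tests.** Per-sample biases are compared with Mann–Whitney U,
  Kruskal–Wallis or Wilcoxon signed-rank; Bonferroni family sizes are
  explicit configuration, never inferred.
- **Down-sampling z.** To compare a low-count focal sample against a
  cohort, equal numbers of hits are redrawn (10,000-fold by default) from
  the cohort's pooled hit classes at the cohort's observed non-template
  share, the bias of each draw computed with the cohort's motif
  denominators, and z = (bias_focal − mean)/sd with an empirical two-sided
  p. Pooling the cohort's hits (rather than resampling per sample) was an
  open choice; pooling is simpler and calibrates correctly (~95% of
  self-draws land within |z| < 2, checked at 100 repetitions).

## Stratifications

Expression tiers are the 33rd/66th RPKM percentiles over protein-coding
genes; zero-RPKM genes fall into "low" (a separate zero tier is available
by flag) and ties at a threshold go to the lower tier. Stratified analyses
restrict both hits and motif denominators to the stratum's genes or
tract-length class; stratified counts sum exactly to the unstratified
counts.

Replication annotation smooths the Repli-seq signal with a moving average
(50 kb default, forced to an odd bin count so reversing the signal exactly
swaps left/right labels), takes the central-difference first derivative,
and labels bins right- or left-replicating by its sign, with |derivative|
below a threshold (default: 5th percentile of |derivative|) labelled
transition; the second derivative flags initiation/termination zones but is
not used downstream. Which reference strand is "lagging" in
right-replicating regions is a convention the source data do not fix; it
is exposed as `rep_convention` with a documented default, and only
convention-independent properties are tested. Gene timing is the
length-weighted mean of overlapping bins; timing quantiles split genes
into five groups differing by at most one gene.

## Synthetic data: what it emulates and what it does not

The generator plants ground truth at every level: a run-suppressed
background sequence (no base three times in a row, no dinucleotide unit
twice in a row) so that planted tracts are the only homopolymer tracts of
≥3 bp and the only ≥2-unit dinucleotide tracts; non-overlapping genes on
random strands; tracts planted inside genes with flank guards that keep
them maximal and exactly detectable; and indel cohorts whose strand
placement is calibrated so the *corrected* bias estimator has expectation
β regardless of the reference skew q (the per-indel non-template
probability is β·m_NT/(β·m_NT + (1−β)·m_T), with the motif counts taken
from the generator's own independent scan of the emitted sequence).

Default conditions: q = 0.533 (non-template/template occurrence ratio
≈ 1.14, the magnitude of the human reference polyT skew); β = 0.55 (a
clearly detectable non-template excess of the size seen in
MMR-compromised cohorts); insertion fraction 0.36 (cohort medians of 124
insertions vs 222 deletions); per-tract relative rate 1.5^(length−1)
(slippage intermediates become likelier as tracts lengthen); MSI samples
get a 3× tract-indel rate at 25% prevalence; tract lengths are truncated
geometric over 1–10. Expression is log-normal with tier-dependent
location so the planted low/medium/high partition is recoverable from the
percentile thresholds; Repli-seq is a sawtooth with per-bin truth labels.

What passing tests on this generator do **not** show about real data: the
background has neither human base composition nor chromatin structure;
indel size spectra are single-unit by default; MSI status modulates rate
but not, by default, the bias itself; and the Repli-seq sawtooth has none
of the noise or domain-size heterogeneity of real timing data. The
generator is a correctness surface for the pipeline's algebra and
calibration, not a cancer-genome emulator.

## Problem sizes and numerical choices

The suite runs the tract scanners against a regex/brute-force oracle on
1,000 random 10 kb sequences and hit assignment against an all-pairs
oracle on 10,000 indels × ~5,000 tracts (exact set equality). Calibration
and recovery use the generator's counts-level fast path at the sizes the
study design names — 2,000 genes for null calibration (2,000 simulations),
1,000 genes / 5,000 indels × 50 replicates per planted β for recovery with
1000-fold bootstrap intervals — and the full FASTA→VCF→report path at
smaller sizes (hundreds of kilobases, tens of genes, thousands of indels),
which keeps the whole suite in a few minutes on one core. Ratios with a
zero denominator are flagged undefined rather than clamped; bin
enrichments satisfy the base-weighted mean-1 identity to machine
precision; all random draws flow from explicit seeds and every output
directory records its config hash and seed.

## Known limitations

- The leading/lagging strand convention is configurable, not inferred;
  orientation-controlled results are interpretable only relative to the
  declared convention.
- The down-sampling comparison pools cohort hits; per-sample weighting
  within cohorts is not implemented.
- Insertions sandwiched between two adjacent tracts count once per tract;
  the ambiguity is rare (flank positions only) but not resolved.
- Multi-unit deletions are supported by the overlap predicate but the
  generator plants one-unit events by default, so size-spectrum behaviour
  beyond one unit is only lightly exercised.
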