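# Methods

This note documents the models, conventions and design choices behind
`arisakit`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Fingerprint processing

A size-called ARISA peak table (sample, replicate, fragment size in bp,
intensity in relative fluorescence units) is reduced to a
relative-intensity OTU table in a fixed order:

1. **Fluorescence floor.** Peaks with intensity ≤ `min_rfu` (default
   10 RFU) are excluded. The bound is strict: a peak at exactly 10 RFU is
   removed. This mirrors how capillary-instrument noise floors are applied
   in practice.
2. **Detection window.** Peaks outside [200, 1150] bp are excluded, both
   endpoints included. The spacer lengths resolvable by the method fall in
   this window, which is what caps observable richness at a few hundred
   phylotypes. Some size standards start at 250 bp; the lower bound is
   configurable through `BinningScheme`.
3. **Binning.** Bin width follows fragment size: 3 bp up to 700 bp, 5 bp
   from 700 to 1000 bp, 10 bp above 1000 bp — wider bins at longer
   fragments compensate for declining size-calling precision. Bins are laid
   on a *fixed grid* anchored at the window's lower edge, half-open
   `[lo, lo + w)`, the last 3 bp bin truncated to [698, 700), and the final
   bin of the window closed ([1140, 1150]) so a peak at exactly 1150 bp is
   kept. A peak at a regime boundary (700 or 1000 bp) belongs to the higher
   regime's first bin ("up to 700" read as < 700). The default scheme has
   167 + 60 + 15 = 242 bins. An alternative reading of 3 bp "± 1 bp" bins
   is dynamic peak-centred binning; the fixed grid was chosen because it is
   deterministic, order-independent and reproducible across runs, which a
   peak-centred scheme is not without extra tie-break rules.
4. **Intensity summation and relative-intensity filter.** Peak intensities
   are summed per bin; each bin's relative intensity is computed against
   the *pre-filter* sample total, bins under `min_relative_intensity`
   (default 0.1%) are dropped in a single pass, and the survivors are
   re-normalized to sum to 1. The filter is deliberately not iterated to a
   fixed point: the exclusion rule describes one calculation. Whether
   intensities should be re-normalized afterwards is not standardized;
   re-normalization is applied here because downstream Bray-Curtis
   comparisons assume compositional vectors.
5. **Technical-replicate QC.** The two PCR replicates of a sample are
   compared as individual profiles by Bray-Curtis similarity on the union
   of their bins. At or above `replicate_threshold` (default 0.8 — a
   package choice; field practice only says "similar") they are merged by
   averaging relative intensities per bin and re-normalizing; below it the
   sample is flagged and excluded from downstream paired analyses rather
   than raising an error, since QC failure is a reportable outcome.

Invariants maintained and tested: intensity is conserved by binning; every
retained bin sits at or above the relative-intensity floor; per-sample OTU
counts never exceed the scheme's bin count.

## Sequencing-arm preprocessing

Amplicon OTU count tables (97%-identity clusters from any upstream
pipeline) are filtered by the standard low-abundance rule: OTUs whose
**total** count across the study is below 3 reads (singletons and
doubletons) are removed. The total-based reading (rather than per-sample)
was adopted because the rule targets clusters, which are defined across the
run; this is flagged as an interpretation. Counts are then converted to
per-sample proportions. No rarefaction is applied; comparisons are made on
proportions, and read depth enters only through its effect on detection.

## Statistics

- **Alpha diversity.** Observed OTUs (> 0 abundance) per sample and per
  group (presence in any member sample), and Shannon–Wiener
  `H' = −Σ pᵢ ln pᵢ` in nats. Natural logarithm is used throughout;
  reported fingerprint diversities around 4–5 nats for ~150 observed bins
  are only consistent with ln.
- **Bray-Curtis.** `d = 1 − 2Σmin(xᵢ, yᵢ)/(Σx + Σy)`; on proportion
  vectors this equals half the L1 distance, a property-tested identity.
  Similarity is `1 − d`.
- **Group-mean tests.** Welch's unequal-variance t-test, two-sided, with
  Welch–Satterthwaite degrees of freedom; plain "t-test" claims in the
  field rarely justify the equal-variance assumption. Degenerate inputs
  (zero variance in both groups, equal means) return p = 1. Multiple
  comparisons are Bonferroni-corrected, `min(1, m·p)`.
- **Similarity-vector correlation.** Pearson r over the n(n−1)/2 paired
  similarities of the two methods. These pairs share samples and are not
  independent, so alongside the parametric p a Mantel-style permutation p
  is computed by relabeling the samples of one matrix (one-sided, positive
  association; exhaustive over all n! orderings when n! is within the
  permutation budget).
- **ANOSIM.** Mid-ranks of all pairwise dissimilarities;
  `R = (r̄_between − r̄_within)/(M/2)`, M = n(n−1)/2. The test is
  one-sided (large R), permutation-based with
  `p = (1 + #{R* ≥ R}) / (1 + n_perm)`; when the number of distinct label
  assignments is at most min(n_perm, 10,000) the distribution is enumerated
  exhaustively and p is the exact fraction with the observed labeling
  included, so p is never 0. Pairwise tests run on each two-group
  submatrix, Bonferroni-corrected by the number of pairs, and are reported
  both long-form and in the conventional square layout (R lower-left,
  corrected p upper-right). Default 9,999 permutations.
- **PCoA.** Eigendecomposition of `B = −½ J D² J`. Coordinates are
  eigenvector·√λ for eigenvalues above a relative tolerance of 1e-9;
  negative eigenvalues (expected for the semi-metric Bray-Curtis index) are
  counted and their axes dropped, with no Lingoes/Cailliez correction — the
  analyses this package reproduces apply none. The largest-magnitude
  loading of every axis is made positive, so output is bit-stable.
- **Procrustes.** Both configurations (first three PCoA axes by default;
  fewer positive axes are zero-padded with a warning) are centred and
  scaled to unit Frobenius norm; the optimal orthogonal map (reflections
  allowed, since PCoA axis orientation is arbitrary) comes from the SVD of
  the cross-covariance, giving `M² = 1 − (Σσᵢ)²`, symmetric in its
  arguments under this symmetric-scaling convention (scaling only one
  configuration would break the symmetry; the symmetric form was chosen as
  the more defensible default). Significance is Monte-Carlo with
  `p = (1 + #{M²* ≤ M²}) / (1 + n_perm)`, default 1,000 row-relabeling
  permutations of one configuration.

## Synthetic-data model

The generator emulates a cross-sectional gut-community study: four age
groups of 6/5/5/5 samples whose true richness rises roughly an order of
magnitude from newborn to adult (defaults 200/600/2000/2400 taxa).

- **Communities.** Each group has a template with normalized log-normal
  abundances (shape σ = 1.5; log-normal rank-abundance is the conventional
  community model, and this σ yields both a detectable core and a faint
  tail that the 0.1% intensity filter and finite read depth truncate, as
  in real data). Sample i of a group is `θ·template + (1−θ)·fresh draw` on
  the same support; θ (default 0.85) maps monotonically to expected
  within-group Bray-Curtis similarity and the default produces the clear
  group separation the analyses assume. Consecutive groups share 30% of
  the smaller group's taxa as a core.
- **Sequencing arm.** Per-sample depth is normal (mean 10,800, SD 2,860)
  truncated below at 1,000 reads to avoid degenerate samples; reads are
  multinomial on the true proportions. Sequencing error, chimeras and PCR
  bias are *not* modelled — the package's scope starts at the OTU table.
- **Fingerprint arm.** Each taxon receives one spacer length uniform on
  [200, 1150] bp, plus a second independent length with probability 0.2
  (multiple ribosomal operons); unrelated taxa may therefore collide on a
  length or bin, and one taxon may occupy two bins — the two mechanisms
  that skew fingerprint richness. A sample emits `gain × abundance` RFU at
  each length (gain 10⁵, putting dominant peaks in the thousands of RFU
  and sub-10⁻⁴ abundances under the 10 RFU floor), with per-replicate
  log-normal intensity noise (σ = 0.05), Gaussian size-calling noise
  (SD 0.2 bp), Poisson baseline peaks (rate 20/profile, exponential RFU
  scale 5, mostly under the floor), and an 0.5 RFU reporting floor
  standing in for the instrument's own detection limit. The replicate
  noise levels correspond to a well-behaved capillary run and keep
  processed duplicate similarity above the 0.8 QC threshold by
  construction; raising them simulates failing runs.

What passing tests on this generator show: the pipeline's filtering and
binning arithmetic is exact; the comparison statistics behave correctly on
data with known group structure; and the qualitative phenomena — richness
saturation of the fingerprint below its 242-bin capacity, agreement of
both methods on β-diversity structure — emerge from the mechanisms that
produce them in real studies. What they do not show: quantitative fidelity
to any particular instrument's noise, to real spacer-length phylogenetic
structure (lengths here are uniform and independent, real ones cluster by
lineage), or to sequencing artifacts.

## Workflow and reproducibility

`pipeline.run_comparison` executes the stages in a fixed linear order and
writes a versioned JSON report plus TSV tables and plots. Every stochastic
stage draws its seed deterministically from the single run seed, elapsed
times go to the log stream and never into report files, and JSON keys are
sorted — two runs with the same config produce byte-identical reports.
The acceptance script runs this workflow at the caller's seed on the
default design (21 samples, ~4,400 pool taxa, ~65,000 simulated peaks,
9,999 ANOSIM and 1,000 Procrustes permutations), sizes at which a full run
takes a few seconds.

## Known limitations

- The fixed-grid binning can split a true peak straddling a bin edge
  between adjacent bins across replicates; the replicate merge averages
  this out but does not undo it.
- ANOSIM exhaustive enumeration treats label assignments (not partitions)
  as the unit; for two equal-sized groups each partition is counted twice
  in both numerator and denominator, leaving p unchanged.
- The Mantel permutation p is one-sided for positive association; testing
  for negative association requires negating one similarity vector.
- Groups with fewer than two samples are skipped in group summaries and
  rejected by ANOSIM; single-pair groups report SD 0.
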