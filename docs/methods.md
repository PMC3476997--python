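# Methods

This note documents the statistical procedure implemented by `cnage`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Signal model and normalization

Inputs are positive, platform-normalized intensity matrices: copy-number
(CN) probes and gene-expression (GE) loci, over the same cohort of tumor
samples plus reference normals.  Upstream probe-level normalization
(RMA-style expression summaries, CN raw-array calibration) is out of scope;
the pipeline starts from these matrices.  Each tumor value is divided by
the per-feature median over normal samples and log2-transformed, so 0 means
"no change relative to the normal reference".  The median uses the
midpoint-of-two rule for even normal counts.  Non-positive or missing
values are rejected rather than imputed: every downstream statistic
(segment means, Pearson r, k-means boundaries) assumes complete, finite
ratios, and silent imputation would bias the per-locus correlations.
Matrices that already contain log2 ratios can skip the stage
(`normalization.enabled: false`).

Coordinates are 0-based half-open everywhere (BED convention), including
the SEG output; chromosome order is natural (chr1..chr22, chrX, chrY).

## Smoothing and segmentation

Both data types are smoothed and segmented identically, which is what makes
regional CN and GE signals comparable.  Gene tracks are ordered by locus
midpoint; position enters only through ordering, never through the
statistic.

**Outlier smoothing.**  A point is shrunk when it deviates from its
±`smooth_region` (default 10) window median by more than `smooth_sd`
(default 3) window SDs, to median ± 3 SD with the deviation's sign.  The SD
is estimated from the window *excluding the point itself*.  This choice is
deliberate: a genuine run of shifted points inflates its own window SD and
is therefore preserved, while a single discordant spike against a quiet
neighbourhood is shrunk.  (A robust MAD-based window scale was rejected: it
collapses any shifted run narrower than half the window, i.e. exactly the
focal alterations the method is meant to find.)  Vectors shorter than the
full window pass through unchanged.

**Circular binary segmentation.**  For a segment of n ordered values, every
admissible circular arc (i, j] is scored with the two-sample statistic

    T(i, j) = (mean_arc - mean_rest) / sqrt(s2 * (1/k + 1/(n-k))),

with pooled variance s2 on n-2 df.  Arcs touching an end reduce to
ordinary binary splits; admissible arcs leave every resulting piece at
least `min_width` = 2 features.  Ties in |T| take the smallest (i, j);
complementary arcs describe the same partition and are treated as ties.
The observed max |T| is referred to a permutation null: the max |T| of
random permutations of the segment's values.  A split is accepted when
p < `alpha` = 0.01 and recursion continues on the 2–3 pieces.

Numerics: since the total sum of squares is permutation-invariant, |T| is a
monotone transform of the arc's between-group sum of squares
BSS = g^2 · n / (k(n-k)) (g the centered arc sum), so each permutation only
needs the max BSS — one cumulative sum and one gather per draw.  Zero
within-variance arcs (noiseless steps) are handled by capping |T|^2 at
1e12 on both sides of the comparison.  A segment with numerically zero
total variance is never split.

**Sequential permutation testing.**  The split decision only needs to know
whether p < alpha, not p itself.  Permutations are therefore drawn in
doubling blocks (128, 256, ..., capped at `n_perm` = 10000) and stop as
soon as a 99% Clopper–Pearson interval for p lies entirely below or above
alpha — noise segments typically resolve within ~128 draws and strong
splits within ~900, keeping a 64-sample cohort's segmentation in seconds.
The standalone `split_pvalue` always runs the full `n_perm` draws and
returns the exact (1 + exceedances)/(1 + n_perm).  No DNAcopy-style hybrid
tail approximation or undo-splits pruning is used: pure permutation is
reproducible bit-for-bit from a seed, and at the problem sizes targeted
here the approximation buys nothing.  Per-(sample, chromosome) random
streams are derived from (seed, crc32(sample id), chromosome rank), so a
sample's segmentation never depends on which other samples are present or
in what order.

Whether expression should be smoothed as well as copy number is genuinely
open; both are smoothed by default and each track can opt out
(`smooth_cn` / `smooth_ge`).

## Locus correlation and outlier rescue

For each gene locus, the CN value is the seg-mean of the CN segment
containing the gene's central point (floor midpoint of its span); a
midpoint falling in a gap between probe-delimited segments takes the
nearest segment by center distance rather than being dropped.  The GE value
is the gene's own segmented value.  Pearson r across the n tumors gets a
two-sided p via the t-transform with n-2 df; Bonferroni m is the number of
loci with defined r (zero-variance loci are excluded from the family).
Significance is one-sided on the coefficient itself, r >= `r_threshold`
(default 0.60): the method looks for expression driven *by* dosage, and at
n = 64 with 20,000 loci this threshold sits below adjusted p 0.005.

Sparse expression coverage can bury a dosage-responsive gene inside a
discordant segment (smoothing and segmentation flatten it).  Such loci are
detected per sample by |raw − seg_mean| > `k_mad` = 3 robust SDs
(1.4826 · MAD) of the segment's residuals — segments with fewer than three
member loci cannot flag, the MAD being unstable — and a locus flagged in at
least ceil(n/3) samples is re-tested: raw expression against segmented CN,
same threshold.  Rescued loci are *added* to the significant set; nothing
is ever removed.  "Statistically significant outlier" is not further
specified by the approach this implements, so the 3 × MAD residual rule was
chosen as a robust, parameter-light operationalization.

## Discretization and alteration frequency

Gain/Loss and Up/Down thresholds are estimated by k-means with k = 3 on the
pooled segmented locus × tumor values of each data type (pooling across the
genome matches the single genome-wide threshold pair the procedure
reports; normal samples do not enter the pool).  Sorted 1-D data admit
contiguous optimal clusters, so the solver is exact: a divide-and-conquer
boundary search over the two-cluster subproblem (the squared-error cost is
concave-Monge, making the inner argmin monotone), with no random
initialization and hence no seed dependence.  Each threshold is the
midpoint between adjacent clusters' extreme members; classification is
strict (boundary equality = no change).  Fewer than three distinct pooled
values is a hard error — with fewer than three populations the three-state
vocabulary is meaningless.

Each locus × sample pair lands in one of nine joint states
(U/N/D × G/N/L).  The per-direction frequency cutoff is the type-1
(nearest-rank, ceil(q·m)) empirical quantile of the per-locus U-G and D-L
counts at q = 0.90, floored at one sample: a locus that is never altered
concordantly in any sample cannot qualify however degenerate the count
distribution is.  A locus qualifies when its count ≥ cutoff.

## Hotspot regions

A locus is a hotspot member for a direction when it is
correlation-significant (directly or rescued) *and* frequency-qualifying.
Runs of members merge into regions, tolerating `max_gap_loci` = 1
intervening non-member (isolated dropouts — a decoupled gene, a boundary
misclassification — should not split an otherwise contiguous region;
broader gaps should).  Regions never cross chromosomes.  Reported
summaries: span (min start to max end), member genes, mean r over members,
and mean percentage of samples in the exact concordant category.  Cytoband
labels are annotation pass-through from a user-supplied BED, never
computed.

## Synthetic cohorts

The generator emulates the paired-cohort study design at desk scale:
default 64 tumors and 10 normals over 3 chromosomes with 120 CN probes and
60 gene loci each (uniformly spaced; a dense CN track against ~2× sparser
gene coverage).  Planted alterations are rectangles: a gain of +0.8 log2
units at prevalence 0.6 (chr1, 20% of the chromosome, 12 genes) and a loss
of −1.0 at prevalence 0.5 (chr2) — magnitudes in the range of a
single-copy loss and a low-level gain/amplification mixture.  Affected
samples are drawn *without replacement* at exactly round(prevalence · n),
so truth counts are exact.  Genes inside an affected region shift by
`beta` × cn_shift (default beta 0.8, expression tracking dosage
sub-proportionally), except a `outlier_gene_rate` = 0.05 fraction of
decoupled genes whose expression ignores copy number.  Gaussian log-scale
noise (SD 0.15 on both platforms) is added and signals are emitted on the
positive linear scale, so the real normalization stage is exercised rather
than bypassed.  A separate focal-amplification scenario plants a narrow
CN gain (a few probes) containing exactly one dosage-coupled gene — the
situation in which segmentation flattens the gene's expression and only
the unsegmented rescue finds it.

What this does **not** emulate: SNP-array wave artifacts and allele-specific
signals, GC effects, mixed focal/broad alteration spectra, subclonality,
non-Gaussian expression noise, and correlated probe noise.  Passing the
synthetic suites therefore demonstrates the *machinery* (segmentation,
thresholds, selection logic, rescue) under the stated noise model, not
performance on any particular real cohort; dataset-derived quantities
(thresholds, cutoffs, region lists) will differ on real data and are always
recomputed.

## Validation problem sizes

The shipped checks use: 200 random vectors (length ≤ 50) against an
exhaustive split-search oracle; 50 planted three-level profiles (3 × 40
points, noise SD 0.1) for breakpoint/mean recovery; 100 fixtures (length ≤
200) against a brute-force 3-means search; 20 seeds of the focal-rescue
scenario (48 tumors, 160 probes, 40 genes); and 20 planted plus 20 null
cohorts at the default cohort scale for locus-level precision/recall and
false-call control.  These sizes make the whole suite run in minutes on a
single core while keeping every random quantity seeded and reproducible.

## Known limitations

- Permutation tests make segmentation O(n²) per draw in the segment length;
  very dense tracks (10^5+ probes per chromosome) would need the hybrid
  tail approximation this package deliberately omits.
- Bonferroni control is conservative when loci share segments (they do, by
  construction); the r-threshold selection rule, not the adjusted p, is the
  operative filter.
- One CN segment value per gene midpoint ignores genes straddling
  breakpoints.
- The k = 3 discretization assumes three populations per data type; highly
  aneuploid genomes with multi-level gains are collapsed into one "gain"
  state.
- Frequency cutoffs are genome-wide, not per-chromosome; arm-level events
  dominating one chromosome can raise the bar for focal events elsewhere.
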