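# Methods

## Allelic quantification

The unit of analysis is the per-gene allelic ratio Xi/(Xi+Xa), computed
from fragments whose reads overlap strain-distinguishing SNPs. A ratio of
0.5 means biallelic expression; silencing drives it toward 0. Ratios are
undefined (propagated as missing, never imputed) when a gene has no
allelic fragments in a sample.

Gene admission uses two filters, both with strict inequalities as the
defaults are documented: (i) coverage — at least `min_allelic_frags` (10)
allelically assigned fragments in strictly more than `min_wt_sample_frac`
(80%) of wild-type samples, so a gene covered in exactly 4 of 5 samples is
rejected; (ii) baseline biallelism — the mean allelic ratio across
uninduced (day-0, NoDox, mESC) samples must lie strictly inside
(`baseline_low`, `baseline_high`) = (0.1, 0.9), since strongly monoallelic
baseline genes are typically artifacts of mis-annotated SNPs. Whether the
baseline is the mean of per-sample ratios or the ratio of pooled counts is
not uniquely determined by convention; the per-sample mean is the default
and `baseline_mode="pooled"` selects the alternative.

Replicates of the same (line, condition, day) are combined as the
unweighted mean of per-sample ratios, not the ratio of summed counts;
missing per-sample ratios are omitted from the mean. Expression
normalization offers RPM (counts ×10⁶ / library size) and TPM
(length-normalized rates scaled to sum to 10⁶ per sample); expression
tertiles are rank-based with group sizes differing by at most one,
remainders assigned to the lowest group and ties broken by stable input
order, so results are reproducible on tied data.

## Silencing kinetics

Each gene's trajectory over days of Xist induction is modelled as
y(t) = yf + y0·e^(−tk) with parameters constrained to proportions
(y0, yf ∈ [0,1], y0+yf ≤ 1, 0 ≤ k ≤ `k_max` = 10/day). yf is fixed at 0
for genes that inactivate completely; it is a free parameter only for
escapees, defined as mean allelic ratio strictly above
`escapee_threshold` (0.1) in mature samples (day ≥ `mature_day_min`,
default 7 — the end of the differentiation course; later samples should
be used when available, since slowly silencing genes are still decaying
at day 7).

Fitting is two-stage. A pooled fit of y0·e^(−tk) to all (t, y) points of
all genes provides a common starting point; each gene is then fit by
bounded nonlinear least squares (trust-region reflective). Escapee fits
are parameterized as (r0, φ, k) with y0 = r0(1−φ), yf = r0·φ, which keeps
y0 + yf ≤ 1 inside a box-constrained solver without penalty terms. Each
gene runs `n_starts` (5) seeded initializations — the pooled start plus
multiplicative jitter — and keeps the lowest-SSE solution; the per-gene
jitter stream is derived from the config seed and a CRC of the gene
identifier, so fits are independent of gene order and of the ordering of
timepoints and replicates. Solver tolerances are 10⁻¹²; noise-free
trajectories recover parameters to ~10⁻¹⁵ relative error. Genes with
fewer than three points or fewer than three distinct timepoints return an
unconverged fit with missing parameters and are excluded from
classification rather than imputed.

The half-time is the time the fitted curve reaches a fraction F (0.5) of
the initial ratio y0+yf:

    t½ = −(1/k)·ln((F·(y0+yf) − yf) / y0)

anchored by the yf = 0 limit t½ = ln 2 / k. It is undefined when k = 0,
y0 = 0, or F·(y0+yf) ≤ yf (half-point at or below the plateau — the curve
never reaches it); such genes stay unclassified. Defined half-times are
split into fast/intermediate/slow rank tertiles (fast = smallest), with
the same size and tie rules as expression tertiles. Cross-line agreement
of half-times is summarized by Spearman rank correlation on the shared
genes with defined values.

## Dependence classification and statistics

SmcHD1 dependence is called per gene from mature allelic ratios:
escapee if the wild-type ratio exceeds `smchd1_escapee_min` (0.1);
otherwise dependent if the knockout ratio is ≥ `smchd1_dep_min` (0.2),
not dependent if ≤ `smchd1_not_max` (0.05), partial in between. SPOC
dependence uses the day-6 Dox−NoDox change in the SPOC-mutant line:
independent (still silencing) at ≤ −0.15, dependent at ≥ −0.05,
unclassified between. The thresholds are configuration with these
defaults — the contract is the procedure; cutoff values should be tuned
to the experiment at hand — and every call table records the thresholds
used. Classification is total on defined inputs and monotone in its
thresholds.

Group comparisons use the Wilcoxon rank-sum test: exact by full
enumeration of rank assignments for combined n ≤ 12 (ties via mid-ranks;
two-sided extremeness by deviation of U from its null mean), and the
tie-corrected normal approximation (no continuity correction) above.
Fisher's exact test enumerates all r×c tables with the observed margins
and sums probabilities of tables at most as probable as the observed one,
which for 2×2 reproduces the classical two-sided convention and extends
it to 2×3 category-by-condition tables. P-values are reported raw — no
multiplicity adjustment by default, with Benjamini–Hochberg available as
an option — and each report row carries both group sizes.

## Calibrated allelic ChIP windows

The allelically analysable chrX region (103.5 Mb) is tiled into
contiguous half-open 250-kb windows (414 of them; the final window is
truncated when the region length is not a multiple). Spike-in calibration
uses the occupancy-ratio factor

    α = (spike_input / spike_IP) × (target_IP / target_input)

isolated in a single function so an alternative derivation can be
substituted. Window signal is depth-normalized within each sample (per
million target-genome reads) before α is applied:

    E_a = α · (IP_a / N_IP) / (input_a / N_input),  a ∈ {Xi, Xa}

Algebraically this equals (spike_input/spike_IP)·(IP_a/input_a), making
calibrated enrichment exactly invariant to uniform rescaling of either
sample's reads-plus-signal — the property a calibration must have — which
applying α to raw, non-depth-normalized window signal would not satisfy.
Zero allelic input is guarded by a pseudocount and flagged rather than
producing infinities. Per window, the differential D = E_Xi − E_Xa and
ratio R = E_Xi/E_Xa are internally normalized summaries (robust to ChIP
efficiency differences); sign(D) = sign(R−1) wherever both are defined.

Blacklisting is computed from input tracks only: poor-mappability windows
deviate from the median non-allelic input by more than `mad_k` (2.5)
median absolute deviations (MAD unscaled by default; the 1.4826
normal-consistency factor is a config option, since either reading of
"MAD" is defensible), and low-allelic windows fall strictly below the 5%
lower (type-1) empirical quantile of allelic input. With all-equal input
the MAD is 0 and nothing exceeds the threshold, and no value is strictly
below the quantile — degenerate tracks mask nothing. Replicate summaries
take the unweighted per-window mean of D, exclude masked windows from the
ratio distribution, and always report masked/retained counts.

## Synthetic data generator

The generator defines the study conditions used throughout the tests:
a time course at days 0–7 of induction/differentiation with 2 replicates
per point, uninduced (NoDox) day-0 baselines, ~100 allelically assigned
fragments per gene and sample on average, and 300 X-linked genes.
Per gene: initial allelic ratio ~ N(0.5, 0.03) clipped to [0.35, 0.65];
silencing rates drawn from three equal strata — fast U(0.9, 2.5),
intermediate U(0.45, 0.9), slow U(0.25, 0.45) per day (half-times of
roughly 0.3–2.8 days) — so silencing of non-escapees is largely complete
by around day 7, with slow genes approaching their plateau last; 6% of
genes are escapees with plateau yf ~ U(0.15, 0.35) (the flag is
equivalent to yf > 0.1 by construction). Counts are gamma-Poisson totals
(dispersion 0.05; 0 degenerates to Poisson), binomial allelic thinning
with per-gene SNP fraction U(0.15, 0.45), and beta-binomial Xi draws with
intra-class correlation ρ = 0.01 — a stand-in for replicate-to-replicate
ratio scatter, not an inference about real allelic noise. Counts conserve
xi + xa + unassigned = total exactly, and all draws are deterministic
given the design seed.

Mutant lines are modelled phenomenologically: a multiplicative rate
attenuation (k-multiplier 0 gives a fully silencing-deficient line that
stays biallelic) and/or plateau overrides from each gene's planted
dependence label (dependent 0.30, partial 0.15, not 0.02). Planted
dependence labels correlate probabilistically with kinetic strata (slow
genes mostly dependent, fast mostly not), mirroring the association the
analysis is meant to detect. An optional Xist row ramps up with induction
and carries almost no allelic fragments, so it contributes to RPM-based
abundance but is excluded from gene-level silencing analysis by the
coverage filter.

ChIP tracks are generated noise-free by default (optional Poisson noise):
planted per-allele enrichment over uniform input, an IP generated at a
known material scale with spike reads scaled accordingly (so calibration
recovers the planted enrichment exactly), 10×-inflated non-allelic input
in artifact windows and 20×-deflated allelic input in low-allelic
windows, making the planted blacklist exactly recoverable.

What the generator does not emulate: genomic autocorrelation of
expression and SNP density, differentiation-induced expression changes of
the total-count channel, selection against silencing-deficient cells,
library-preparation batch effects, and read-level artifacts (the
generator starts from counts, not reads). Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every property of real data.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 300 genes × ~34
samples for recovery (about 3 s of fitting), 100 random 50-gene matrices
for the filter oracle, ≥200 enumerated small-sample test cases, and
50–60-window ChIP tracks. Chromosome-scale quantities that are pure
arithmetic (window counts) are computed at full scale. Exact-test
enumeration switches to the asymptotic approximation above combined
n = 12, where enumeration cost grows combinatorially and the normal
approximation is standard practice.

## Known limitations

Escapee status and kinetic fits interact: a gene is flagged from mature
samples before fitting, so a non-escapee gene with a slow rate and noisy
day-7 ratios can occasionally be fit with a free plateau (and vice
versa). Dependence calls made at day 7 are biased upward for slowly
silencing genes that have not reached their plateau; calling from later
differentiated samples is preferred when the design includes them. The
rank-sum normal approximation omits the continuity correction, which can
differ slightly from other software at moderate n. Uncertainty intervals
on kinetic parameters and alternative trajectory models (bi-exponential,
logistic) are out of scope.
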