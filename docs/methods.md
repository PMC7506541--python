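# Methods

## Stutter model and deconvolution

Polymerase slippage on a mononucleotide run of length L produces, per
amplified template, a ladder of fragments offset by δ bases from the
template length. We model the fraction of signal remaining in the
template band as a two-parameter logistic of repeat length,
p(L) = 1/(1+exp(a(L−b))) with a > 0, fitted by unweighted least squares
to the (L, main-band fraction) points of all MMR-proficient control
profiles (20 controls per locus by default). The parameterization is a
choice of ours; any strictly decreasing sigmoid anchored by the control
data would serve, and the fit recovers generating parameters to within
a few per mil at the default noise level. The per-locus reference shape
p_ref(δ) is the mean normalized control profile, renormalized to sum to
one over the window δ ∈ [−4, +4].

The contribution operator C for a locus maps true allele fractions to
expected band fractions. Rather than evaluating the textbook stutter
formula at δ = 0 — which would double-count the main band and violate
signal conservation — the diagonal of each column Δ is set to
p_effective(Δ) = p(L_eff + Δ), where the effective length
L_eff = p⁻¹(p_ref(0)) calibrates the locus to its observed control
behaviour, and only off-diagonal entries use the stutter shape scaled
by (1 − p_effective)/(1 − p_ref(0)). Because p_ref sums to one, each
column then sums to one exactly; columns truncated by the window edge
are renormalized. Degenerate controls with no stutter at all
(p_ref(0) = 1) make C the identity. p_effective values falling outside
(0, 1) numerically are clamped to [1e−9, 1−1e−9] with a warning.

The inverse problem argmin ‖Cp − p_obs‖₂ with 0 ≤ p ≤ 1 is solved by
active-set non-negative least squares; the upper bound is enforced by a
bounded-variable fallback in the rare case an NNLS coordinate exceeds
one, and the solution is renormalized to the simplex (which also caps
every entry at one). The solver is deterministic and, on noiseless
forward-convolved input, inverts C to machine precision — the
acceptance run measures a worst-case L∞ error of order 1e−13 over 1000
random models, far below the 1e−6 documentation threshold.

Peak tables are read with a 1% noise floor (bands below 1% of the
profile maximum are zeroed before normalization; configurable). Bands
outside the ±4 bp offset window are dropped with a warning: window
choice trades coverage of rare large indels against conditioning of C.

## Calls and cohort summaries

Indel mass is pooled by reading frame via Δ mod 3 (0 → M0, 2 → M1,
1 → M2, so m1/p2 feed M1 and m2/p1 feed M2). A sample is mutant at a
locus when at least 15% of allele mass is non-wild-type and biallelic
when the wild-type fraction falls below 50%; both cutoffs are
parameters. The dominant frame is the frameshift frame with more mutant
mass; exact ties break to M1 by default (M1 is the predominant
frameshift class in MSI tumors), configurable. MSI status over a marker
panel requires strictly more than 30% unstable markers.

Cohort summaries (per-cMS mutation prevalence p_mut, biallelic
fraction, mean allele ratios, frame distributions) exclude missing
tumor×locus cells from every denominator. Frame bias per cMS is tested
with an exact two-sided binomial test of M1 vs M2 dominant-frame counts
against the cohort-wide M1 share (or a user-supplied null), Bonferroni
corrected over the number of testable loci.

p_mut is defined as the fraction of non-missing tumors at or above the
15% mutant-fraction cutoff; a mean-allele-ratio mode is provided as an
alternative because prevalence and mean ratio are both defensible
frequency notions for correlation analyses. Prevalence is the default.

## Frameshift peptides

Coding microsatellites are maximal single-base runs of at least eight
bases in an in-frame CDS. The M1 peptide derives from a one-base
deletion and M2 from a two-base deletion, both placed at the 3′ end of
the run — within a homopolymer the indel position is unobservable and
every placement yields the same mutant sequence. Divergence is defined
at the amino-acid level (first codon whose translation differs from
wild type), the peptide carries at most eight wild-type residues
upstream of divergence, and translation stops before the first stop
codon; run-off translation (no stop before the CDS end) is flagged
rather than discarded. Insertion forms (p2/p1), which duplicate the
deletion peptides up to one junction residue, are available behind a
flag but not emitted by default.

## Immunogenicity scores

ELS combines a Hardy–Weinberg carrier probability 1−(1−f_H)² with the
probability 1−(1−p_binding)^k that at least one of k predicted binders
is real, treating predictions as independent Bernoulli trials with
success rate p_binding (the predictor's assumed true-positive rate).
Independence across predicted epitopes, across HLA alleles within a
locus, and between the A and B locus aggregates is assumed throughout;
linkage disequilibrium between HLA loci is ignored. Predicted binders
are classed by half-open IC50 intervals [0,50), [50,500), [500,5000) nM
— a prediction at exactly 5000 nM is discarded — and identical
(mer, allele) rows are deduplicated before counting, so k counts
distinct candidate epitopes. Scores are computed on a p_binding grid of
10%…90% in 10% steps with 0.5 as the headline default, at the 500 nM
threshold by default. HLA-C is excluded; the supertype panels cover
five HLA-A and seven HLA-B representative alleles. Frequency tables
below 10,000 data points are rejected unless forced, since small panels
make the carrier term unstable.

## Immunoediting statistics

Correlations are Pearson's r with two-sided t-test p-values and 95%
confidence intervals from the Fisher z-transform (verified to cover a
true r = 0.4 in ~95% of 1000 simulated samples at n = 41). All tests
are two-sided. Length adjustment subtracts the mean frequency of each
repeat-length bin (adjusted values are exactly mean-zero per bin). The
allele-restricted analysis replaces GELS with the binding factor
1−(1−p_binding)^k alone, since stratifying on measured carrier status
makes the population carrier term inappropriate; the unit of analysis
defaults to one observation per cMS, with a per-tumor×cMS pair mode
available (the two differ in effective sample size and hence p-values).

Clustering features are (M2, M1, wt) frame-abundance triples per
tumor×cMS cell, grouped by cMS (default) or tumor; missing cells are
imputed with the column mean. Clustering is Ward-linkage agglomerative
on Euclidean distance, cut at three clusters by default or at a
dissimilarity threshold; embeddings use RBF kernel PCA with
gamma = 1/n_features by default and a deterministic sign convention
(each component's largest-magnitude coordinate is positive).

## Synthetic data

The generator emulates the study geometry: 100 tumors over a panel of
41 cMS with repeat lengths 8–27, 20 controls per locus, ~5% missing
cells, a quarter of tumors B2M-mutant and half HLA-A*02:01-positive.
Stutter truth uses the same logistic family (a = 0.35, b = 18, chosen
so main-band fractions traverse their informative range over lengths
8–27) with a geometric, deletion-biased stutter shape (decay 0.55, 12%
of stutter mass on insertions). Peak noise is multiplicative Gaussian
(CV 5% by default), chosen over Poisson because capillary intensities
are scale-free. Mutant tumors draw allele fractions uniform on
[0.15, 1] — fractions above 0.5 represent biallelic hits — placed on m1
with probability 0.77, else m2, mirroring the observed dominance of
one-base deletions.

The editing signal enters as mutation log-odds base(L) − β·GELS in
immune-competent tumors (B2M wild type; additionally HLA-positive in
allele-restricted mode), with base(L) = 0.35·(L−16) rising with repeat
length as slippage rates do. For a concrete panel, `calibrate_beta`
solves deterministically for the β that plants a requested
candidate-level correlation between GELS and mutation probability
(≈ −0.4 in the headline experiments); the planted correlation is a
non-monotone function of β (it rebounds once editing suppresses nearly
all mutation), so the calibration takes the first crossing on the
descending branch. Recovery experiments redraw the panel and GELS per
replicate and calibrate per panel, which keeps the planted effect size
fixed while making the no-editing null a proper 5%-level test.

What the generator does not emulate: PCR chemistry beyond the stutter
operator itself, allele-specific amplification bias, clonal
heterogeneity within a tumor (each cell is a single mutant clone plus
wild type), inter-locus correlation of mutation events, and real HLA
haplotype structure. Passing recovery tests therefore demonstrate that
the statistics detect the planted selection signal under the stated
noise model, not that real cohorts satisfy these assumptions.

## Problem sizes

The test suite runs the recovery experiment at 200 replicates per arm
(planted signal and null) with 100 tumors × 41 loci each, the
deconvolution oracle at 1000 random models, and the Fisher-CI
calibration at 1000 replicates; the acceptance script uses the same
sizes and additionally pushes one full 100×41 cohort through peak
simulation and deconvolution. These sizes give Monte-Carlo standard
errors comfortably inside the documented tolerances (e.g. ±1.5
percentage points on a 5% rejection rate at 200 replicates).

## Known limitations

- The offset window of ±4 bp cannot represent larger indels; profiles
  dominated by them will misattribute mass.
- Columns of C are built from a single cohort-level logistic; loci whose
  stutter behaviour deviates systematically from the length trend are
  only partially corrected by the per-locus p_ref anchor.
- ELS/GELS treat predicted epitopes as exchangeable; overlapping mers
  are counted separately.
- The binomial frame-bias test conditions on dominant frame per tumor
  and ignores tumors where both frames are mutated equally.
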