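# Methods

## Scope and model

The package contrasts codon-pair (bicodon) usage between coding sequences of
lowly and highly abundant proteins. The unit of analysis is the ordered pair
of adjacent in-frame codons (P-site, A-site); the universe is the 61 x 64 =
3,904 pairs with a sense codon in the P-site. Pairs with a stop codon in the
P-site are excluded because they cannot occur inside a valid CDS; sense:stop
pairs are kept because every CDS ends in one. Counting is over *overlapping*
adjacent pairs (positions t, t+1 for every t), so a sequence of c codons
contributes c - 1 pairs; pairs never span sequence boundaries.

Synonymous groups collect all bicodons encoding one dipeptide. The three
stop codons are treated as a single STOP symbol for grouping, so an aa:STOP
group has (codons of aa) x 3 members; the groups partition the universe
(sum of q_ap = 3,904). The alternative — three separate aa:stop groups per
amino acid — was considered and rejected to keep stop-codon choice inside
the group comparison; it only affects the 61 x 3 sense:stop cells.

## Statistics

**RSBU and pause propensity.** RSBU normalizes each bicodon count by its
group total and scales by group size, so uniform within-group usage gives
RSBU = 1. Normalization is *per sample* by default (`N_ap_L`, `N_ap_H`):
this makes RSBU a proper relative-usage measure (each group sums to q_ap in
each sample), gives pi = RSBU_L - RSBU_H an exact sign interpretation, and
implies the identity sum-over-group(pi) = 0 for every group observed in both
samples, which the tests assert. A `pooled` normalization (one combined
N_ap) is available behind a flag for comparison; it scales pi but does not
reorder it within a group.

**Fisher exact test.** Each bicodon is tested against the rest of its
synonymous group (margins `N_ap_L`, `N_ap_H`), i.e., the question is "is
this pair's share of its dipeptide different between samples?", not "is its
share of all bicodons different?" — a whole-sample background is available
behind a flag. Two-siding follows the minimum-likelihood convention: the
p-value sums hypergeometric probabilities of all tables (same margins) whose
probability is at most the observed table's, with a relative tolerance of
1e-7 on that comparison to absorb floating-point ties. Probability mass is
accumulated in log space, so p-values far below double underflow are still
meaningful through `support_log_pvalues`. The implementation is verified
against exact integer-arithmetic enumeration (exhaustively for all margins
with table total <= 200) and against `scipy.stats.fisher_exact` on random
tables.

**Factorial evaluation.** Default is the exact log-gamma route. The
`stirling25` mode instead uses bare Stirling, sqrt(2 pi n) (n/e)^n, for
n >= 25 and exact products below — the historical approximation some
analyses used. Its log-factorial error is <= 1/(12 x 25) ~ 3e-3, giving
typical p-value deviations of ~2e-3 in log10. One caveat is structural: the
minimum-likelihood rule is *discontinuous* in the pmf ordering, so when
another support point's probability lies within the approximation error of
the observed table's (~5e-4 of random tables), its inclusion can flip and
the p-value jumps by that term's mass (never more than ~2x, since the
flipped term's mass cannot exceed the p-value itself). No factorial
approximation can avoid this under minimum-likelihood two-siding; the tests
therefore check the typical deviation and the 2x bound rather than a
uniform bound.

**Residual scores.** e_ij = f_i f_j N_p / N_tot^2 with f over all 64 codons
(stops occur at A-sites and are counted in N_tot). The within-group
rescaling to e_hat removes amino-acid-pair nonrandomness and guarantees
sum(e_hat) = sum(o) per group (asserted to 1e-9). chi2 = (o - e_hat)^2 /
e_hat with the conventions: 0/0 -> 0; o > 0 with e_hat = 0 -> +inf sentinel,
flagged (this cannot arise for counts produced by the pipeline, since o > 0
implies both codon frequencies are positive).

**Shuffle null.** Codon order is permuted uniformly within each sequence
with the terminal stop fixed, which preserves the codon count vector f
exactly (asserted bit-exactly) while destroying pair correlations. Each of
the 200 replicates recomputes o, the group rescaling and chi2 (e itself is
invariant because f is); the per-bicodon null mean and SD (ddof = 1) give
z = (chi2 - mean)/SD. The low and high samples are shuffled and standardized
independently. Replicate RNG streams are spawned from one master seed, so
the replicate set is deterministic and order-independent. SD = 0 cases give
z = 0 when chi2 equals the null mean and an undefined sentinel (NaN,
withheld from classification and logged) otherwise.

**Classification.** unbiased if p >= 0.01; otherwise unexplained
(low or high by the sign of pi) if the combined null deviation reaches 3 SD,
else explained_biased. The combined deviation defaults to max(z_L, z_H),
the per-axis reading of a 3-SD quadrant rule; a `sum` rule that
standardizes chi2_L + chi2_H against its own null (means add, variances add
across the independently shuffled samples) is provided, since the summed
residual is the other defensible reading. The 3-SD cut corresponds to a
two-sided normal tail of 0.003.

## Sample selection

Candidates are ordered by abundance (ties by ID, for determinism) and walked
from one extreme; a candidate of length l is accepted when
`exp(-(l - l_o)^2 / (2 sigma)) > r` with r uniform on (0,1). `sigma` plays a
*variance* role: with the defaults — l_o and sigma the mean and variance of
the pooled candidate lengths — the weight is exp(-z^2/2) in standardized
length and is unit-free. The alternative reading (sigma = SD) was examined
and rejected: it makes the rule unit-dependent, and in either unit system it
degenerates — the acceptance window becomes so narrow that either the
sampler cannot fill 500 slots or the walk consumes the entire
abundance-ordered list, destroying the low/high abundance contrast the
analysis depends on. Unaccepted records are revisited with fresh draws for
up to `max_passes` = 100 passes.

What the Gaussian reweighting achieves is *partial* length matching: it
shrinks the mean-length gap between the two tails by roughly the posterior
factor var_weight/(var_tail + var_weight) ~ 1/2. With the generator's
length-abundance correlation of -0.2, the residual gap measures ~0.3 pooled
SD at 500 + 500 from 5,000 genes (from ~0.7 SD unweighted). Tighter matching
under this acceptance rule would require a weaker correlation than real
proteomes show; the residual gap is a property of the procedure, not of the
implementation.

Isoform deduplication keeps one record per gene: highest abundance, ties to
the lexicographically smallest ID.

## Synthetic proteome generator

The generator emulates the features of proteome-scale data the analysis
relies on, with defaults chosen to resemble a yeast-like proteome:

* **Abundance**: lognormal, log-mean 1.5, log-SD 2.0 (ppm; median ~4.5,
  ~5 decades of dynamic range, right-skewed).
* **Length**: lognormal codon count, log-mean 6.0 (~400 codons), log-SD 0.5,
  with correlation rho = -0.2 between log-length and log-abundance —
  mid-range of reported negative abundance-length correlations
  (~ -0.15 to -0.3).
* **Residues**: i.i.d. from average proteome amino-acid frequencies, first
  residue forced to Met; stop codon drawn from yeast-like weights
  (TAA 0.47, TAG 0.23, TGA 0.30).
* **Codon profiles**: per-amino-acid codon weights, one profile per
  expression class (median split of drawn abundance). Defaults: uniform
  weights for the low class and geometrically biased weights (2:1 ratios)
  for the high class, emulating the stronger codon usage bias of highly
  expressed genes. Setting both to the same profile yields an exact null.
* **Couplings**: a coupling (P-codon, A-codon, multiplier m, class)
  multiplies the A-codon's weight by m whenever it follows the P-codon in a
  gene of that class, then renormalizes *within the amino acid's synonymous
  codons*. This plants pair-level bias while leaving the residue sequence
  distribution untouched — precisely the signal the residual score is meant
  to isolate. `expected_pair_frequency` returns the planted conditional
  distribution in closed form and is the oracle for recovery tests.

What the generator does *not* emulate: intra-gene codon autocorrelation
beyond first order, GC-content gradients, position-dependent codon usage
(e.g., 5' ramps), isoform structure, and measurement noise in abundance.
Passing recovery tests therefore demonstrates statistical correctness of the
pipeline, not robustness to every artefact of real proteomics data.

## Numerical and design conventions

* Empty synonymous groups: RSBU = 0 for all members, flagged; Fisher on
  empty margins returns p = 1.
* p = 0 (possible only through underflow) is clamped to the smallest
  positive double with a warning before taking logs.
* Heat maps are 64 x 64 grids with the three stop P-site rows masked (192
  masked cells), so the universe occupies the grid exactly once. Axis
  clustering is average-linkage (UPGMA) on Euclidean distances, masked cells
  treated as 0; dendrogram leaves are ordered deterministically by orienting
  every subtree smallest-leaf-first.
* Candidate filtering (pi > 0.75, p < 0.01, occupancy > 0.03) uses strict
  inequalities; bicodons missing from the occupancy table are excluded with
  a warning.
* The synonymous-SNP report looks up pi for the reference and variant forms
  of both flanking bicodons; values absent from the stats table are reported
  as absent, never as zero.
* Benjamini-Hochberg adjusted p-values are emitted as an extra column for
  convenience; classification uses raw p < 0.01 throughout.

## Problem sizes

The shipped analysis uses 5,000-gene proteomes with 500 + 500 selected
sequences and 200 shuffle replicates per sample. The test suite runs the
same study design at 1,500 genes for the multi-seed calibration and recovery
checks (5 and 10 seeds respectively) and 800-1,000 genes for unit-level
fixtures; at these sizes a planted multiplier-6 coupling is recovered with
z two orders of magnitude above the 3-SD threshold, so the scaled-down
conditions do not sit near the decision boundary.
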