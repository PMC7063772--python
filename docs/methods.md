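# Methods

## Model and quantities

The unit of analysis is the species-mean ΔLFE profile. For one CDS
*p*, local folding energy is evaluated on every 40-nt window at 10-nt
steps, anchored at the CDS start (offsets are window-start positions,
window 0 = first 40 nt) or at the CDS end (offsets are window-end
positions from the 3′ terminus; the window at end-offset *e* covers
`[L−40−e, L−e)`). Windows lie strictly inside the annotated CDS, which
is folded in full including the terminal stop codon, with T read as U.
The profile span is capped at 300 nt per anchor (31 grid positions),
configurable.

ΔLFE_i = nativeLFE_i − mean over N randomized sequences. The null
ensembles (default N = 20) preserve, per the null model chosen:

- **CDS-wide**: protein, per-CDS codon multiset, nucleotide counts
  (so GC is exactly invariant). Implemented as an independent
  Fisher–Yates permutation of each amino-acid family's codons within
  the CDS. Stop codons form their own family; the start codon is
  shuffled within its family like any other position unless
  `pin_first_codon=True` (default off — nothing in the construction
  requires exempting it, and the option records the choice).
- **Positional (vertical)**: protein per CDS, and the codon multiset
  at each codon position (counted from the CDS start) across the
  genome. Positions are indexed from the start only; end-anchored
  vertical shuffling is not implemented.

Replicate RNG seeds derive from (master seed, replicate index, MD5 of
the CDS/species id), so ensembles are bit-reproducible and independent
of processing order.

Significance at position *i* is the two-sided Wilcoxon signed-rank
test on the pooled differences d_i(p, n) = nativeLFE_i(p) −
randomizedLFE_i(p, n); all-zero inputs return p = 1.0 by convention.
**Caveat:** the N replicate differences within one CDS share the same
native window, so pooling inflates the effective sample size; the
canonical pooled test is anticonservative position-wise. Type-I
calibration is exact with N = 1 (used for the null-recovery check)
and with `aggregate='per_cds'`, which tests per-CDS mean differences
instead (provided, non-canonical).

## Folding backends

The builtin backend is a nested-pairing (pseudoknot-free) dynamic
program minimizing the sum of pair energies GC = −3, AU = −2, GU = −1
with at least 3 unpaired bases between the ends of any pair. The
constants are fixed properties of the artifact and are **not**
thermodynamic parameters; a temperature argument is accepted for
interface parity and ignored. Ties in the recursion resolve toward
the unpaired decomposition; only the energy is reported, so tie-breaks
never affect output. The DP is verified against exhaustive enumeration
of all nested structures (plain recursion, no shared memoisation) for
sequences up to 25 nt. An `RNAfoldBackend` adapter shells out to any
RNAfold-compatible program (sequence on stdin, trailing "(energy)"
parsed) for real MFE values in kcal/mol at a configurable temperature;
it is opt-in and not used by any test oracle. Window energies are
memoised in a content-addressed cache keyed by encoded window bytes,
since randomized windows repeat.

## Profile model rules

Ranges on the 10-nt grid enumerate grid offsets: "0–10 nt" = {0, 10},
"200–300 nt" = {200, 210, …, 300}, "100–200 nt" = {100, …, 200}.
Element A (Model 1) requires mean ΔLFE > 0 with position-Wilcoxon
p < 0.05 at both start offsets {0, 10}; D is the mirror at end offsets
{10, 0}; C requires mean < 0 and p < 0.05 at every offset 200–300 from
*both* anchors; E = A∧C∧D. The transition peak B takes i* = argmin of
the mean start-anchored profile over 0–300 nt, requires i* ∈ [20, 80],
and tests the paired differences w_i(p, n) = d_i*(p, n) − d_i(p, n)
against every flank offset in {0, 10} ∪ {100..200}: Wilcoxon p < 0.05
with median w < 0 (the peak strictly below the flank; the sign follows
directly from the w construction). Model 2 relaxes A/D to "terminal
offset 0 significantly higher than each offset in 200–300", using the
same paired-w machinery — the minimal consistent reading, since the
paired construction is only spelled out for B. "Positive and
significant" for Model 1 A/D is read as the one-sample position test
against zero (the canonical interpretation here); comparisons between
positions always use the paired test.

Pairing is by (CDS, replicate), restricted to CDSs covering both
offsets; if no CDS covers both, the comparison fails with a
diagnostic rather than passing vacuously.

## Phylogenetic regression

Trees are pruned to the analysed species with single-child nodes
merged by summing branch lengths (tip-to-tip path lengths are exact
invariants). Ultrametricity is imposed by mean-path smoothing: node
ages are computed bottom-up as the mean over children of (branch +
child age), then each child subtree is rescaled multiplicatively so
its tips land exactly at the parent's age — branch lengths stay
positive and only *relative* depths are meaningful. The Brownian
covariance sets V[i,j] to the root-to-MRCA depth; GLS estimates,
t-tests and the R² above are invariant to any global rescaling of V
(asserted in tests), which is why relative depths suffice and why
closed-form GLS (Cholesky-whitened least squares) is exact here — for
a fixed Brownian V known up to scale, REML estimation of the residual
variance changes nothing about β, t, p or R². The R² denominator
centers on Ȳ, the intercept of the intercept-only GLS, with e the
first design column. Continuous traits get an intercept; discrete
traits become unordered-factor dummies with no intercept and a
mean-centered response, with a joint F-test (single continuous slopes
use the t-test). Species missing a trait or profile are dropped
pairwise per regression and n is reported. Singular V draws a jitter
ridge of 1e−10 × mean diagonal with a warning; collinear designs are
an error.

Robustness sweeps fit all 31 single positions and all 496 contiguous
subranges (mean ΔLFE over the subrange as response). Taxon scans fit
every taxonomic group at any rank with ≥ 9 usable species; the
reported R² is the median of per-position R² over the position range,
the p-value comes from the region-mean fit, and Benjamini–Hochberg
FDR is applied across taxa (the procedure is the field default where
"FDR correction" is otherwise unspecified).

## Codon-usage metrics

ENc is Wright's effective number of codons on pooled genome-wide
codon counts (per-gene mode exists but is non-canonical):
Nc = Σ_k N_k / F̄_k with F = (nΣp² − 1)/(n − 1) per family, families
grouped by degeneracy, capped at 61. Families with fewer than two
observations are excluded from their class average; a class with no
estimable family borrows the mean of neighbouring classes (the
standard convention for sparse 3-fold families). ENc′ replaces F by
F′ = (χ² + n − m)/(m(n − 1)), where χ² measures deviation from codon
frequencies expected under the background nucleotide composition —
by default the pooled mononucleotide frequencies of the same CDS set,
optionally supplied explicitly. With a uniform background F′ reduces
algebraically to F, so ENc′ ≈ ENc on composition-balanced genomes;
with a self-estimated background, fully degenerate usage shifts the
background itself, so the theoretical minimum of 20 is attained
exactly only under an explicit uniform background.

## Profile summaries

Region correlations are Spearman on per-species region means, with
the large-sample t approximation for p and exact permutation below
n = 10. PCA (scikit-learn, 3 components, first two displayed) reports
explained-variance ratios and a 500-resample bootstrap of component
angles. Characteristic profiles use plain agglomerative clustering
with average linkage under correlation distance (1 − Pearson r);
average linkage is the choice most compatible with the
centroid-distance stopping rule, and K is the smallest cluster count
for which every member is within the threshold (0.8 start-anchored,
1.3 end-anchored) of its cluster centroid. ("K-nearest-neighbour
agglomerative" is ambiguous; a KNN connectivity option is deliberately
not the default.) MIC follows the MINE approximation: grids bounded by
B(n) = n^0.6, one axis equipartitioned (ties share a bin), the other
optimized by dynamic programming over clumps with the superclump cap
c = 15 per column; both orientations are tried and the best normalized
mutual information over the grid family is reported. Setting c = 0
disables the cap, making the per-grid optimization exact over the
equipartitioned axis — verified against brute-force cut enumeration
for n ≤ 12 on 2×2..3×3 grids. p-values are permutation tails with the
+1 correction (default 10,000 permutations).

The weak-profile classifier labels a species "weak" when the standard
deviation (population, ddof 0) of its start-anchored 31-position
profile is below 0.14, and predicts weakness by the disjunction:
endosymbiont, or genomic GC < 38%, or genomic ENc′ > 56.5, or optimum
growth temperature > 58 °C; a missing trait makes its clause false.

## Synthetic data: what it emulates and what it does not

Genomes are sampled codon-by-codon: amino acids i.i.d. uniform over
the 20 (configurable), synonymous codons from a softmax over codon
GC-count whose inverse temperature is solved (Brent) so expected GC
hits the per-species target, mixed with a point mass on a per-family
preferred codon with weight `cub_strength` (0 = uniform usage, 1 =
one codon per family, ENc → 20). CDSs are ATG + interior + one stop;
achieved GC lands within ±2% of target for ≥ 100 CDSs when the target
is reachable (roughly 0.30–0.63 under uniform amino-acid frequencies;
outside that range the generator warns and clamps). Trees are Yule
(pure birth) via dendropy with tip branches extended by the
Exp(nλ) waiting time to the next unrealized speciation, so branches
are positive and the tree exactly ultrametric; continuous traits are
Brownian (multivariate normal with covariance σ²V); binary traits are
painted on whole clades, emulating once-per-lineage origins such as
endosymbiosis.

Folding-strength signal is injected by hill-climbing over synonymous
codon *swaps* (never resampling), accepting only moves that shift the
mean builtin window energy over the target region in the requested
direction. Protein, per-CDS codon multiset and GC are therefore exact
invariants of injection, which makes detected ΔLFE attributable purely
to arrangement — the causal quantity the null models isolate. Default
bias templates place "weaker" regions in the first and last 50 nt and
a "stronger" region mid-CDS, with effort (proposal counts) of a few
hundred per region, chosen so a 30-CDS species at 450 nt yields an
unambiguous Model-2 profile.

For association-stage testing there is also a profile-level cohort
generator that emits trait-linked 31-position ΔLFE vectors directly
(canonical shape scaled by an amplitude the four weak-profile clauses
suppress, plus Gaussian noise) without any folding. It exercises the
classifier, regression and summary machinery cheaply; it does not
test the folding or null-model stages, which the genome-level path
covers.

What passing these tests shows — and does not. Synthetic genomes have
i.i.d. codons, uniform amino-acid usage, fixed CDS lengths, no UTRs,
operons, expression structure, dinucleotide or codon-pair bias.
Detection power and calibration demonstrated here therefore speak to
the correctness of the machinery, not to effect sizes in real genomes;
real-data profile magnitudes also depend on the folding backend (the
builtin scorer's units are arbitrary).

## Problem sizes and numerical choices

Cohort-scale checks run at sizes chosen to exercise the statistics
properly on one CPU: null calibration uses 200 unbiased species of
100 × 300-nt CDSs with N = 1 (position-wise rejection expected within
[2.5%, 8%] at α = 0.05); signal recovery uses 20 biased and 20 control
replicates (30 × 450-nt CDSs, N = 10); GLS calibration uses 500
Brownian replicates on 30-tip trees; conservation is checked
exhaustively on 1,000 CDSs; the acceptance script repeats the same
computations at moderately reduced replicate counts (60 null species,
10 + 10 recovery replicates) as its own demonstration scale. Wilcoxon
uses scipy's implementation (exact for small n, normal approximation
with tie/zero handling otherwise). The builtin DP is numba-jitted;
energies are float64 and comparisons exact since all quantities are
small integers. Cholesky factorization backs all GLS solves; V is
validated symmetric p.s.d. within 1e−10 in tests.

## Known limitations

- The builtin energy model ignores stacking, loop entropies and
  temperature; only the external backend yields physical MFEs.
- The pooled Wilcoxon's dependence caveat above: position-wise p-values
  under the canonical N = 20 pooling overstate certainty.
- Mean-path smoothing is a lightweight stand-in for penalized rate
  smoothing; it preserves relative depths well on clock-like trees but
  is not a substitute for proper dating when absolute ages matter.
- Pure Brownian V only: no Pagel's λ or Ornstein–Uhlenbeck extensions.
- The positional null shuffles relative to CDS starts only.
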