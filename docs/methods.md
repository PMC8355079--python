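# Methods

This note documents the models implemented in `chemobarcode`, the
parameters that matter, what the synthetic-data generators emulate (and do
not), and the numerical and design choices made where the design was
genuinely open.

## SBS96 catalogues

Single-base substitutions are classified by the mutated pyrimidine and its
5'/3' flanks; purine-reference mutations are reverse-complemented first.
The channel order is substitution-major (C>A, C>G, C>T, T>A, T>C, T>G) with
flanks alphabetical — the COSMIC file order — and is a package constant.
Coordinates are 1-based (VCF convention); the context window is
[pos−1, pos+1]. Multi-nucleotide input rows are never treated as SNVs;
double-base substitutions are instead detected post hoc as adjacent SNV
pairs of one sample, a run of L adjacent SNVs contributing ⌊L/2⌋ DBS paired
left to right. This adjacency convention is a package decision: callers
differ in how (or whether) they phase DBS.

The blood-somatic filter applies, in order: caller PASS; ≥2 supporting
reads; VAF strictly < 0.5 (a true heterozygous clonal variant in a pure
sample sits at 0.5; blood somatic mutations from a partially expanded clone
sit below); a variant blacklist with frequencies (a generic stand-in for
panel-of-normals/population filtering, so no external download is needed);
an optional region blacklist (BED-style intervals); and finally exclusion
of whole samples whose surviving burden exceeds the cohort's 97.5th
percentile, treating outlier burdens as unreliable calling. Each rejected
record carries exactly its first failing reason, which makes filter audits
additive.

## Signature profiles and the HSC signature

A signature is a probability vector over the 96 channels (sum 1 within
1e-9). The mean ("HSC") signature of a healthy-blood catalogue is computed
in count space: mean per-channel count across samples divided by the mean
total. This weighs samples by burden — identical to pooling all mutations
and normalizing once — rather than averaging per-sample normalized
profiles; for clock-like processes the distinction is small but the
count-space reading matches the derivation the package emulates.

### Fixture signatures

Simulations need signature shapes, not exact reference vectors. The
fixtures are parametric templates Dirichlet-perturbed at concentration
2000 (so a given (kind, seed) is deterministic and different seeds give
same-shaped, distinct profiles):

- `platinum_like`: C>T peaks with a 5' C (C[C>T]N) plus secondary C>A
  mass — the SBS31 character. Cosine to `hsc_like` ≈ 0.36, in the range of
  the real SBS31/SBS5 overlap.
- `fivefu_like`: T>G peaks in N[T>G]T context, dominated by T[T>G]T and
  C[T>G]T — the SBS17b character.
- `hsc_like`: broad clock-like profile over all channels with mild C>T/T>C
  tilts and a CpG>TpG bump — the SBS5-like hematopoietic background.
- `flat`: exactly uniform (1/96), used as an uninformative noise profile.

These are synthetic stand-ins constructed for testing, not copies of COSMIC
vectors; user-supplied COSMIC-format TSVs flow through the same code paths.

## De novo extraction (bootstrap KL-NMF)

The factorization minimizes the generalized Kullback-Leibler divergence
between the catalogue and W·H by multiplicative updates (the Poisson
likelihood, matching the established signature-extraction family), with
W's columns normalized to probability vectors and the scale carried by H.
Convergence: relative objective change < 1e-8 (checked every 10 updates) or
10,000 iterations; the objective is non-increasing by construction.

Stability is assessed by resampling each sample's counts (multinomial with
total preserved) `n_bootstraps` times, factorizing each replicate from
`n_inits` random initializations (best objective kept), and clustering the
pooled k-per-replicate signatures by greedy best-cosine assignment to
running centroids. Greedy matching (rather than Hungarian assignment) is
the default for simplicity; at k ≤ 3 and well-separated processes the two
coincide. Reported signatures are renormalized centroid means; stability is
the per-cluster mean silhouette under cosine distance (for k=1, where the
silhouette is undefined, the mean cosine of members to the centroid is
reported instead). Negative silhouettes are logged as unstable, not fatal.
Final exposures are least-squares refits of the centroids on the original
catalogue (no weight floor), so exposure rows reconstruct sample totals.

Rank selection is deliberately manual: `rank_sweep` reports mean silhouette
and reconstruction error across candidate k, but no automatic choice is
made. An identifiability caveat worth knowing: NMF recovers extreme rays of
the data cone, so a process that never dominates any sample (e.g. ~22% of
the burden in a few samples) is recovered only up to background admixture —
measured ceiling ≈ 0.83–0.89 cosine in the synthetic tAML pooling test —
whereas at ~50% contribution recovery exceeds 0.97.

## Refitting and per-mutation attribution

`fit_exposures` minimizes the squared error between the normalized observed
profile and a convex combination of the signature set (non-negative least
squares with a sum-to-one constraint row), then iteratively drops the
weakest signature while any weight is below the floor and refits. The floor
defaults to 0.06, the convention of the deconstructSigs-style refitting
family (the value is exposed as a flag); it is what removes
"signature-bleeding" artifacts — small spurious exposures to signatures the
sample was never exposed to. Activities are weights × total mutation count;
the residual is the cosine between reconstructed and observed profiles.

Individual mutations are attributed by maximum likelihood: a mutation in
channel c gets argmax_s activity_s × P_s(c), ties broken by signature order,
and label "unassigned" when every product is zero. Hard assignment is used
(soft posteriors are a non-goal); aggregate label totals track activities on
large catalogues but reshuffle individual overlap channels.

## Negative-binomial presence test

Channel counts are modeled as NB with mean μ_c = (S·e)_c and one shared
size parameter r ("dispersion", default 10, exposed as a flag — variance
μ + μ²/r, so r→∞ recovers Poisson). Exposures e ≥ 0 are fit by multi-start
bounded L-BFGS-B with analytic gradients (starts: the least-squares refit,
a uniform split, three Dirichlet draws, plus a caller warm start). The LRT
compares the background-only fit to background+foreign; the alternative is
warm-started at the null solution so the maximized likelihood can never
decrease, and the statistic is clamped at 0. Because the foreign exposure
is tested on the boundary of its parameter space, the null is the mixture
½χ²₀ + ½χ²₁: p = 1 at Λ = 0 and p = ½·P(χ²₁ ≥ Λ) otherwise. On multinomial
synthetic data this is conservative (measured type-I error 0.00–0.02 at
nominal 0.05), which is the safe direction for presence claims.

## Synthetic cohorts and the limit of detection

`generate_cohort` draws each sample's total burden from either an explicit
list or a negative binomial, and channels multinomially from a background
mixture. The blood-like defaults — 100 samples, NB(mean 100, size 2),
HSC-like background — mirror a CH-positive blood cohort where hematopoiesis
contributes on the order of 100 mutations per sample. `inject_signature`
adds exactly k multinomial draws from the foreign profile to every sample.

The limit-of-detection experiment runs the presence test per sample on the
baseline and on each injected cohort, then compares foreign-exposure
distributions with a one-tailed empirical permutation test (statistic:
difference of means, median behind a flag; p = (1+#{perm ≥ obs})/(n_perm+1)
with 1000 permutations by default). Under these conditions the per-sample
NB-MLE exposure is nearly unbiased (injected cohorts' mean exposure tracks
k within a few percent) with baseline noise sd ≈ 2.4 mutations, so the
cohort-level mean test at n=100 resolves a shift of ~1 mutation and the
smallest significant level over the default grid is 3. A cohort whose
baseline reconstruction is noisier (larger multi-signature backgrounds,
smaller cohorts) would push this boundary upward; the experiment exposes
every one of those knobs.

The synthetic tAML generator draws each sample's background from the HSC
profile admixed with flat noise (weight 0.1 — the "noise" component is
deliberately uninformative since no specific artifact process is modeled)
and injects a rounded-normal (mean 279, sd 71 by default, floored at 0)
number of mutations from the designated signature.

The clonal-cohort generator places clonal mutations at expected VAF ρ/2
(diploid, multiplicity 1) and subclonal mutations at ρ·u/2 with subclone
CCF u ~ Uniform(0.1, 0.6); alt reads are binomial at the sampled depth, and
truth labels ride on the records. What these generators do *not* emulate:
sequencing-error channels, mappability structure, site-level genome
context, copy-number variation, or correlated (lesion-segregation) mutation
placement — so passing tests demonstrate correctness of the statistical
machinery under the stated model, not robustness to every artifact of real
sequencing data.

## Clonality

CCF = VAF · (ρ·CN + 2(1−ρ)) / (ρ·m) for purity ρ, local total copy number
CN and multiplicity m; defaults CN=2, m=1 (largely diploid AML genomes),
both accepted per mutation. The 95% CI transforms the exact Clopper-Pearson
binomial interval for the VAF through the same affine map (Wilson behind a
flag; the exact interval is the conservative default at low alt counts). A
mutation is subclonal iff the CI upper bound is below 1 — a simplified
two-state replacement for full probabilistic timing models, sufficient
because the downstream statistics need only the dichotomy. CCF point
estimates above 2 are flagged, not fatal. Timing summaries pseudocount each
stratum (Haldane-Anscombe, 0.5) so clonal/subclonal fold changes stay
finite when a signature is absent from a stratum.

## Cohort statistics

Mann-Whitney comparisons enumerate the exact U null over all rank splits
when the pooled size is ≤ 12 (ties handled via half-counts) and otherwise
use the tie-corrected normal approximation with mid-ranks. The burden-age
regression is OLS with Pearson r, its t-transform p-value, and the 95%
mean-response band. Gene overrepresentation uses Haldane-corrected (+0.5
per cell) log odds ratios with Wald CIs, two-sided Fisher exact p, and
Benjamini-Hochberg adjustment across genes. The detectability logistic
model is fit by IRLS (iteration cap 100; complete separation reported at
the cap with a converged=False flag); continuous covariates are z-scored so
coefficients are comparable; candidate covariate subsets come from
configuration ("a:b" spells an interaction as a product column), tumor
types with ≤ 10 samples are excluded, and model selection takes the lowest
BIC with ties broken by the higher mean auROC over 100 random 30% holdouts.

## Problem sizes and determinism

Default test and acceptance problem sizes (100-sample detection cohorts,
32-sample extraction cohorts at 50 bootstraps, 200 null simulations for
calibration, n=2000 clonality cohorts) were chosen so the full suite and
the acceptance script each complete in well under a minute of NumPy-bound
compute while keeping Monte-Carlo error comfortably inside the asserted
tolerances. Every stochastic component is a pure function of an explicit
seed: cohort generation, bootstrap resampling (per-replicate seeds spawned
from the master seed), optimizer restarts, permutation tests, and holdout
splits, so identical configurations reproduce bit-identical artifacts.
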